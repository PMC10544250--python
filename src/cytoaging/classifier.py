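"""Disease-status prediction from immunophenotypes: PCA + logistic regression
with repeated random train-test splits.

Per split, principal components are fit on the training portion only, the
first ``n_components`` scores feed an (unpenalized) logistic regression of
disease vs control status, and the AUROC is computed on the held-out
portion; the headline number is the mean AUROC over splits. Running the
procedure on uncorrected features, all age-corrected centiles, and the
significant age-corrected subset quantifies how much age correction helps
disease prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = ["ClassifierConfig", "ClassifierResult", "evaluate_classifier", "compare_feature_sets"]


@dataclass(frozen=True)
class ClassifierConfig:
    """PCA + logistic regression evaluation parameters.

    Defaults follow the original protocol (30 components, 80:20 splits);
    ``n_splits`` defaults to a desk-scale 100 with the original 1000
    available by override. ``leaky_pca=True`` reproduces the variant where
    the PCA basis is fit once on all subjects before splitting.
    """

    n_components: int = 30
    n_splits: int = 100
    test_fraction: float = 0.2
    leaky_pca: bool = False
    seed: int = 0

    def validate(self, n_subjects: int, n_features: int) -> None:
        if not (1 <= self.n_components <= min(n_subjects, n_features)):
            raise ValueError("n_components must be <= min(n_subjects, n_features)")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


@dataclass
class ClassifierResult:
    mean_auroc: float
    sd_auroc: float
    aurocs: np.ndarray = field(repr=False)
    loadings: np.ndarray = field(default=None, repr=False)  # PCA components (diagnostic)
    explained_variance_ratio: np.ndarray = field(default=None, repr=False)


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    import warnings

    est = LogisticRegression(C=np.inf, max_iter=2000)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, y)
        return est
    except Exception:  # separation or other failure: small ridge fallback
        logger.debug("unpenalized logistic fit failed; falling back to small ridge")
        est = LogisticRegression(C=1e4, max_iter=2000)
        est.fit(X, y)
        return est


def evaluate_classifier(
    X: pd.DataFrame, labels: np.ndarray, config: Optional[ClassifierConfig] = None
) -> ClassifierResult:
    """Mean held-out AUROC of PCA + logistic regression over random splits.

    ``X`` must be median-imputed and z-scaled (or consist of centiles);
    ``labels`` are binary (1 = disease). Splits yielding a single class in
    either portion are redrawn.
    """
    config = config or ClassifierConfig()
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(labels).astype(int)
    n, p = Xv.shape
    config.validate(n, p)
    if set(np.unique(yv)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")

    rng = np.random.default_rng(config.seed)
    n_test = max(1, int(round(config.test_fraction * n)))
    k = min(config.n_components, p, n - n_test)

    pca_all = PCA(n_components=k).fit(Xv) if config.leaky_pca else None

    aurocs = np.empty(config.n_splits)
    for s in range(config.n_splits):
        for _ in range(100):
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if np.ptp(yv[test_idx]) > 0 and np.ptp(yv[train_idx]) > 0:
                break
        else:
            raise RuntimeError("could not draw a split with both classes present")
        if config.leaky_pca:
            Ztr, Zte = pca_all.transform(Xv[train_idx]), pca_all.transform(Xv[test_idx])
        else:
            pca = PCA(n_components=k).fit(Xv[train_idx])
            Ztr, Zte = pca.transform(Xv[train_idx]), pca.transform(Xv[test_idx])
        est = _fit_logistic(Ztr, yv[train_idx])
        scores = est.decision_function(Zte)
        aurocs[s] = roc_auc_score(yv[test_idx], scores)

    diag = PCA(n_components=k).fit(Xv)
    return ClassifierResult(
        mean_auroc=float(aurocs.mean()),
        sd_auroc=float(aurocs.std(ddof=1)) if config.n_splits > 1 else np.nan,
        aurocs=aurocs,
        loadings=diag.components_,
        explained_variance_ratio=diag.explained_variance_ratio_,
    )


def compare_feature_sets(
    uncorrected: pd.DataFrame,
    corrected: pd.DataFrame,
    significant: Sequence[str],
    labels: np.ndarray,
    config: Optional[ClassifierConfig] = None,
) -> Mapping[str, ClassifierResult]:
    """Evaluate the three feature sets under a shared seed schedule.

    Arms: ``all-uncorrected`` (imputed/scaled raw features), ``all-corrected``
    (age-corrected centiles), ``significant-corrected`` (centiles of the
    disease-associated subset). All arms see identical split sequences, so
    identical inputs give identical AUROCs. An empty significant set skips
    that arm with a warning.
    """
    config = config or ClassifierConfig()
    if list(uncorrected.index) != list(corrected.index):
        raise ValueError("feature matrices must cover the same subjects in the same order")
    arms = {
        "all-uncorrected": uncorrected,
        "all-corrected": corrected,
    }
    significant = [f for f in significant if f in corrected.columns]
    if significant:
        arms["significant-corrected"] = corrected[significant]
    else:
        logger.warning("empty significant feature set; skipping that arm")
    out = {}
    for name, Xarm in arms.items():
        cfg = replace(config, n_components=min(config.n_components, Xarm.shape[1]))
        out[name] = evaluate_classifier(Xarm, labels, cfg)
    return out
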