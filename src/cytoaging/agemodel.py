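"""Two-stage random-lasso immunological-age model and residual-age analyses.

The estimator regresses chronological age on standardized immunophenotype
features with a bootstrap ensemble of lasso fits:

* stage 1 - on each bootstrap resample of the training set, a lasso is fit
  on a small random feature subset (a fraction drawn uniformly from
  ``q1_range``); the initial importance of a feature is its coefficient
  averaged over bootstraps, with bootstraps that did not draw the feature
  contributing 0;
* stage 2 - a second bootstrap ensemble samples ``q2 * p`` features without
  replacement with probability proportional to |initial importance| and
  averages the resulting lasso coefficients;
* the two stages run inside an outer loop of random train-test splits, and
  the overall importance of a feature is the average of its per-split
  stage-2 coefficients;
* an importance cutoff is chosen by repeated k-fold cross-validation: for
  each candidate cutoff, a linear model on the features above it is scored
  by RMSE, the elbow of the RMSE-vs-cutoff curve is located per repeat
  (maximum perpendicular distance from the chord), and the final cutoff is
  the mean of the per-repeat elbows.

Features with |importance| above the cutoff form the retained set; the
final age predictor is the affine map given by the averaged coefficients of
the retained features. The difference between predicted ("immunological")
and chronological age, and its association with clinical covariates, is
quantified by :func:`residual_age_analysis`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso, LassoCV

logger = logging.getLogger(__name__)

__all__ = [
    "RandomLassoConfig",
    "RandomLassoModel",
    "ResidualAgeResult",
    "fit_random_lasso",
    "random_lasso_stage1",
    "random_lasso_stage2",
    "estimate_cutoff",
    "elbow_point",
    "predict_age",
    "residual_age_analysis",
]


@dataclass(frozen=True)
class RandomLassoConfig:
    """Random-lasso hyperparameters.

    Defaults are the desk-scale configuration (100 splits / 100 bootstraps
    per stage); :meth:`full_scale` returns the original 1000/1000/1000
    setting. ``alpha`` fixes the lasso penalty; when None it is chosen by
    internal cross-validation on a representative bootstrap of each split
    (``alpha_mode='per-split-cv'``) or of every bootstrap
    (``'per-bootstrap-cv'``).
    """

    n_splits: int = 100
    test_fraction: float = 0.2
    n_boot1: int = 100
    n_boot2: int = 100
    q1_range: tuple = (0.15, 0.20)
    q2: float = 0.10
    cv_folds: int = 5
    cv_repeats: int = 20
    alpha: Optional[float] = None
    alpha_mode: str = "per-split-cv"
    n_alphas: int = 20
    inner_cv_folds: int = 3
    signed_selection: bool = False
    absent_as_zero: bool = True
    passthrough_bootstrap: bool = False
    n_cutoff_candidates: int = 40
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_splits", "n_boot1", "n_boot2", "cv_folds", "cv_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in [0, 1)")
        q1l, q1h = self.q1_range
        if not (0.0 < q1l <= q1h <= 1.0):
            raise ValueError("q1_range must satisfy 0 < lo <= hi <= 1")
        if not (0.0 < self.q2 <= 1.0):
            raise ValueError("q2 must be in (0, 1]")
        if self.alpha_mode not in ("per-split-cv", "per-bootstrap-cv"):
            raise ValueError("alpha_mode must be 'per-split-cv' or 'per-bootstrap-cv'")

    @classmethod
    def full_scale(cls, **overrides) -> "RandomLassoConfig":
        return cls(**{"n_splits": 1000, "n_boot1": 1000, "n_boot2": 1000, **overrides})


@dataclass
class RandomLassoModel:
    """Fitted random-lasso age model."""

    features: list
    importance: pd.Series  # averaged stage-2 coefficients per feature
    cutoff: float
    retained: list  # features whose |importance| exceeds the cutoff
    coef: pd.Series  # full averaged coefficient vector (the age predictor)
    intercept: float
    train_r2: float
    heldout_r2: float
    heldout_r2_sd: float
    config: RandomLassoConfig

    def to_json(self, path=None) -> str:
        import dataclasses as _dc
        import json

        payload = json.dumps(
            {
                "features": self.features,
                "importance": self.importance.to_dict(),
                "cutoff": self.cutoff,
                "retained": self.retained,
                "coef": self.coef.to_dict(),
                "intercept": self.intercept,
                "train_r2": self.train_r2,
                "heldout_r2": self.heldout_r2,
                "heldout_r2_sd": self.heldout_r2_sd,
                "config": _dc.asdict(self.config),
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


# ---------------------------------------------------------------------------
# lasso plumbing
# ---------------------------------------------------------------------------


def _fit_lasso(X: np.ndarray, y: np.ndarray, alpha: float):
    """Single lasso fit; returns (coef, intercept)."""
    est = Lasso(alpha=alpha, max_iter=5000, tol=1e-6)
    est.fit(np.asfortranarray(X), np.ascontiguousarray(y), check_input=False)
    return est.coef_, float(est.intercept_)


def _cv_alpha(X: np.ndarray, y: np.ndarray, config: RandomLassoConfig) -> float:
    """Minimum-CV-error lasso penalty on the given design."""
    est = LassoCV(
        alphas=config.n_alphas, cv=config.inner_cv_folds, max_iter=5000, tol=1e-5
    )
    with np.errstate(all="ignore"):
        est.fit(X, y)
    return float(est.alpha_)


def _probe_alpha(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator, frac: float,
    config: RandomLassoConfig,
) -> float:
    """Alpha for a stage: CV on one representative bootstrap/subset draw."""
    n, p = X.shape
    rows = np.arange(n) if config.passthrough_bootstrap else rng.integers(0, n, n)
    k = max(1, round(frac * p))
    cols = rng.choice(p, size=k, replace=False)
    return _cv_alpha(X[np.ix_(rows, cols)], y[rows], config)


def _resample(rng, n, config):
    if config.passthrough_bootstrap:
        return np.arange(n)
    return rng.integers(0, n, n)


def random_lasso_stage1(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: RandomLassoConfig,
    rng: np.random.Generator,
    alpha: Optional[float] = None,
) -> np.ndarray:
    """Initial per-feature importance from lasso fits on random feature subsets.

    Features not drawn in a bootstrap contribute coefficient 0 to the
    average (set ``absent_as_zero=False`` to average over appearances only).
    """
    n, p = X_train.shape
    sums = np.zeros(p)
    counts = np.zeros(p)
    for _ in range(config.n_boot1):
        rows = _resample(rng, n, config)
        tries = 0
        while np.ptp(y_train[rows]) == 0:
            tries += 1
            if tries > 100:
                raise RuntimeError("could not draw a bootstrap with non-constant age")
            logger.debug("degenerate bootstrap (constant age); redrawing")
            rows = _resample(rng, n, config)
        frac = rng.uniform(*config.q1_range)
        k = max(1, round(frac * p))
        cols = rng.choice(p, size=k, replace=False)
        a = alpha
        if a is None:
            a = _cv_alpha(X_train[np.ix_(rows, cols)], y_train[rows], config)
        coef, _ = _fit_lasso(X_train[np.ix_(rows, cols)], y_train[rows], a)
        sums[cols] += coef
        counts[cols] += 1
    if config.absent_as_zero:
        return sums / config.n_boot1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def _selection_probs(importance: np.ndarray, k: int, signed: bool) -> np.ndarray:
    w = importance.copy() if signed else np.abs(importance)
    if signed:
        w = np.maximum(w, 0.0)
    if not np.any(w > 0):
        logger.debug("all stage-1 importances zero; falling back to uniform sampling")
        return np.full(len(w), 1.0 / len(w))
    if np.count_nonzero(w) < k:
        # too few positive-weight features to fill a draw without replacement
        w = w + w[w > 0].min() * 1e-9
    return w / w.sum()


def random_lasso_stage2(
    X_train: np.ndarray,
    y_train: np.ndarray,
    stage1_importance: np.ndarray,
    config: RandomLassoConfig,
    rng: np.random.Generator,
    alpha: Optional[float] = None,
) -> tuple:
    """Importance-weighted bootstrap lasso ensemble; returns (coef, intercept).

    Per bootstrap, ``q2 * p`` features are sampled without replacement with
    probability proportional to |stage-1 importance|; coefficients are the
    bootstrap average (absent features contributing 0).
    """
    n, p = X_train.shape
    k = max(1, round(config.q2 * p))
    probs = _selection_probs(stage1_importance, k, config.signed_selection)
    sums = np.zeros(p)
    int_sum = 0.0
    for _ in range(config.n_boot2):
        rows = _resample(rng, n, config)
        tries = 0
        while np.ptp(y_train[rows]) == 0:
            tries += 1
            if tries > 100:
                raise RuntimeError("could not draw a bootstrap with non-constant age")
            rows = _resample(rng, n, config)
        cols = rng.choice(p, size=k, replace=False, p=probs)
        a = alpha
        if a is None:
            a = _cv_alpha(X_train[np.ix_(rows, cols)], y_train[rows], config)
        coef, intercept = _fit_lasso(X_train[np.ix_(rows, cols)], y_train[rows], a)
        sums[cols] += coef
        int_sum += intercept
    return sums / config.n_boot2, int_sum / config.n_boot2


# ---------------------------------------------------------------------------
# importance cutoff
# ---------------------------------------------------------------------------


def elbow_point(x: np.ndarray, y: np.ndarray) -> int:
    """Index of the elbow: maximum perpendicular distance to the end chord.

    Coordinates are min-max normalized so the rule is scale free. Ties —
    including a perfectly flat curve, where every distance is 0 — resolve to
    the largest x (for an RMSE-vs-cutoff curve, the largest cutoff, i.e. the
    fewest features).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 points to locate an elbow")
    xr = np.ptp(x)
    yr = np.ptp(y)
    xn = (x - x.min()) / (xr if xr > 0 else 1.0)
    yn = (y - y.min()) / (yr if yr > 0 else 1.0)
    x0, y0, x1, y1 = xn[0], yn[0], xn[-1], yn[-1]
    chord = np.hypot(x1 - x0, y1 - y0)
    if chord == 0:
        return len(x) - 1
    dist = np.abs((y1 - y0) * xn - (x1 - x0) * yn + x1 * y0 - y1 * x0) / chord
    best = 0
    for i in range(1, len(x)):
        if dist[i] >= dist[best] - 1e-12:
            best = i
    return best


def _cv_rmse_for_cutoffs(X, y, importance, cutoffs, folds):
    """Pooled k-fold RMSE of an OLS refit for each importance cutoff.

    Per fold the centered Gram matrix is formed once; each cutoff's OLS is a
    subsystem solve on the retained features (cutoff candidates are nested).
    """
    n = len(y)
    abs_imp = np.abs(importance)
    sq_err = np.zeros(len(cutoffs))
    for train_idx, test_idx in folds:
        Xtr, ytr = X[train_idx], y[train_idx]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        Xc = Xtr - xm
        G = Xc.T @ Xc
        c = Xc.T @ (ytr - ym)
        ridge = 1e-10 * (np.trace(G) / max(G.shape[0], 1) + 1.0)
        Xte_c = X[test_idx] - xm
        yte_c = y[test_idx] - ym
        for ci, cut in enumerate(cutoffs):
            keep = np.flatnonzero(abs_imp > cut)
            if keep.size:
                beta = np.linalg.solve(
                    G[np.ix_(keep, keep)] + ridge * np.eye(keep.size), c[keep]
                )
                resid = yte_c - Xte_c[:, keep] @ beta
            else:
                resid = yte_c
            sq_err[ci] += float(resid @ resid)
    return np.sqrt(sq_err / n)


def estimate_cutoff(
    importance: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    config: RandomLassoConfig,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Importance cutoff from repeated cross-validated RMSE elbow detection.

    Candidate cutoffs span the sorted |importance| values (subsampled evenly
    in rank when there are many). For each CV repeat the RMSE-vs-cutoff
    curve's elbow is located; the final cutoff is the mean of the per-repeat
    elbow cutoffs.
    """
    rng = np.random.default_rng(rng)
    abs_imp = np.unique(np.abs(np.asarray(importance, dtype=float)))
    cand = np.unique(np.concatenate([[0.0], abs_imp]))
    if len(cand) < 2:
        raise ValueError("need at least 2 candidate cutoffs")
    if len(cand) > config.n_cutoff_candidates:
        idx = np.unique(
            np.linspace(0, len(cand) - 1, config.n_cutoff_candidates).round().astype(int)
        )
        cand = cand[idx]
    n = len(y)
    elbows = []
    for _ in range(config.cv_repeats):
        perm = rng.permutation(n)
        folds = [
            (np.delete(perm, chunk), perm[chunk])
            for chunk in np.array_split(np.arange(n), config.cv_folds)
        ]
        rmse = _cv_rmse_for_cutoffs(np.asarray(X, float), np.asarray(y, float),
                                    importance, cand, folds)
        # rank spacing on x: importance values bunch near zero, and the
        # elbow of interest is the knee where RMSE starts climbing as real
        # predictors drop out, not a feature of the value scale
        elbows.append(cand[elbow_point(np.arange(len(cand)), rmse)])
    return float(np.mean(elbows))


# ---------------------------------------------------------------------------
# full procedure
# ---------------------------------------------------------------------------


def fit_random_lasso(
    X: pd.DataFrame, y: np.ndarray, config: Optional[RandomLassoConfig] = None
) -> RandomLassoModel:
    """Fit the full two-stage random-lasso age model.

    ``X`` must already be preprocessed (median-imputed and z-scaled); ``y``
    is chronological age in years. The procedure is a pure function of
    (data, config): rerunning with the same seed reproduces importances
    bit for bit.
    """
    config = config or RandomLassoConfig()
    config.validate()
    feats = list(X.columns)
    Xv = np.ascontiguousarray(X.to_numpy(dtype=float))
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape

    ss = np.random.SeedSequence(config.seed)
    split_seeds = ss.spawn(config.n_splits + 1)
    coef_splits = np.zeros((config.n_splits, p))
    int_splits = np.zeros(config.n_splits)
    test_r2s = []
    n_test = int(round(config.test_fraction * n))
    for s in range(config.n_splits):
        rng = np.random.default_rng(split_seeds[s])
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        Xtr, ytr = Xv[train_idx], yv[train_idx]
        a1 = a2 = config.alpha
        if a1 is None and config.alpha_mode == "per-split-cv":
            a1 = _probe_alpha(Xtr, ytr, rng, float(np.mean(config.q1_range)), config)
            a2 = _probe_alpha(Xtr, ytr, rng, config.q2, config)
        imp1 = random_lasso_stage1(Xtr, ytr, config, rng, alpha=a1)
        coef_s, int_s = random_lasso_stage2(Xtr, ytr, imp1, config, rng, alpha=a2)
        coef_splits[s] = coef_s
        int_splits[s] = int_s
        if n_test > 0:
            pred = int_s + Xv[test_idx] @ coef_s
            resid = yv[test_idx] - pred
            tot = yv[test_idx] - yv[test_idx].mean()
            test_r2s.append(1.0 - np.sum(resid**2) / np.sum(tot**2))

    importance = coef_splits.mean(axis=0)
    intercept = float(int_splits.mean())
    cut_rng = np.random.default_rng(split_seeds[-1])
    cutoff = estimate_cutoff(importance, Xv, yv, config, rng=cut_rng)
    retained_mask = np.abs(importance) > cutoff
    # the cutoff labels features as age-predictive; the predictor itself is
    # the full averaged coefficient vector
    coef = importance.copy()

    pred_train = intercept + Xv @ coef
    resid = yv - pred_train
    train_r2 = float(1.0 - np.sum(resid**2) / np.sum((yv - yv.mean()) ** 2))

    return RandomLassoModel(
        features=feats,
        importance=pd.Series(importance, index=feats, name="importance"),
        cutoff=float(cutoff),
        retained=[f for f, m in zip(feats, retained_mask) if m],
        coef=pd.Series(coef, index=feats, name="coef"),
        intercept=intercept,
        train_r2=train_r2,
        heldout_r2=float(np.mean(test_r2s)) if test_r2s else np.nan,
        heldout_r2_sd=float(np.std(test_r2s, ddof=1)) if len(test_r2s) > 1 else np.nan,
        config=config,
    )


def predict_age(model: RandomLassoModel, X_new: pd.DataFrame) -> pd.Series:
    """Predicted immunological age: intercept + X_new . coef (deterministic).

    ``X_new`` must be preprocessed with the same TransformSpec as the
    training data; columns are matched by name, so column order is
    irrelevant. A missing retained feature raises, naming the column.
    """
    missing_retained = [f for f in model.retained if f not in X_new.columns]
    if missing_retained:
        raise KeyError(f"missing retained feature column(s): {missing_retained}")
    missing = [f for f in model.features if f not in X_new.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    coef = model.coef[model.features].to_numpy()
    pred = model.intercept + X_new[model.features].to_numpy(dtype=float) @ coef
    return pd.Series(pred, index=X_new.index, name="predicted_age")


# ---------------------------------------------------------------------------
# residual-age analyses
# ---------------------------------------------------------------------------


@dataclass
class ResidualAgeResult:
    """Downstream analyses of predicted vs chronological age."""

    residuals: pd.Series  # residuals from the reference regression
    reference_fit: dict  # intercept, slope of predicted ~ age on reference
    group_contrast: float  # disease-group offset in years (age-adjusted)
    group_contrast_p: float
    covariate_table: pd.DataFrame  # standardized beta and p per covariate
    piecewise: dict = field(default_factory=dict)  # break, coefficients


def residual_age_analysis(
    predicted: pd.Series,
    cohort,
    age_ceiling: Optional[float] = 30.0,
    reference_groups: Sequence[str] = ("CTR", "REL"),
    disease_group: str = "T1D",
    covariates: Optional[Sequence[str]] = None,
    covariate_scope: str = "disease",
    response: str = "residual",
    piecewise_break: float = 30.0,
) -> ResidualAgeResult:
    """Quantify accelerated immune aging and its covariate associations.

    Within subjects under ``age_ceiling`` (where the age model is
    informative; None disables the restriction): (i) predicted age is
    regressed on chronological age over the reference groups and residuals
    computed for everyone; (ii) the disease-group contrast in years comes
    from a regression of predicted age on age plus a disease indicator;
    (iii) a multivariable regression of the residual (or predicted age, per
    ``response``) on z-scored continuous covariates yields standardized
    coefficients with p-values, fit within the disease group by default
    (``covariate_scope='all'`` uses every subject). A piecewise linear fit
    of predicted on chronological age with a fixed break is returned as a
    diagnostic over the full age range.
    """
    pred = predicted
    age = cohort.age
    group = cohort.group
    keep = np.ones(len(pred), dtype=bool)
    if age_ceiling is not None:
        keep &= (age < age_ceiling).to_numpy()

    ref_mask = keep & group.isin(reference_groups).to_numpy()
    dis_mask = keep & (group == disease_group).to_numpy()
    if ref_mask.sum() < 3:
        raise ValueError("too few reference subjects under the age ceiling")

    # (i) reference regression and residuals
    Xref = sm.add_constant(age[ref_mask].to_numpy())
    fit_ref = sm.OLS(pred[ref_mask].to_numpy(), Xref).fit()
    b0, b1 = fit_ref.params
    residuals = pred[keep] - (b0 + b1 * age[keep])
    residuals.name = "residual_age"

    # (ii) age-adjusted disease-group contrast
    both = ref_mask | dis_mask
    Xc = sm.add_constant(
        np.column_stack([age[both].to_numpy(), dis_mask[both].astype(float)])
    )
    fit_c = sm.OLS(pred[both].to_numpy(), Xc).fit()
    contrast, contrast_p = float(fit_c.params[2]), float(fit_c.pvalues[2])

    # (iii) standardized multivariable covariate model
    if covariates is None:
        covariates = [c for c in cohort.covariates.columns]
    scope = dis_mask if covariate_scope == "disease" else keep
    cov = cohort.covariates.loc[scope, list(covariates)].copy()
    resp = residuals.loc[cohort.age.index[scope]] if response == "residual" else pred[scope]
    cols, dropped = [], []
    for c in cov.columns:
        v = cov[c].to_numpy(dtype=float)
        sd = np.std(v, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            dropped.append(c)
            continue
        if set(np.unique(v)) <= {0.0, 1.0}:
            cols.append((c, v))  # binary covariates enter unscaled
        else:
            cols.append((c, (v - v.mean()) / sd))
    if dropped:
        logger.warning("dropping zero-variance covariate(s): %s", dropped)
    if cols:
        Xm = sm.add_constant(np.column_stack([v for _, v in cols]))
        fit_m = sm.OLS(resp.to_numpy(dtype=float), Xm).fit()
        cov_table = pd.DataFrame(
            {
                "beta_std": fit_m.params[1:],
                "p": fit_m.pvalues[1:],
            },
            index=pd.Index([c for c, _ in cols], name="covariate"),
        )
    else:
        cov_table = pd.DataFrame(columns=["beta_std", "p"])

    # (iv) piecewise fit over the full age range
    a_all = age.to_numpy()
    hinge = np.maximum(a_all - piecewise_break, 0.0)
    Xp = sm.add_constant(np.column_stack([a_all, hinge]))
    fit_p = sm.OLS(pred.to_numpy(), Xp).fit()
    piecewise = {
        "break": piecewise_break,
        "intercept": float(fit_p.params[0]),
        "slope_below": float(fit_p.params[1]),
        "slope_change": float(fit_p.params[2]),
    }

    return ResidualAgeResult(
        residuals=residuals,
        reference_fit={"intercept": float(b0), "slope": float(b1)},
        group_contrast=contrast,
        group_contrast_p=contrast_p,
        covariate_table=cov_table,
        piecewise=piecewise,
    )
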