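"""Age-corrected cross-group testing and the age-vs-disease feature partition.

Per feature, a Kruskal-Wallis test across the clinical groups is followed by
post hoc Dunn pairwise comparisons (rank-based z statistics with tie
correction) and a Benjamini-Hochberg adjustment; by default the BH family is
global over all features x requested pairs (the more conservative choice;
``bh_family='per-pair'`` adjusts each pair across features separately).
Combining the disease flags with a Spearman age screen partitions features
into age-only / disease-only / both / neither.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "FeaturePartition",
    "kruskal_dunn",
    "partition_features",
]


@dataclass
class ComparisonResult:
    """Kruskal-Wallis + Dunn results.

    kruskal
        Per-feature H statistic and raw/BH-adjusted p.
    dunn
        One row per (feature, pair): Dunn z, raw p, BH-adjusted p.
    effects
        Per-feature direction (sign of median difference) and effect size
        (difference in mean quantile) for the primary contrast.
    """

    kruskal: pd.DataFrame
    dunn: pd.DataFrame
    effects: pd.DataFrame
    bh_family: str = "global"


def _dunn_z(ranks: np.ndarray, groups: np.ndarray, pair, tie_term: float) -> float:
    a, b = pair
    ra = ranks[groups == a]
    rb = ranks[groups == b]
    n = len(ranks)
    var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / len(ra) + 1.0 / len(rb))
    return float((ra.mean() - rb.mean()) / np.sqrt(var))


def kruskal_dunn(
    quantiles: pd.DataFrame,
    groups: pd.Series,
    comparisons: Optional[Sequence[tuple]] = None,
    bh_family: str = "global",
    effect_pair: tuple = ("T1D", "CTR"),
) -> ComparisonResult:
    """Kruskal-Wallis across groups plus Dunn post hoc tests per feature.

    ``quantiles`` is a subjects x features table (age-corrected centiles or
    any values; the tests are rank based). Groups with fewer than 2 members
    are excluded with a warning. Midranks handle ties in both H and the
    Dunn variance term.
    """
    if bh_family not in ("global", "per-pair"):
        raise ValueError("bh_family must be 'global' or 'per-pair'")
    g = np.asarray(groups)
    counts = pd.Series(g).value_counts()
    usable = [lab for lab in counts.index if counts[lab] >= 2]
    skipped = [lab for lab in counts.index if counts[lab] < 2]
    if skipped:
        logger.warning("excluding group(s) with < 2 members: %s", skipped)
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    if comparisons is None:
        # later groups in the risk ordering (CTR < REL < RSK < T1D) come
        # first in each pair, so "T1D vs CTR" reads disease-vs-reference
        canon = [g for g in ("CTR", "REL", "RSK", "T1D") if g in usable]
        canon += sorted(set(usable) - set(canon))
        comparisons = [(b, a) for a, b in combinations(canon, 2)]

    kw_rows, dunn_rows, eff_rows = [], [], []
    for feat in quantiles.columns:
        col = quantiles[feat].to_numpy(dtype=float)
        ok = np.isfinite(col) & pd.Series(g).isin(usable).to_numpy()
        vals, labs = col[ok], g[ok]
        samples = [vals[labs == lab] for lab in usable]
        H, p_kw = stats.kruskal(*samples)
        kw_rows.append({"feature": feat, "H": float(H), "p": float(p_kw)})

        ranks = stats.rankdata(vals)
        _, tie_counts = np.unique(vals, return_counts=True)
        n = len(vals)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
        for pair in comparisons:
            if pair[0] not in labs or pair[1] not in labs:
                continue
            z = _dunn_z(ranks, labs, pair, tie_term)
            dunn_rows.append(
                {
                    "feature": feat,
                    "pair": f"{pair[0]} vs {pair[1]}",
                    "z": z,
                    "p": float(2.0 * stats.norm.sf(abs(z))),
                }
            )
        a, b = effect_pair
        if a in labs and b in labs:
            eff_rows.append(
                {
                    "feature": feat,
                    "direction": float(
                        np.sign(np.median(vals[labs == a]) - np.median(vals[labs == b]))
                    ),
                    "effect_size": float(np.mean(vals[labs == a]) - np.mean(vals[labs == b])),
                }
            )

    kw = pd.DataFrame(kw_rows).set_index("feature")
    kw["p_adj"] = multipletests(kw["p"].to_numpy(), method="fdr_bh")[1]
    dunn = pd.DataFrame(dunn_rows)
    if bh_family == "global":
        dunn["p_adj"] = multipletests(dunn["p"].to_numpy(), method="fdr_bh")[1]
    else:
        dunn["p_adj"] = np.nan
        for pair_name, idx in dunn.groupby("pair").groups.items():
            dunn.loc[idx, "p_adj"] = multipletests(
                dunn.loc[idx, "p"].to_numpy(), method="fdr_bh"
            )[1]
    effects = (
        pd.DataFrame(eff_rows).set_index("feature")
        if eff_rows
        else pd.DataFrame(columns=["direction", "effect_size"])
    )
    return ComparisonResult(kruskal=kw, dunn=dunn, effects=effects, bh_family=bh_family)


@dataclass
class FeaturePartition:
    """Age-only / disease-only / both / neither feature partition."""

    table: pd.DataFrame  # age_flag, disease_flag, label, age_effect, disease_effect

    @property
    def counts(self) -> dict:
        c = self.table["label"].value_counts()
        return {
            lab: int(c.get(lab, 0)) for lab in ("age-only", "disease-only", "both", "neither")
        }


def partition_features(
    age_screen: pd.DataFrame,
    comparison: ComparisonResult,
    age_fdr: float = 0.05,
    disease_alpha: float = 0.05,
    pair: tuple = ("T1D", "CTR"),
) -> FeaturePartition:
    """Label each feature by its age and disease associations.

    A feature is age-associated when its Spearman age screen passes BH FDR
    < ``age_fdr``, and disease-associated when its adjusted Dunn p for the
    requested pair is < ``disease_alpha``. Labels are mutually exclusive and
    exhaustive. Signed effect magnitudes for both axes (Spearman rho; mean
    quantile difference) are carried along.
    """
    pair_name = f"{pair[0]} vs {pair[1]}"
    dunn_pair = comparison.dunn[comparison.dunn["pair"] == pair_name].set_index("feature")
    feats = list(age_screen.index)
    missing = set(feats) ^ set(dunn_pair.index)
    if missing:
        raise ValueError(f"feature(s) missing from one input: {sorted(missing)}")

    screen = age_screen.copy()
    ok = screen["p"].notna()
    screen["p_adj"] = np.nan
    screen.loc[ok, "p_adj"] = multipletests(screen.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]

    rows = []
    for feat in feats:
        age_flag = bool(screen.loc[feat, "p_adj"] < age_fdr) if ok[feat] else False
        disease_flag = bool(dunn_pair.loc[feat, "p_adj"] < disease_alpha)
        label = {
            (True, False): "age-only",
            (False, True): "disease-only",
            (True, True): "both",
            (False, False): "neither",
        }[(age_flag, disease_flag)]
        rows.append(
            {
                "feature": feat,
                "age_flag": age_flag,
                "disease_flag": disease_flag,
                "label": label,
                "age_effect": float(screen.loc[feat, "rho"]),
                "disease_effect": float(
                    comparison.effects.loc[feat, "effect_size"]
                    if feat in comparison.effects.index
                    else np.nan
                ),
            }
        )
    return FeaturePartition(table=pd.DataFrame(rows).set_index("feature"))
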