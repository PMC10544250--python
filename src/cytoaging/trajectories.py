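"""Per-feature age trajectories: smoothing-spline fits, shape clustering,
and cohort-vs-cohort trajectory comparison.

Each preprocessed feature is fit against age with a cubic smoothing spline
at 3 effective degrees of freedom and evaluated on a fixed grid over ages
5-75. Trajectory shape vectors are clustered by complete-linkage
hierarchical clustering under the Canberra distance and cut into four
clusters; cluster numbering is deterministic (descending mean initial
trend). A disease cohort's trajectories are compared to the reference
cohort's via per-feature shifts (grid-mean difference) and per-cluster
one-sample t tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from ._splines import SmoothingSpline
from .cohort import CohortTable
from .preprocess import fit_transform

__all__ = [
    "DEFAULT_GRID",
    "Trajectory",
    "TrajectoryClustering",
    "TrajectoryComparison",
    "fit_trajectory",
    "fit_cohort_trajectories",
    "trajectory_matrix",
    "cluster_trajectories",
    "compare_trajectories",
    "initial_trend",
    "count_crossings",
    "spearman_age_screen",
]

#: Standard evaluation grid: ages 5-75 inclusive at 0.5-year steps.
DEFAULT_GRID = np.round(np.arange(5.0, 75.0 + 1e-9, 0.5), 3)


@dataclass
class Trajectory:
    """A smoothed feature trajectory on the standard age grid."""

    feature: str
    grid: np.ndarray
    values: np.ndarray
    edf: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trajectory {self.feature}: non-finite smoothed values")


def fit_trajectory(
    ages: np.ndarray,
    values: np.ndarray,
    df: float = 3.0,
    grid: np.ndarray = DEFAULT_GRID,
    feature: str = "",
) -> Trajectory:
    """Fit a cubic smoothing spline with ~``df`` effective degrees of freedom.

    ``values`` are expected on the preprocessed (standardized) scale. Grid
    points outside the observed age range take the boundary value rather
    than extrapolating.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(ages) & np.isfinite(values)
    spline = SmoothingSpline(df=df).fit(ages[ok], values[ok])
    return Trajectory(feature=feature, grid=np.asarray(grid, float),
                      values=spline.predict(grid), edf=spline.edf_)


def fit_cohort_trajectories(
    cohort: CohortTable,
    groups: Sequence[str] = ("CTR", "REL"),
    df: float = 3.0,
    grid: np.ndarray = DEFAULT_GRID,
    preprocessed: Optional[pd.DataFrame] = None,
) -> dict:
    """Preprocess (impute -> log-shift -> z-scale) and fit every feature.

    ``preprocessed`` bypasses the internal preprocessing, so a disease
    cohort can be transformed with the reference cohort's TransformSpec
    before fitting.
    """
    mask = cohort.group.isin(groups).to_numpy()
    sub = cohort.subset(mask)
    if preprocessed is None:
        domains = sub.feature_meta["domain"].to_dict()
        data, _ = fit_transform(sub.values, domains=domains, log=True)
    else:
        data = preprocessed.loc[sub.values.index]
    ages = sub.age.to_numpy()
    return {
        feat: fit_trajectory(ages, data[feat].to_numpy(), df=df, grid=grid, feature=feat)
        for feat in data.columns
    }


def trajectory_matrix(trajectories: Mapping[str, Trajectory]) -> pd.DataFrame:
    """Features x grid matrix of smoothed values."""
    feats = list(trajectories)
    grid = trajectories[feats[0]].grid
    mat = np.vstack([trajectories[f].values for f in feats])
    return pd.DataFrame(mat, index=pd.Index(feats, name="feature"), columns=grid)


@dataclass
class TrajectoryClustering:
    labels: pd.Series  # feature -> cluster in {1..k}
    linkage_matrix: np.ndarray = field(repr=False)
    metric: str = "canberra"
    method: str = "complete"

    @property
    def members(self) -> dict:
        return {int(c): list(self.labels.index[self.labels == c])
                for c in sorted(self.labels.unique())}


def cluster_trajectories(
    trajectories: Mapping[str, Trajectory], n_clusters: int = 4
) -> TrajectoryClustering:
    """Complete-linkage clustering of trajectory vectors under Canberra distance.

    The tree is cut into ``n_clusters`` groups and labels are renumbered by
    descending mean initial trend of the member trajectories, so numbering
    does not depend on dendrogram orientation or feature order.
    """
    mat = trajectory_matrix(trajectories)
    if not np.all(np.isfinite(mat.to_numpy())):
        raise ValueError("non-finite trajectory values")
    dists = pdist(mat.to_numpy(), metric="canberra")
    Z = linkage(dists, method="complete")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    trends = np.array([initial_trend(trajectories[f]) for f in mat.index])
    order = sorted(
        np.unique(raw), key=lambda c: -float(np.mean(trends[raw == c]))
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=mat.index, name="cluster")
    return TrajectoryClustering(labels=labels, linkage_matrix=Z)


def initial_trend(trajectory: Trajectory, age_window: tuple = (5.0, 15.0)) -> float:
    """Mean of successive trajectory differences over the early-age window.

    Positive values indicate an initially increasing trajectory, negative an
    initially decreasing one.
    """
    g = trajectory.grid
    sel = (g >= age_window[0]) & (g <= age_window[1])
    vals = trajectory.values[sel]
    if vals.size < 2:
        raise ValueError("grid does not cover the initial-trend age window")
    return float(np.mean(np.diff(vals)))


def count_crossings(traj_a: Trajectory, traj_b: Trajectory) -> int:
    """Number of strict sign changes of (A - B) along the shared grid.

    Exact zeros are collapsed: a touch without a sign change is not a
    crossing.
    """
    if not np.array_equal(traj_a.grid, traj_b.grid):
        raise ValueError("trajectories must share the same grid")
    diff = traj_a.values - traj_b.values
    signs = np.sign(diff)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.sum(signs[1:] != signs[:-1]))


@dataclass
class TrajectoryComparison:
    """Per-feature and per-cluster shifts of cohort B relative to cohort A."""

    features: pd.DataFrame  # shift, trend_a, trend_b, crossings, sampling_variation
    clusters: pd.DataFrame  # n, mean_shift, t, p


def compare_trajectories(
    fits_a: Mapping[str, Trajectory],
    fits_b: Mapping[str, Trajectory],
    clustering: TrajectoryClustering,
    sampling_variation_threshold: int = 2,
) -> TrajectoryComparison:
    """Compare cohort B trajectories against cohort A using A's clustering.

    Per feature: shift = grid mean of (B - A), initial trend signs in both
    cohorts, and the crossing count of the two trajectories; features whose
    initial trends differ but whose trajectories cross at least
    ``sampling_variation_threshold`` times are flagged as sampling
    variation. Per cluster: two-sided one-sample t test of member shifts
    against 0 (p reported missing when a cluster has < 2 members).
    """
    rows = []
    for feat, label in clustering.labels.items():
        a, b = fits_a[feat], fits_b[feat]
        if not np.array_equal(a.grid, b.grid):
            raise ValueError(f"feature {feat}: mismatched grids")
        shift = float(np.mean(b.values - a.values))
        ta, tb = initial_trend(a), initial_trend(b)
        crossings = count_crossings(a, b)
        rows.append(
            {
                "feature": feat,
                "cluster": int(label),
                "shift": shift,
                "trend_a": ta,
                "trend_b": tb,
                "same_initial_direction": bool(np.sign(ta) == np.sign(tb)),
                "crossings": crossings,
                "sampling_variation": bool(
                    np.sign(ta) != np.sign(tb)
                    and crossings >= sampling_variation_threshold
                ),
            }
        )
    feats = pd.DataFrame(rows).set_index("feature")
    crows = []
    for c, members in clustering.members.items():
        shifts = feats.loc[members, "shift"].to_numpy()
        if shifts.size >= 2:
            t, p = stats.ttest_1samp(shifts, 0.0)
        else:
            t, p = np.nan, np.nan
        crows.append(
            {"cluster": c, "n": shifts.size, "mean_shift": float(np.mean(shifts)),
             "t": float(t), "p": float(p)}
        )
    return TrajectoryComparison(features=feats, clusters=pd.DataFrame(crows).set_index("cluster"))


def spearman_age_screen(
    cohort: CohortTable, groups: Sequence[str] = ("CTR", "REL")
) -> pd.DataFrame:
    """Spearman correlation of each feature with age on the reference groups.

    Returns a DataFrame (feature, rho, p, n); constant features get NaN rho.
    Midranks handle ties, so the result matches the textbook rank formula
    with tie correction.
    """
    mask = cohort.group.isin(groups).to_numpy()
    sub = cohort.subset(mask)
    ages = sub.age.to_numpy()
    rows = []
    for feat in sub.values.columns:
        col = sub.values[feat].to_numpy(dtype=float)
        ok = np.isfinite(col)
        n = int(ok.sum())
        if n < 3 or np.unique(col[ok]).size < 2:
            rows.append({"feature": feat, "rho": np.nan, "p": np.nan, "n": n})
            continue
        rho, p = stats.spearmanr(ages[ok], col[ok])
        rows.append({"feature": feat, "rho": float(rho), "p": float(p), "n": n})
    return pd.DataFrame(rows).set_index("feature")
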