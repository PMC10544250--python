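"""Synthetic immunophenotyping cohort generator.

Emulates the statistical structure of a cross-sectional flow-cytometry + CBC
cohort spanning childhood to old age: a bimodal age distribution (pediatric
probands plus adult relatives), ~190 features whose population means follow
one of four age-trajectory shapes (increasing linear, upward parabolic,
decreasing linear, stable), right-skewed expression-intensity features,
percentage features bounded in [0, 100], sparse missing-completely-at-random
entries, and group-dependent disease effects for the type 1 diabetes (T1D)
arm expressed either as per-cluster mean shifts or as an effective
aging acceleration in years.

Groups follow the study design of T1D risk cohorts: unaffected controls
(CTR), unaffected first-degree relatives (REL), multiple-autoantibody-
positive at-risk participants (RSK), and diagnosed T1D.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "GROUPS",
    "CLUSTER_SHAPES",
    "CohortConfig",
    "CohortConfigError",
    "CohortTable",
    "generate_cohort",
    "generate_null_cohort",
]

GROUPS = ("CTR", "REL", "RSK", "T1D")

#: Continuous covariates carried per subject (plus binary ``sex``).
COVARIATES = ("sex", "bmi_percentile", "hba1c", "blood_glucose", "duration", "grs")


class CohortConfigError(ValueError):
    """Raised when a CohortConfig field is invalid; names the field."""


# ---------------------------------------------------------------------------
# trajectory shape archetypes
# ---------------------------------------------------------------------------
# Shapes are defined on age scaled to u in [0, 1] and standardized to mean 0,
# variance 1 under u ~ Uniform(0, 1), so a feature's amplitude is its
# standardized age effect.


def _shape_linear_up(u):
    return (u - 0.5) / np.sqrt(1.0 / 12.0)


_PARABOLA_VERTEX = 0.38  # scaled age of the dip (~age 33 on the default range)


def _shape_parabola(u, c=_PARABOLA_VERTEX):
    # upward (U-shaped) parabola dipping in adulthood; moments of (U-c)^2
    # under U ~ Uniform(0, 1) give the exact standardization
    m2 = 1.0 / 3.0 - c + c * c
    m4 = ((1.0 - c) ** 5 + c**5) / 5.0
    return ((u - c) ** 2 - m2) / np.sqrt(m4 - m2 * m2)


def _shape_linear_down(u):
    return -_shape_linear_up(u)


def _shape_stable(u):
    return np.zeros_like(u)


CLUSTER_SHAPES = {
    1: _shape_linear_up,
    2: _shape_parabola,
    3: _shape_linear_down,
    4: _shape_stable,
}


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters; defaults emulate the study cohort.

    n_per_group
        Subjects per clinical group. Defaults follow the study design
        (252 CTR, 310 REL, 24 RSK, 240 T1D; n = 826 total).
    age_components
        (mean yr, sd yr, weight) normal mixture components for the bimodal
        age draw, truncated to ``age_range``.
    n_features_per_cluster
        Feature counts for the four trajectory shapes (increasing linear,
        upward parabolic, decreasing linear, stable); defaults follow the
        observed 66/20/74/12 split of flow phenotypes.
    amplitude_range
        Per-feature standardized age-effect amplitudes drawn uniformly.
    noise_sd
        Residual SD on the standardized latent scale.
    skew_fraction
        Fraction of features generated as right-skewed intensity readouts
        (log-normal latent mapping).
    stable_drift
        Amplitude of the weak common upward drift given to "stable"
        (cluster 4) features, emulating the slight compositional drift of
        innate subsets as adaptive naive compartments contract with age;
        their age effect stays an order of magnitude below the
        age-associated clusters. 0 makes them pure noise.
    disease_shift
        Per-cluster standardized mean offset applied to T1D subjects. The
        default places a disease-specific shift on the stable cluster only:
        shifts of the age-associated clusters already arise from
        ``aging_acceleration_years``, and doubling them would overstate the
        disease effect.
    aging_acceleration_years
        Extra effective age (years) applied to T1D subjects' age-dependent
        features.
    covariate_acceleration
        Optional mapping covariate -> extra effective-age years per SD of
        that covariate, applied within T1D.
    shared_factor_sd
        SD of an optional shared per-subject latent factor inducing
        cross-feature correlation (0 disables it).
    missing_rate
        MCAR missingness fraction; must stay below the 0.0503 per-feature
        ceiling observed in the study.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"CTR": 252, "REL": 310, "RSK": 24, "T1D": 240}
    )
    age_components: Sequence[tuple] = ((12.0, 4.0, 0.5), (42.0, 12.0, 0.5))
    age_range: tuple = (2.0, 83.0)
    n_features_per_cluster: Sequence[int] = (66, 20, 74, 12)
    amplitude_range: tuple = (0.2, 1.3)
    noise_sd: float = 1.0
    skew_fraction: float = 0.25
    percent_fraction: float = 0.85
    stable_drift: float = 0.08
    disease_shift: Sequence[float] = (0.0, 0.0, 0.0, 0.3)
    aging_acceleration_years: float = 3.0
    covariate_acceleration: Mapping[str, float] = field(default_factory=dict)
    shared_factor_sd: float = 0.0
    missing_rate: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        for g in self.n_per_group:
            if g not in GROUPS:
                raise CohortConfigError(f"n_per_group: unknown group {g!r}")
        if any(int(v) < 0 for v in self.n_per_group.values()):
            raise CohortConfigError("n_per_group: counts must be >= 0")
        comps = list(self.age_components)
        if not comps:
            raise CohortConfigError("age_components: at least one component required")
        w = np.array([c[2] for c in comps], dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise CohortConfigError("age_components: mixture weights must sum to 1")
        if any(c[1] <= 0 for c in comps):
            raise CohortConfigError("age_components: sds must be > 0")
        lo, hi = self.age_range
        if not (2.0 <= lo < hi <= 83.0):
            raise CohortConfigError("age_range: must satisfy 2 <= lo < hi <= 83")
        if len(self.n_features_per_cluster) != 4:
            raise CohortConfigError("n_features_per_cluster: need counts for 4 clusters")
        if any(int(v) < 0 for v in self.n_features_per_cluster):
            raise CohortConfigError("n_features_per_cluster: counts must be >= 0")
        a0, a1 = self.amplitude_range
        if not (0 <= a0 <= a1):
            raise CohortConfigError("amplitude_range: need 0 <= lo <= hi")
        if self.noise_sd < 0:
            raise CohortConfigError("noise_sd: must be >= 0")
        if self.stable_drift < 0:
            raise CohortConfigError("stable_drift: must be >= 0")
        for name, val in (
            ("skew_fraction", self.skew_fraction),
            ("percent_fraction", self.percent_fraction),
        ):
            if not (0.0 <= val <= 1.0):
                raise CohortConfigError(f"{name}: must be in [0, 1]")
        if len(self.disease_shift) != 4:
            raise CohortConfigError("disease_shift: need one offset per cluster")
        for k in self.covariate_acceleration:
            if k not in COVARIATES:
                raise CohortConfigError(f"covariate_acceleration: unknown covariate {k!r}")
        if self.shared_factor_sd < 0:
            raise CohortConfigError("shared_factor_sd: must be >= 0")
        if not (0.0 <= self.missing_rate < 0.0503):
            raise CohortConfigError("missing_rate: must be in [0, 0.0503)")


@dataclass
class CohortTable:
    """Subjects x features matrix with per-subject and per-feature metadata.

    values
        DataFrame (subjects x features); NaN marks missing entries.
    age
        Age in years per subject.
    group
        Clinical group per subject, one of CTR/REL/RSK/T1D.
    covariates
        Per-subject covariates (sex 0/1, BMI percentile, HbA1c, rested blood
        glucose, disease duration, genetic risk score).
    feature_meta
        Per-feature metadata: value ``domain`` (percent/intensity/count) and,
        for synthetic cohorts, the true ``cluster`` label, ``amplitude``
        and ``skewed`` flag.
    """

    values: pd.DataFrame
    age: pd.Series
    group: pd.Series
    covariates: pd.DataFrame
    feature_meta: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def features(self) -> pd.Index:
        return self.values.columns

    def subset(self, mask) -> "CohortTable":
        """Row subset by boolean mask or index array."""
        mask = np.asarray(mask)
        return CohortTable(
            values=self.values.loc[mask] if mask.dtype == bool else self.values.iloc[mask],
            age=self.age.loc[mask] if mask.dtype == bool else self.age.iloc[mask],
            group=self.group.loc[mask] if mask.dtype == bool else self.group.iloc[mask],
            covariates=(
                self.covariates.loc[mask] if mask.dtype == bool else self.covariates.iloc[mask]
            ),
            feature_meta=self.feature_meta,
        )

    def validate(self) -> None:
        meta = self.feature_meta
        for fid in self.features:
            dom = meta.loc[fid, "domain"]
            col = self.values[fid].dropna()
            if dom == "percent" and ((col < 0).any() or (col > 100).any()):
                raise ValueError(f"feature {fid}: percent values outside [0, 100]")
            if dom in ("intensity", "count") and (col <= 0).any():
                raise ValueError(f"feature {fid}: non-positive {dom} values")
        if not self.group.isin(GROUPS).all():
            raise ValueError("group labels outside CTR/REL/RSK/T1D")

    def to_csv(self, out_dir) -> None:
        """Write tidy cohort CSV (one row per subject) plus feature metadata."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tidy = pd.concat(
            [self.age.rename("age"), self.group.rename("group"), self.covariates, self.values],
            axis=1,
        )
        tidy.index.name = "subject_id"
        tidy.to_csv(out / "cohort.csv")
        self.feature_meta.to_csv(out / "features.csv")

    @classmethod
    def from_csv(cls, out_dir) -> "CohortTable":
        out = Path(out_dir)
        tidy = pd.read_csv(out / "cohort.csv", index_col="subject_id")
        meta = pd.read_csv(out / "features.csv", index_col=0)
        cov_cols = [c for c in COVARIATES if c in tidy.columns]
        feat_cols = [c for c in tidy.columns if c not in ("age", "group", *cov_cols)]
        values = tidy[feat_cols]
        values.columns.name = "feature"
        return cls(
            values=values,
            age=tidy["age"],
            group=tidy["group"],
            covariates=tidy[cov_cols],
            feature_meta=meta,
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_ages(rng: np.random.Generator, n: int, config: CohortConfig) -> np.ndarray:
    comps = list(config.age_components)
    w = np.array([c[2] for c in comps], dtype=float)
    lo, hi = config.age_range
    ages = np.empty(n)
    which = rng.choice(len(comps), size=n, p=w / w.sum())
    for i, k in enumerate(which):
        mean, sd, _ = comps[k]
        a = rng.normal(mean, sd)
        while not (lo <= a <= hi):  # truncated draw
            a = rng.normal(mean, sd)
        ages[i] = a
    return ages


def _draw_covariates(
    rng: np.random.Generator, group: np.ndarray, age: np.ndarray
) -> pd.DataFrame:
    n = len(group)
    t1d = group == "T1D"
    rsk = group == "RSK"
    rel = group == "REL"
    cov = pd.DataFrame(index=pd.RangeIndex(n))
    cov["sex"] = rng.integers(0, 2, size=n)
    cov["bmi_percentile"] = 100.0 * rng.beta(2.0, 2.0, size=n)
    hba1c = rng.normal(5.3, 0.35, size=n)
    hba1c[t1d] = rng.normal(7.9, 1.4, size=t1d.sum())
    cov["hba1c"] = np.clip(hba1c, 3.5, None)
    glu = rng.normal(95.0, 12.0, size=n)
    glu[t1d] = rng.normal(180.0, 55.0, size=t1d.sum())
    cov["blood_glucose"] = np.clip(glu, 40.0, None)
    dur = np.zeros(n)
    dur[t1d] = np.minimum(rng.exponential(6.0, size=t1d.sum()), np.maximum(age[t1d] - 0.5, 0.0))
    cov["duration"] = dur
    grs = rng.normal(0.0, 1.0, size=n)
    grs += 1.2 * t1d + 1.0 * rsk + 0.4 * rel
    cov["grs"] = grs
    return cov


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Generate a synthetic cohort with the configured structure.

    Deterministic given ``config.seed``: all draws flow from a single
    ``numpy`` generator. Each feature's noiseless mean over age follows its
    assigned cluster shape; T1D subjects receive the per-cluster latent shift
    and/or effective-age acceleration; skew-flagged features are produced on
    a log-normal latent scale; a MCAR mask is applied at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = []
    for g in GROUPS:
        groups.extend([g] * int(config.n_per_group.get(g, 0)))
    group = np.array(groups, dtype=object)
    n = len(group)
    if n == 0:
        raise CohortConfigError("n_per_group: no subjects requested")

    age = _draw_ages(rng, n, config)
    cov = _draw_covariates(rng, group, age)

    # ---- feature metadata ------------------------------------------------
    clusters = np.concatenate(
        [np.full(int(k), c) for c, k in zip((1, 2, 3, 4), config.n_features_per_cluster)]
    ).astype(int)
    p = len(clusters)
    if p == 0:
        raise CohortConfigError("n_features_per_cluster: no features requested")
    names = [f"ph{j + 1:03d}_c{clusters[j]}" for j in range(p)]
    amp = rng.uniform(*config.amplitude_range, size=p)
    # stable features: weak common drift instead of a full-size age effect
    amp[clusters == 4] = config.stable_drift
    skewed = rng.random(p) < config.skew_fraction
    domain = np.where(
        skewed, "intensity", np.where(rng.random(p) < config.percent_fraction, "percent", "count")
    )
    # per-feature location/scale constants for the domain mapping
    logit_base = rng.normal(0.0, 1.2, size=p)
    mfi_scale = np.exp(rng.normal(3.0, 1.0, size=p))
    count_base = np.exp(rng.normal(2.0, 0.8, size=p))
    factor_loading = rng.normal(0.0, 1.0, size=p)

    # ---- effective age ---------------------------------------------------
    t1d = group == "T1D"
    eff_age = age.copy()
    eff_age[t1d] += config.aging_acceleration_years
    for cov_name, per_sd in config.covariate_acceleration.items():
        z = (cov[cov_name] - cov[cov_name].mean()) / cov[cov_name].std(ddof=1)
        eff_age[t1d] += per_sd * z.to_numpy()[t1d]

    lo, hi = config.age_range
    u = (eff_age - lo) / (hi - lo)

    # ---- latent matrix ---------------------------------------------------
    latent = np.empty((n, p))
    shift = np.asarray(config.disease_shift, dtype=float)
    shared = (
        rng.normal(0.0, config.shared_factor_sd, size=n)
        if config.shared_factor_sd > 0
        else None
    )
    # disease_shift is stated on the standardized (z-scored) feature scale;
    # scaling by the total latent SD makes it land there after preprocessing
    total_sd = np.sqrt(
        amp**2
        + config.noise_sd**2
        + (config.shared_factor_sd * factor_loading) ** 2
    )
    for j in range(p):
        # cluster 4 drifts weakly in the common (upward) direction;
        # amp is stable_drift there, so stable_drift=0 recovers a flat mean
        cshape = _shape_linear_up if clusters[j] == 4 else CLUSTER_SHAPES[clusters[j]]
        mean_j = amp[j] * cshape(u)
        mean_j = mean_j + shift[clusters[j] - 1] * total_sd[j] * t1d
        latent[:, j] = mean_j
        if shared is not None:
            latent[:, j] += factor_loading[j] * shared
    latent += rng.normal(0.0, config.noise_sd, size=(n, p)) if config.noise_sd > 0 else 0.0

    # ---- map latent to the declared value domain -------------------------
    values = np.empty((n, p))
    for j in range(p):
        if domain[j] == "intensity":
            values[:, j] = mfi_scale[j] * np.exp(0.5 * latent[:, j])
        elif domain[j] == "percent":
            # mild squash: bounded in [0, 100] without atoms, near-linear so
            # the conditional law stays close to its latent (Gaussian) shape
            values[:, j] = 100.0 * expit(logit_base[j] + 0.25 * latent[:, j])
        else:  # count
            values[:, j] = count_base[j] * (1.0 + latent[:, j] / 10.0)
            values[:, j] = np.maximum(values[:, j], count_base[j] * 1e-3)

    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        values[mask] = np.nan

    idx = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="subject_id")
    # map_base records the domain-mapping constant (logit base for percent,
    # intensity scale, count base), making the true conditional law of every
    # feature recoverable for oracle checks
    map_base = np.where(
        domain == "percent", logit_base, np.where(domain == "intensity", mfi_scale, count_base)
    )
    meta = pd.DataFrame(
        {
            "domain": domain,
            "cluster": clusters,
            "amplitude": amp,
            "skewed": skewed,
            "map_base": map_base,
        },
        index=pd.Index(names, name="feature"),
    )
    table = CohortTable(
        values=pd.DataFrame(values, index=idx, columns=meta.index),
        age=pd.Series(age, index=idx, name="age"),
        group=pd.Series(group, index=idx, name="group"),
        covariates=cov.set_index(idx),
        feature_meta=meta,
    )
    table.validate()
    return table


def generate_null_cohort(config: CohortConfig) -> CohortTable:
    """As :func:`generate_cohort` but with every disease effect forced to 0.

    Group labels remain, making the cohort exchangeable across groups; used
    for type-I-error and centile-calibration checks.
    """
    null_config = dataclasses.replace(
        config,
        disease_shift=(0.0, 0.0, 0.0, 0.0),
        aging_acceleration_years=0.0,
        covariate_acceleration={},
    )
    return generate_cohort(null_config)
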