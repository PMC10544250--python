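"""Imputation, log transformation, and scaling applied before modeling.

The trajectory pipeline applies, in order: per-feature median imputation,
a shifted log transform (constant 1, enlarged when values can fall below 0
so the argument of the log stays >= 1), and per-feature z-scaling. The
immune-age model path uses imputation and scaling only (no log), selected by
the ``log`` switch. A fitted :class:`TransformSpec` is a pure function on new
data: applying it never refits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TransformSpec",
    "impute_median",
    "log_shift",
    "zscale",
    "fit_transform",
]


def impute_median(df: pd.DataFrame, reference_index=None) -> pd.DataFrame:
    """Median-impute each column; observed entries are left unchanged.

    The imputation value is the median of the observed entries of that
    feature, computed on ``reference_index`` rows when given (so a training
    population can define the value applied to held-out subjects).
    """
    ref = df if reference_index is None else df.loc[reference_index]
    medians = ref.median(axis=0, skipna=True)
    fully_missing = medians.index[medians.isna()]
    if len(fully_missing):
        raise ValueError(f"feature(s) fully missing, cannot impute: {list(fully_missing)}")
    return df.fillna(medians)


def log_shift(values: np.ndarray, domain: Optional[str] = None) -> tuple:
    """Shifted log transform; returns ``(log(values + shift), shift)``.

    The shift is 1 for features whose domain cannot fall below 0 (percent,
    intensity, count) or whose observed minimum is >= 0; otherwise it is
    enlarged to ``1 + (-min)`` so the smallest transformed argument is 1 and
    the log stays nonnegative.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("log_shift expects imputed (fully observed) values")
    if domain in ("percent", "intensity", "count"):
        shift = 1.0
    else:
        shift = 1.0 + max(0.0, -float(np.min(values)))
    shifted = values + shift
    if np.any(shifted <= 0):
        raise ValueError("non-positive value after shift; shift rule violated")
    return np.log(shifted), shift


def zscale(values: np.ndarray) -> tuple:
    """Standardize to mean 0, sample (n-1) SD 1; returns ``(z, mean, sd)``."""
    values = np.asarray(values, dtype=float)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("constant feature cannot be z-scaled")
    return (values - mean) / sd, mean, sd


@dataclass
class TransformSpec:
    """Fitted per-feature transform: impute -> (optional log-shift) -> z-scale.

    ``params`` maps feature id to a dict with keys ``impute``, ``shift``
    (None when the log step is off), ``mean`` and ``sd``.
    """

    log: bool
    params: Mapping[str, dict] = field(default_factory=dict)

    @classmethod
    def fit(
        cls,
        df: pd.DataFrame,
        domains: Optional[Mapping[str, str]] = None,
        log: bool = True,
        reference_index=None,
        drop_constant: bool = False,
    ) -> "TransformSpec":
        """Fit transform parameters on ``df`` (optionally on a reference subset).

        ``reference_index`` restricts the rows used to estimate the
        imputation medians and scaling moments, enabling a leak-free variant
        where parameters come from the training population only; by default
        the full table is used, matching the original analysis.
        """
        imputed = impute_median(df, reference_index=reference_index)
        ref = imputed if reference_index is None else imputed.loc[reference_index]
        medians = (df if reference_index is None else df.loc[reference_index]).median(
            axis=0, skipna=True
        )
        params = {}
        for feat in df.columns:
            col = ref[feat].to_numpy(dtype=float)
            entry = {"impute": float(medians[feat]), "shift": None}
            if log:
                dom = domains.get(feat) if domains else None
                col, shift = log_shift(col, domain=dom)
                entry["shift"] = shift
            try:
                _, mean, sd = zscale(col)
            except ValueError:
                if drop_constant:
                    continue
                raise ValueError(f"constant feature cannot be z-scaled: {feat}")
            entry["mean"], entry["sd"] = mean, sd
            params[feat] = entry
        return cls(log=log, params=params)

    @property
    def features(self):
        return list(self.params)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored transform to new data (pure; no refitting)."""
        out = {}
        for feat, par in self.params.items():
            if feat not in df.columns:
                raise KeyError(f"feature missing from input: {feat}")
            col = df[feat].to_numpy(dtype=float).copy()
            col[np.isnan(col)] = par["impute"]
            if self.log:
                col = np.log(col + par["shift"])
            out[feat] = (col - par["mean"]) / par["sd"]
        res = pd.DataFrame(out, index=df.index)
        res.columns.name = df.columns.name
        return res

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for feat, par in self.params.items():
            if feat not in df.columns:
                continue
            col = df[feat].to_numpy(dtype=float) * par["sd"] + par["mean"]
            if self.log:
                col = np.exp(col) - par["shift"]
            out[feat] = col
        res = pd.DataFrame(out, index=df.index)
        res.columns.name = df.columns.name
        return res

    def to_json(self, path=None) -> str:
        payload = json.dumps({"log": self.log, "params": self.params}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "TransformSpec":
        import os

        if isinstance(source, os.PathLike) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            with open(source) as fh:
                data = json.load(fh)
        else:
            data = json.loads(source)
        return cls(log=data["log"], params=data["params"])


def fit_transform(
    df: pd.DataFrame,
    domains: Optional[Mapping[str, str]] = None,
    log: bool = True,
    reference_index=None,
    drop_constant: bool = False,
) -> tuple:
    """Fit a :class:`TransformSpec` and apply it; returns ``(transformed, spec)``."""
    spec = TransformSpec.fit(
        df, domains=domains, log=log, reference_index=reference_index,
        drop_constant=drop_constant,
    )
    return spec.transform(df), spec
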