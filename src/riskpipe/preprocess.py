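"""Encoding, train-fitted [-1, 1] rescaling, and the first-pass feature filter.

The scaler and the filter are always *fitted on discovery (training) rows
only*; the learned parameters are then applied unchanged to external rows.
Test values falling outside [-1, 1] are preserved, never clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "ScalerParams",
    "FilterParams",
    "FilterReport",
    "one_hot",
    "fit_scaler",
    "apply_scaler",
    "first_pass_filter",
    "univariate_auc",
]


def one_hot(
    clinical: pd.DataFrame,
    categorical: list[str],
    known_levels: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One-hot encode the declared categorical columns.

    Returns the encoded table and the level dictionary learned (pass it back
    at apply time so unseen levels map to an all-zero indicator block, with a
    warning, instead of creating new columns).
    """
    out = clinical.copy()
    levels_out: dict[str, list[str]] = {}
    for col in categorical:
        if col not in out.columns:
            raise KeyError(f"declared categorical column {col!r} missing")
        series = out[col].astype(str)
        if known_levels is not None and col in known_levels:
            levels = known_levels[col]
            unseen = sorted(set(series) - set(levels))
            if unseen:
                warnings.warn(
                    f"column {col!r}: unseen level(s) {unseen} encoded as all-zero",
                    stacklevel=2,
                )
        else:
            levels = sorted(series.unique())
        levels_out[col] = list(levels)
        for lev in levels:
            out[f"{col}_{lev}"] = (series == lev).astype(int)
        out = out.drop(columns=[col])
    return out, levels_out


@dataclass
class ScalerParams:
    """Per-feature (min, max) learned from training rows."""

    min_: pd.Series
    max_: pd.Series

    @property
    def columns(self) -> list[str]:
        return list(self.min_.index)


def fit_scaler(train: pd.DataFrame) -> ScalerParams:
    """Learn per-feature min/max from the training split only."""
    return ScalerParams(train.min(axis=0), train.max(axis=0))


def apply_scaler(features: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """Map each feature by ``x' = 2 (x - min) / (max - min) - 1``.

    A constant training feature maps to 0; values outside the training range
    (possible on external data) are preserved, not clamped.
    """
    cols = params.columns
    span = (params.max_ - params.min_).replace(0, np.nan)
    scaled = 2.0 * (features[cols] - params.min_) / span - 1.0
    scaled = scaled.fillna(0.0)
    out = features.copy()
    out[cols] = scaled
    return out


def univariate_auc(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC of one feature against binary labels (ties 0.5)."""
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes required")
    ranks = rankdata(x)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


@dataclass(frozen=True)
class FilterParams:
    variance_tol: float = 1e-8
    weak_auc: float = 0.55
    redundancy_rho: float = 0.95


@dataclass
class FilterReport:
    removed: list[tuple[str, str]] = field(default_factory=list)  # (feature, reason)
    retained: list[str] = field(default_factory=list)
    params: FilterParams = field(default_factory=FilterParams)

    def removed_names(self) -> set[str]:
        return {name for name, _ in self.removed}

    def to_dict(self) -> dict:
        return {
            "removed": [{"feature": f, "reason": r} for f, r in self.removed],
            "retained": self.retained,
            "params": vars(self.params) | {},
        }


def first_pass_filter(
    train: pd.DataFrame,
    labels: np.ndarray,
    params: FilterParams = FilterParams(),
    clinical_columns: list[str] | None = None,
) -> FilterReport:
    """Remove weak, confounding and redundant features before selection.

    Three rules applied in order, on the scaled training split only:

    1. near-constant: variance below ``variance_tol``;
    2. weak: folded univariate AUC ``max(a, 1-a)`` below ``weak_auc``;
    3. redundant: pairwise Spearman ``|rho|`` above ``redundancy_rho`` — the
       member with the lower folded AUC is dropped (ties: the
       lexicographically later name).

    Clinically determined columns are exempt from all three rules.
    """
    clinical = set(clinical_columns or [])
    labels = np.asarray(labels, dtype=int)
    report = FilterReport(params=params)
    candidates = [c for c in train.columns if c not in clinical]

    # rule 1: near-constant
    variances = train[candidates].var(axis=0, ddof=0)
    near_const = [c for c in candidates if variances[c] < params.variance_tol]
    for c in near_const:
        report.removed.append((c, "near-constant"))
    candidates = [c for c in candidates if c not in set(near_const)]

    # rule 2: weak discriminators
    folded: dict[str, float] = {}
    weak = []
    for c in candidates:
        a = univariate_auc(train[c].to_numpy(), labels)
        folded[c] = max(a, 1.0 - a)
        if folded[c] < params.weak_auc:
            weak.append(c)
    for c in weak:
        report.removed.append((c, "weak"))
    candidates = [c for c in candidates if c not in set(weak)]

    # rule 3: redundancy (greedy over correlated pairs)
    if len(candidates) >= 2:
        rho = spearmanr(train[candidates].to_numpy()).statistic
        if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        dropped: set[str] = set()
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                a, b = candidates[i], candidates[j]
                if a in dropped or b in dropped:
                    continue
                if abs(rho[i, j]) > params.redundancy_rho:
                    if folded[a] > folded[b]:
                        loser = b
                    elif folded[b] > folded[a]:
                        loser = a
                    else:
                        loser = max(a, b)  # tie -> lexicographically later name
                    dropped.add(loser)
                    report.removed.append((loser, "redundant"))
        candidates = [c for c in candidates if c not in dropped]

    report.retained = [c for c in train.columns if c in set(candidates) | clinical]
    if not report.retained:
        raise ValueError("first-pass filter removed every feature; cannot proceed")
    return report
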