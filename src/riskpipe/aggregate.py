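"""Slice -> lesion -> patient frequency thresholding and the evaluation
statistics around it (ROC / Youden-J / fast DeLong, confusion metrics,
RECIST response labelling).

The hierarchy: a slice is "high risk" when its model score is at least the
slice cutoff ``X``; a lesion's frequency score is the number of its high-risk
slices; a lesion is PD when that count is at least ``Y``; a patient is PD
when at least ``Z`` lesions are PD. All comparisons are inclusive. The
published operating point is X=0.22, Y=2, Z=1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "ThresholdSet",
    "RocResult",
    "ConfusionStats",
    "roc_auc",
    "youden_threshold",
    "delong_ci",
    "lesion_frequency_score",
    "classify_hierarchy",
    "optimize_thresholds",
    "confusion",
    "recist_classify",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Operating thresholds of the hierarchy; the published defaults are
    slice cutoff X=0.22, slice-count cutoff Y=2, lesion-count cutoff Z=1."""

    slice_cutoff: float = 0.22
    slice_count_cutoff: int = 2
    lesion_count_cutoff: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.slice_cutoff <= 1.0:
            raise ValueError("slice_cutoff must lie in [0, 1]")
        if not 1 <= self.slice_count_cutoff <= 5:
            raise ValueError("slice_count_cutoff must lie in {1..5}")
        if self.lesion_count_cutoff < 1:
            raise ValueError("lesion_count_cutoff must be >= 1")

    def to_dict(self) -> dict:
        return {
            "slice_cutoff": self.slice_cutoff,
            "slice_count_cutoff": self.slice_count_cutoff,
            "lesion_count_cutoff": self.lesion_count_cutoff,
        }


@dataclass
class RocResult:
    auc: float
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    ci95: tuple[float, float] | None = None


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve and AUC by the Mann-Whitney identity (ties count 0.5).

    Curve points are evaluated at every distinct score used as an inclusive
    cutoff (predict positive when score >= threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))
    # curve via cumulative counts over scores sorted descending
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.r_[True, np.diff(sorted_scores) != 0]
    idx = np.nonzero(distinct)[0]
    cum_tp = np.cumsum(sorted_labels)
    cum_fp = np.cumsum(1 - sorted_labels)
    # inclusive cutoffs: counts up to the last tied score
    last = np.r_[idx[1:] - 1, len(scores) - 1]
    thresholds = sorted_scores[idx]
    sens = cum_tp[last] / n1
    spec = 1.0 - cum_fp[last] / n0
    return RocResult(auc=auc, thresholds=thresholds, sensitivities=sens, specificities=spec)


def youden_threshold(roc: RocResult) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1; ties are broken
    toward the LOWER threshold (the sensitivity-favouring operating point)."""
    j = roc.sensitivities + roc.specificities - 1.0
    best = np.max(j)
    candidates = roc.thresholds[j >= best - 1e-12]
    return float(np.min(candidates))


def _midranks(x: np.ndarray) -> np.ndarray:
    return rankdata(x)  # average ranks == midranks


def delong_ci(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC with a fast-DeLong normal-approximation confidence interval.

    Uses the placement-value (structural component) variance estimator;
    the CI is clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("both classes need at least 2 members")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    # placement values
    v10 = (all_ranks[:m] - pos_ranks) / n          # per-positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per-negative
    s10 = np.var(v10, ddof=1)
    s01 = np.var(v01, ddof=1)
    var = s10 / m + s01 / n
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def lesion_frequency_score(slice_scores, slice_cutoff: float) -> int:
    """Number of slice scores at or above the slice cutoff (inclusive)."""
    scores = np.asarray(list(slice_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("lesion has no slice scores")
    return int((scores >= slice_cutoff).sum())


def classify_hierarchy(
    slice_scores: pd.DataFrame, thresholds: ThresholdSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the frequency-threshold hierarchy.

    ``slice_scores`` needs columns ``patient_id, lesion_id, score``. Returns
    (lesion table, patient table); the patient table carries a continuous
    risk statistic for ROC construction — the maximum lesion frequency score
    (0–5) — alongside the binary PD/DC call.
    """
    required = {"patient_id", "lesion_id", "score"}
    if not required <= set(slice_scores.columns):
        raise ValueError(f"slice_scores must have columns {sorted(required)}")
    X, Y, Z = thresholds.slice_cutoff, thresholds.slice_count_cutoff, thresholds.lesion_count_cutoff

    grouped = slice_scores.groupby(["patient_id", "lesion_id"], sort=True)["score"]
    freq = grouped.apply(lambda s: lesion_frequency_score(s, X))
    n_slices = grouped.size()
    short = n_slices[n_slices < Y]
    if len(short):
        warnings.warn(
            f"{len(short)} lesion(s) have fewer than Y={Y} slices and can never be "
            "classified PD at this slice-count cutoff",
            stacklevel=2,
        )
    lesions = freq.rename("frequency_score").reset_index()
    lesions["lesion_pd"] = lesions["frequency_score"] >= Y

    pat = lesions.groupby("patient_id", sort=True).agg(
        n_pd_lesions=("lesion_pd", "sum"),
        patient_score=("frequency_score", "max"),
    ).reset_index()
    pat["patient_pd"] = pat["n_pd_lesions"] >= Z
    return lesions, pat


def optimize_thresholds(
    slice_scores: pd.DataFrame,
    patient_labels: dict[str, int] | pd.Series,
    split_tags: pd.Series | None = None,
    max_y: int = 5,
) -> ThresholdSet:
    """Fit the hierarchy thresholds on discovery out-of-fold scores.

    X is the Youden-J cutoff of the slice-level ROC (slice labels inherited
    from the patient); Y and Z maximize the patient-level Youden-J of the
    resulting classification, ties toward smaller Y then Z (sensitivity-
    favouring). Refuses externally tagged rows outright.
    """
    if split_tags is not None and (np.asarray(split_tags) == "external").any():
        raise ValueError("optimize_thresholds must never see external rows")
    if isinstance(patient_labels, pd.Series):
        patient_labels = patient_labels.to_dict()
    df = slice_scores.copy()
    y_slice = df["patient_id"].map(patient_labels).to_numpy(dtype=int)
    X = youden_threshold(roc_auc(df["score"].to_numpy(), y_slice))

    pat_true = pd.Series(patient_labels)
    best = None
    for Y in range(1, max_y + 1):
        lesions, pat = classify_hierarchy(df, ThresholdSet(X, Y, 1))
        max_lesions = int(pat["n_pd_lesions"].max()) if len(pat) else 1
        for Z in range(1, max(1, max_lesions) + 1):
            pred = (pat.set_index("patient_id")["n_pd_lesions"] >= Z).astype(int)
            truth = pat_true.loc[pred.index].to_numpy()
            stats = confusion(pred.to_numpy(), truth)
            j = stats.sn + stats.sp - 1.0
            key = (j, -Y, -Z)
            if best is None or key > best[0]:
                best = (key, ThresholdSet(X, Y, Z))
    return best[1]


@dataclass(frozen=True)
class ConfusionStats:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sn(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def sp(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f1(self) -> float:
        denom = self.ppv + self.sn
        return 2 * self.ppv * self.sn / denom if denom else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "sn": self.sn, "sp": self.sp, "ppv": self.ppv, "f1": self.f1,
        }


def confusion(pred: np.ndarray, true: np.ndarray) -> ConfusionStats:
    """Confusion counts and derived rates with PD as the positive class."""
    pred = np.asarray(pred, dtype=int)
    true = np.asarray(true, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have the same length")
    return ConfusionStats(
        tp=int(((pred == 1) & (true == 1)).sum()),
        fn=int(((pred == 0) & (true == 1)).sum()),
        fp=int(((pred == 1) & (true == 0)).sum()),
        tn=int(((pred == 0) & (true == 0)).sum()),
    )


def recist_classify(
    baseline_sum_mm: float, followup_sum_mm: float, all_target_lesions_disappeared: bool = False
) -> str:
    """RECIST v1.1 response category from target-lesion diameter sums.

    PD at >= +20% change, PR at <= -30%, CR when all target lesions have
    disappeared; boundaries inclusive.
    """
    if baseline_sum_mm <= 0:
        raise ValueError("baseline sum of diameters must be positive")
    if all_target_lesions_disappeared:
        return "CR"
    change = (followup_sum_mm - baseline_sum_mm) / baseline_sum_mm
    if change >= 0.20:
        return "PD"
    if change <= -0.30:
        return "PR"
    return "SD"
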