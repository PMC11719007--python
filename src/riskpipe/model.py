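"""Grouped nested-cross-validated logistic regression and the published
risk calculator.

All cross-validation is *grouped by patient*: every slice and lesion of a
patient lives in the same fold, so no patient contributes to both the
training and evaluation side of any split.

The published risk calculator (``eq1_risk``) is the fixed logistic model

    risk = [1 + exp(-0.282 - 0.509*PackYears + 0.999*NMetSites
                    - 0.816*ODCentroidDifference_RING
                    + 1.148*RadCentre_RING)]^-1

read *literally* from its printed form. Read this way the risk decreases as
the number of metastatic sites grows, which is the opposite of the cohort's
clinical directionality, so a ``conventional`` flag is provided that negates
the linear predictor before the exponent; the convention used is recorded in
every output and a warning is emitted for the literal default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .aggregate import roc_auc

__all__ = [
    "FoldPlan",
    "RiskModel",
    "NestedCVResult",
    "PublishedEq1",
    "DEFAULT_GRID",
    "make_fold_plan",
    "fit_lr_nested",
    "grouped_cv_auc",
    "eq1_risk",
]

#: Hyperparameter grid: L2 strength x class weighting.
DEFAULT_GRID: tuple[dict, ...] = tuple(
    {"C": C, "class_weight": cw}
    for C in (0.01, 0.1, 1.0, 10.0, 100.0)
    for cw in (None, "balanced")
)


@dataclass
class FoldPlan:
    """Patient-level stratified fold assignment."""

    folds: list[list[str]]  # patient ids per outer fold
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def fold_of(self) -> dict[str, int]:
        return {pid: i for i, fold in enumerate(self.folds) for pid in fold}


def make_fold_plan(
    patient_ids: list[str], patient_labels: dict[str, int] | pd.Series, k: int = 5, seed: int = 0
) -> FoldPlan:
    """Random patient-level folds, stratified by patient label.

    Deterministic for a fixed seed; raises if ``k`` exceeds the minority
    class patient count (a fold would otherwise lack one class).
    """
    if isinstance(patient_labels, pd.Series):
        patient_labels = patient_labels.to_dict()
    ids = list(dict.fromkeys(patient_ids))
    by_class: dict[int, list[str]] = {}
    for pid in ids:
        by_class.setdefault(int(patient_labels[pid]), []).append(pid)
    minority = min(len(v) for v in by_class.values())
    if k > minority:
        raise ValueError(f"k={k} exceeds minority-class patient count {minority}")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for label in sorted(by_class):
        members = sorted(by_class[label])
        rng.shuffle(members)
        for i, pid in enumerate(members):
            folds[i % k].append(pid)
    return FoldPlan(folds=folds, seed=seed)


def _check_finite(X: pd.DataFrame) -> None:
    bad = X.columns[~np.isfinite(X.to_numpy(dtype=float)).all(axis=0)]
    if len(bad):
        raise ValueError(f"non-finite values in feature column(s): {list(bad)}")


def _fit_lr(X: np.ndarray, y: np.ndarray, grid_point: dict, seed: int) -> LogisticRegression:
    return LogisticRegression(
        C=grid_point["C"],
        class_weight=grid_point["class_weight"],
        solver="lbfgs",
        max_iter=2000,
        random_state=seed,
    ).fit(X, y)


def grouped_cv_auc(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    plan: FoldPlan,
    grid_point: dict | None = None,
    seed: int = 0,
) -> tuple[float, np.ndarray, list[float]]:
    """Out-of-fold AUC of a logistic model under a patient-level fold plan.

    Returns (pooled OOF AUC, OOF score vector, per-fold AUCs).
    """
    if grid_point is None:
        grid_point = {"C": 1.0, "class_weight": None}
    groups = np.asarray(groups)
    y = np.asarray(y, dtype=int)
    fold_of = plan.fold_of()
    fold_idx = np.array([fold_of[g] for g in groups])
    oof = np.full(len(y), np.nan)
    fold_aucs: list[float] = []
    Xv = X.to_numpy(dtype=float)
    for f in range(plan.k):
        test = fold_idx == f
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError("degenerate labels: a training split contains one class")
        clf = _fit_lr(Xv[train], y[train], grid_point, seed)
        oof[test] = clf.predict_proba(Xv[test])[:, 1]
        if len(np.unique(y[test])) == 2:
            fold_aucs.append(roc_auc(oof[test], y[test]).auc)
    pooled = roc_auc(oof, y).auc
    return pooled, oof, fold_aucs


@dataclass
class RiskModel:
    """A fitted logistic risk model: linear predictor + logistic link."""

    intercept: float
    coefficients: dict[str, float]
    hyperparameters: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        z = np.full(len(X), self.intercept)
        for name, coef in self.coefficients.items():
            z = z + coef * X[name].to_numpy(dtype=float)
        return z

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "hyperparameters": {
                k: (v if v is None or isinstance(v, (int, float, str)) else str(v))
                for k, v in self.hyperparameters.items()
            },
            "metadata": self.metadata,
        }


@dataclass
class NestedCVResult:
    model: RiskModel
    oof_scores: np.ndarray
    cv_auc_mean: float
    cv_auc_sd: float
    fold_aucs: list[float]
    chosen_grid: list[dict]


def _inner_best_grid(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    grid: tuple[dict, ...],
    k: int,
    seed: int,
) -> dict:
    patient_label = pd.Series(y, index=groups).groupby(level=0).max()
    ids = list(dict.fromkeys(groups))
    k_eff = min(k, int(patient_label.value_counts().min()))
    plan = make_fold_plan(ids, patient_label, k=max(2, k_eff), seed=seed)
    best, best_auc = grid[0], -np.inf
    for gp in grid:
        auc, _, _ = grouped_cv_auc(X, y, groups, plan, gp, seed=seed)
        if auc > best_auc:
            best, best_auc = gp, auc
    return best


def fit_lr_nested(
    features: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray,
    plan: FoldPlan,
    signature: list[str],
    grid: tuple[dict, ...] = DEFAULT_GRID,
    inner_k: int = 5,
    seed: int = 0,
) -> NestedCVResult:
    """Nested grouped CV: the inner loop grid-searches hyperparameters on each
    outer-train split, the outer loop produces out-of-fold slice scores, and
    the final model is refit on all discovery rows with the grid point chosen
    by grouped CV over the whole discovery set."""
    X = features[signature]
    _check_finite(X)
    y = np.asarray(labels, dtype=int)
    groups = np.asarray(groups)
    fold_of = plan.fold_of()
    fold_idx = np.array([fold_of[g] for g in groups])
    Xv = X.to_numpy(dtype=float)
    oof = np.full(len(y), np.nan)
    fold_aucs: list[float] = []
    chosen: list[dict] = []
    for f in range(plan.k):
        test = fold_idx == f
        train = ~test
        gp = _inner_best_grid(
            X[train], y[train], groups[train], grid, inner_k, seed=seed * 1009 + f
        )
        chosen.append(gp)
        clf = _fit_lr(Xv[train], y[train], gp, seed)
        oof[test] = clf.predict_proba(Xv[test])[:, 1]
        if len(np.unique(y[test])) == 2:
            fold_aucs.append(roc_auc(oof[test], y[test]).auc)
    final_gp = _inner_best_grid(X, y, groups, grid, inner_k, seed=seed)
    final = _fit_lr(Xv, y, final_gp, seed)
    model = RiskModel(
        intercept=float(final.intercept_[0]),
        coefficients={name: float(c) for name, c in zip(signature, final.coef_[0])},
        hyperparameters=dict(final_gp),
        metadata={"folds": plan.k, "seed": seed, "signature": list(signature)},
    )
    return NestedCVResult(
        model=model,
        oof_scores=oof,
        cv_auc_mean=float(np.mean(fold_aucs)),
        cv_auc_sd=float(np.std(fold_aucs)),
        fold_aucs=fold_aucs,
        chosen_grid=chosen,
    )


@dataclass(frozen=True)
class PublishedEq1:
    """The published risk-calculator coefficients (immutable)."""

    intercept: float = -0.282
    pack_years: float = -0.509
    n_met_sites: float = 0.999
    odcd_ring: float = -0.816
    radcentre_ring: float = 1.148


EQ1 = PublishedEq1()


def eq1_risk(
    pack_years_scaled: float,
    n_met_sites_scaled: float,
    odcd_ring: float,
    radcentre_ring: float,
    convention: str = "literal",
) -> float:
    """Risk of progression from the published calculator.

    ``literal``: risk = 1 / (1 + exp(E)) with
    E = -0.282 - 0.509*PY + 0.999*M - 0.816*ODCD + 1.148*RC, exactly as the
    formula is printed. ``conventional`` negates E first (the usual logistic
    reading, restoring the clinically expected sign of the metastatic-site
    term). Inputs are expected on the [-1, 1] training scale; the calculator
    never rescales internally.
    """
    if convention not in ("literal", "conventional"):
        raise ValueError("convention must be 'literal' or 'conventional'")
    E = (
        EQ1.intercept
        + EQ1.pack_years * pack_years_scaled
        + EQ1.n_met_sites * n_met_sites_scaled
        + EQ1.odcd_ring * odcd_ring
        + EQ1.radcentre_ring * radcentre_ring
    )
    if convention == "literal":
        warnings.warn(
            "eq1_risk literal convention: risk decreases with the number of "
            "metastatic sites as printed; pass convention='conventional' for "
            "the standard logistic reading",
            stacklevel=2,
        )
        return float(1.0 / (1.0 + np.exp(E)))
    return float(1.0 / (1.0 + np.exp(-E)))
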