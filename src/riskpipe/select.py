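"""Feature selection: sequential forward selection with a ΔAUC admission
rule, minimum-redundancy-maximum-relevance, and ReliefF; plus the
six-signature menu (each algorithm, with and without clinical covariates).

Signature size is capped at five features (the one-in-five rule for a
27-patient minority class), and a candidate only enters a signature if it
improves the grouped-cross-validated AUC by more than 0.03. Ties everywhere
are broken lexicographically by feature name, so selection is deterministic
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import mutual_info_score

from .model import FoldPlan, grouped_cv_auc, make_fold_plan

__all__ = [
    "SelectionConfig",
    "Signature",
    "sfs_select",
    "mrmr_select",
    "relieff_select",
    "build_signature_menu",
]


@dataclass(frozen=True)
class SelectionConfig:
    max_features: int = 5
    delta_auc_threshold: float = 0.03
    include_clinical: bool = True
    algorithm: str = "sfs"  # sfs | mrmr | relieff
    cv_folds: int = 5
    mrmr_bins: int = 8
    relieff_neighbors: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if self.delta_auc_threshold < 0:
            raise ValueError("delta_auc_threshold must be >= 0")


@dataclass
class Signature:
    features: list[str]
    auc_trace: list[float]
    algorithm: str
    config: SelectionConfig
    cv_auc_mean: float = float("nan")
    cv_auc_sd: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "auc_trace": self.auc_trace,
            "algorithm": self.algorithm,
            "cv_auc_mean": self.cv_auc_mean,
            "cv_auc_sd": self.cv_auc_sd,
        }


def _plan_for(labels: np.ndarray, groups: np.ndarray, config: SelectionConfig) -> FoldPlan:
    patient_label = pd.Series(labels, index=groups).groupby(level=0).max()
    ids = list(dict.fromkeys(groups))
    k = min(config.cv_folds, int(patient_label.value_counts().min()))
    return make_fold_plan(ids, patient_label, k=max(2, k), seed=config.seed)


def sfs_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> Signature:
    """Greedy forward selection maximizing grouped-CV logistic AUC.

    Stops when the best candidate's improvement is <= the ΔAUC threshold
    or the signature reaches ``max_features``.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate labels: one class only")
    groups = np.asarray(groups)
    plan = _plan_for(labels, groups, config)
    pool = sorted(features.columns)
    selected: list[str] = []
    trace: list[float] = []
    current_auc = 0.5  # chance baseline for the empty model
    while len(selected) < config.max_features and pool:
        best_feat, best_auc = None, -np.inf
        for feat in pool:  # lexicographic order -> deterministic tie-break
            auc, _, _ = grouped_cv_auc(
                features[selected + [feat]], labels, groups, plan, seed=config.seed
            )
            if auc > best_auc + 1e-12:
                best_feat, best_auc = feat, auc
        improvement = best_auc - current_auc
        if selected and improvement <= config.delta_auc_threshold:
            break
        if not selected and best_auc <= 0.5:
            # even the first feature must beat chance
            selected.append(best_feat)
            trace.append(best_auc)
            pool.remove(best_feat)
            break
        selected.append(best_feat)
        trace.append(best_auc)
        current_auc = best_auc
        pool.remove(best_feat)
    return Signature(selected, trace, "sfs", config)


def _quantile_bin(x: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(edges), x, side="right")


def mrmr_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    k: int,
    config: SelectionConfig = SelectionConfig(),
) -> Signature:
    """mRMR, difference (MID) form: greedily add the feature maximizing
    relevance MI(f; y) minus the mean MI(f; already-selected), with mutual
    information estimated on quantile-binned features."""
    if k < 1 or k > features.shape[1]:
        raise ValueError(f"k={k} out of range for pool of {features.shape[1]}")
    labels = np.asarray(labels, dtype=int)
    cols = sorted(features.columns)
    binned = {c: _quantile_bin(features[c].to_numpy(dtype=float), config.mrmr_bins) for c in cols}
    relevance = {c: mutual_info_score(binned[c], labels) for c in cols}
    selected: list[str] = []
    trace: list[float] = []
    mi_cache: dict[tuple[str, str], float] = {}

    def mi_pair(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = mutual_info_score(binned[a], binned[b])
        return mi_cache[key]

    while len(selected) < k:
        best_feat, best_score = None, -np.inf
        for c in cols:
            if c in selected:
                continue
            redundancy = (
                np.mean([mi_pair(c, s) for s in selected]) if selected else 0.0
            )
            score = relevance[c] - redundancy
            if score > best_score + 1e-12:
                best_feat, best_score = c, score
        selected.append(best_feat)
        trace.append(float(best_score))
    return Signature(selected, trace, "mrmr", config)


def relieff_weights(
    features: pd.DataFrame, labels: np.ndarray, n_neighbors: int = 10
) -> pd.Series:
    """Standard ReliefF weights: every instance is used, distances are
    Manhattan on the given (pre-scaled) features, with ``n_neighbors``
    nearest hits and misses per instance."""
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if n_neighbors >= counts.min():
        raise ValueError(
            f"n_neighbors={n_neighbors} must be below the smallest class size {counts.min()}"
        )
    n, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    D = cdist(X, X, metric="cityblock")
    np.fill_diagonal(D, np.inf)
    W = np.zeros(p)
    for i in range(n):
        ci = y[i]
        for c in classes:
            idx = np.where(y == c)[0]
            idx = idx[idx != i]
            order = idx[np.argsort(D[i, idx], kind="stable")][:n_neighbors]
            diff = np.abs(X[order] - X[i]) / span  # normalized per-feature diff
            mean_diff = diff.mean(axis=0)
            if c == ci:
                W -= mean_diff / n
            else:
                W += (priors[c] / (1.0 - priors[ci])) * mean_diff / n
    return pd.Series(W, index=features.columns)


def relieff_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    k: int,
    config: SelectionConfig = SelectionConfig(),
) -> Signature:
    """Top-k features by ReliefF weight; ties break lexicographically."""
    if k < 1 or k > features.shape[1]:
        raise ValueError(f"k={k} out of range for pool of {features.shape[1]}")
    weights = relieff_weights(features, labels, config.relieff_neighbors)
    order = sorted(features.columns, key=lambda c: (-weights[c], c))
    selected = order[:k]
    return Signature(selected, [float(weights[c]) for c in selected], "relieff", config)


def _trim_by_delta_auc(
    ordered: list[str],
    features: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray,
    config: SelectionConfig,
) -> tuple[list[str], list[float]]:
    """Admit features in the given rank order while each addition improves
    grouped-CV AUC by more than the ΔAUC threshold (the same admission rule
    the forward search uses), up to max_features."""
    plan = _plan_for(labels, groups, config)
    kept: list[str] = []
    trace: list[float] = []
    current = 0.5
    for feat in ordered[: config.max_features * 3]:
        cand = kept + [feat]
        auc, _, _ = grouped_cv_auc(features[cand], labels, groups, plan, seed=config.seed)
        if not kept or auc - current > config.delta_auc_threshold:
            kept.append(feat)
            trace.append(auc)
            current = auc
        if len(kept) == config.max_features:
            break
    return kept, trace


def build_signature_menu(
    features: pd.DataFrame,
    clinical_columns: list[str],
    labels: np.ndarray,
    groups: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
    algorithms: tuple[str, ...] = ("sfs", "mrmr", "relieff"),
) -> list[Signature]:
    """The candidate-signature menu: each algorithm run with and without the
    clinical covariates in the pool (six signatures for the full set).

    Every signature is evaluated by grouped-CV logistic AUC (mean ± sd over
    folds); rank-based selectors are trimmed by the same ΔAUC admission rule
    the forward search applies.
    """
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(groups)
    menu: list[Signature] = []
    for include_clinical in (True, False):
        pool_cols = list(features.columns)
        if not include_clinical:
            pool_cols = [c for c in pool_cols if c not in set(clinical_columns)]
        pool = features[pool_cols]
        for algo in algorithms:
            cfg = SelectionConfig(
                max_features=config.max_features,
                delta_auc_threshold=config.delta_auc_threshold,
                include_clinical=include_clinical,
                algorithm=algo,
                cv_folds=config.cv_folds,
                mrmr_bins=config.mrmr_bins,
                relieff_neighbors=config.relieff_neighbors,
                seed=config.seed,
            )
            if algo == "sfs":
                sig = sfs_select(pool, labels, groups, cfg)
            elif algo == "mrmr":
                ranked = mrmr_select(pool, labels, min(cfg.max_features * 3, pool.shape[1]), cfg)
                kept, trace = _trim_by_delta_auc(ranked.features, pool, labels, groups, cfg)
                sig = Signature(kept, trace, "mrmr", cfg)
            elif algo == "relieff":
                ranked = relieff_select(pool, labels, min(cfg.max_features * 3, pool.shape[1]), cfg)
                kept, trace = _trim_by_delta_auc(ranked.features, pool, labels, groups, cfg)
                sig = Signature(kept, trace, "relieff", cfg)
            else:
                raise ValueError(f"unknown algorithm {algo!r}")
            plan = _plan_for(labels, groups, cfg)
            if sig.features:
                _, _, fold_aucs = grouped_cv_auc(
                    features[sig.features], labels, groups, plan, seed=cfg.seed
                )
                sig.cv_auc_mean = float(np.mean(fold_aucs))
                sig.cv_auc_sd = float(np.std(fold_aucs))
            menu.append(sig)
    return menu


def best_signature(menu: list[Signature]) -> Signature:
    """Menu winner: highest mean grouped-CV AUC, ties to the lower sd."""
    return max(menu, key=lambda s: (np.nan_to_num(s.cv_auc_mean), -np.nan_to_num(s.cv_auc_sd, nan=np.inf)))
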