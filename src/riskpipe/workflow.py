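"""End-to-end orchestration: simulate -> segment -> extract -> preprocess ->
select -> train -> optimize thresholds -> evaluate -> survival.

The cohort is split into a discovery set and an external test set at the
patient level. Every fitted object — scaler, filter, signatures, model,
hierarchy thresholds — is learned on discovery rows only and then applied,
frozen, to the external set; a runtime guard raises if externally tagged
rows ever reach a fitting step.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate, imaging, preprocess, radiomics, select, survival
from .model import DEFAULT_GRID, fit_lr_nested, make_fold_plan
from .synthetic import CohortSpec, SyntheticCohort, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "assert_discovery"]

log = logging.getLogger("riskpipe")

CLINICAL_NUMERIC = ["age", "pack_years", "n_met_sites"]
CLINICAL_CATEGORICAL = ["sex", "smoking_status", "ecog"]


def assert_discovery(split_tags) -> None:
    """Leakage guard: raise if any externally tagged row reaches a fit step."""
    tags = np.asarray(split_tags)
    if (tags == "external").any():
        raise RuntimeError("leakage guard: external rows reached a fitting step")


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    window: imaging.WindowSpec = imaging.SOFT_TISSUE_WINDOW
    edge_width_px: int = 2
    ring_target_mm: float = 6.0
    filter_params: preprocess.FilterParams = field(default_factory=preprocess.FilterParams)
    selection: select.SelectionConfig = field(default_factory=select.SelectionConfig)
    algorithms: tuple[str, ...] = ("sfs", "mrmr", "relieff")
    grid: tuple[dict, ...] = DEFAULT_GRID
    external_fraction: float = 0.15
    cv_folds: int = 5
    seed: int = 0
    out_dir: str | None = None


@dataclass
class PipelineResult:
    signatures: list[select.Signature]
    best_signature: select.Signature
    model: object
    thresholds: aggregate.ThresholdSet
    metrics: dict
    predictions: pd.DataFrame
    features: pd.DataFrame


def _split_patients(clinical: pd.DataFrame, external_fraction: float, seed: int) -> pd.Series:
    """Stratified patient-level discovery/external split tags."""
    rng = np.random.default_rng(seed)
    tags = {}
    for cls, group in clinical.groupby("response"):
        ids = sorted(group["patient_id"])
        rng.shuffle(ids)
        n_ext = max(2, int(round(len(ids) * external_fraction)))
        for pid in ids[:n_ext]:
            tags[pid] = "external"
        for pid in ids[n_ext:]:
            tags[pid] = "discovery"
    return clinical["patient_id"].map(tags)


def segment_and_extract(cohort: SyntheticCohort, config: PipelineConfig) -> pd.DataFrame:
    """Segment every annotated lesion and extract the feature bank.

    Returns the wide per-slice table with ``<feature>_<REGION>`` columns.
    """
    long_parts = []
    ring_px = imaging.ring_width_from_spacing(
        config.ring_target_mm, cohort.spec.pixel_spacing_mm
    )
    for _, ann in cohort.annotations.iterrows():
        vol = cohort.volumes[ann["volume_id"]]
        norm = imaging.window_normalize(vol, config.window)
        slices = imaging.select_slices(
            (int(ann["extent_lo"]), int(ann["extent_hi"])),
            int(ann["central_slice"]),
            n_slices_volume=vol.n_slices,
        )
        halfwidth = max(4, round(0.75 * ann["approx_diam_mm"] / cohort.spec.pixel_spacing_mm))
        triplets = {}
        for s in slices:
            try:
                core = imaging.segment_lesion_slice(
                    norm.voxels[s], (int(ann["seed_row"]), int(ann["seed_col"])), halfwidth
                )
                triplets[s] = imaging.build_mask_triplet(
                    core, config.edge_width_px, ring_px
                )
            except (imaging.SegmentationError, ValueError) as exc:
                warnings.warn(
                    f"slice {s} of {ann['volume_id']} skipped: {exc}", stacklevel=2
                )
        if not triplets:
            warnings.warn(f"lesion {ann['volume_id']} fully skipped", stacklevel=2)
            continue
        long_parts.append(
            radiomics.extract_lesion_stack(
                norm, triplets, sorted(triplets), ann["patient_id"], ann["lesion_id"]
            )
        )
    long_df = pd.concat(long_parts, ignore_index=True)
    return radiomics.to_wide(long_df)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis on a synthetic cohort; returns all artifacts.

    Deterministic for a fixed config and seed.
    """
    log.info("simulating cohort: n=%d", config.cohort.n_patients)
    cohort = generate_cohort(config.cohort)

    log.info("segmenting + extracting features")
    wide = segment_and_extract(cohort, config)
    log.info("feature table: %d rows x %d columns", *wide.shape)

    clinical_encoded, levels = preprocess.one_hot(
        cohort.clinical[["patient_id"] + CLINICAL_NUMERIC + CLINICAL_CATEGORICAL],
        CLINICAL_CATEGORICAL,
    )
    clinical_cols = [c for c in clinical_encoded.columns if c != "patient_id"]
    table = wide.merge(clinical_encoded, on="patient_id", how="left")
    labels_by_patient = (
        cohort.clinical.set_index("patient_id")["response"].map({"PD": 1, "DC": 0})
    )
    table["label"] = table["patient_id"].map(labels_by_patient)
    table["split"] = table["patient_id"].map(
        _split_patients(cohort.clinical, config.external_fraction, config.seed + 17)
        .set_axis(cohort.clinical["patient_id"]).to_dict()
    )

    id_cols = ["patient_id", "lesion_id", "slice_index", "label", "split"]
    feature_cols = [c for c in table.columns if c not in id_cols]
    disc = table[table["split"] == "discovery"]
    ext = table[table["split"] == "external"]
    assert_discovery(disc["split"])

    # scaler + first-pass filter fitted on discovery only
    scaler = preprocess.fit_scaler(disc[feature_cols])
    table_scaled = preprocess.apply_scaler(table[feature_cols], scaler)
    disc_scaled = table_scaled.loc[disc.index]
    report = preprocess.first_pass_filter(
        disc_scaled,
        disc["label"].to_numpy(),
        config.filter_params,
        clinical_columns=clinical_cols,
    )
    pool = report.retained
    log.info("filter retained %d / %d features", len(pool), len(feature_cols))

    # signature menu on discovery
    menu = select.build_signature_menu(
        disc_scaled[pool],
        clinical_cols,
        disc["label"].to_numpy(),
        disc["patient_id"].to_numpy(),
        config.selection,
        algorithms=config.algorithms,
    )
    best = select.best_signature(menu)
    log.info("best signature (%s): %s", best.algorithm, best.features)

    # nested-CV model on discovery
    disc_labels_by_patient = labels_by_patient.loc[
        disc["patient_id"].unique()
    ]
    plan = make_fold_plan(
        list(disc["patient_id"].unique()), disc_labels_by_patient,
        k=config.cv_folds, seed=config.seed + 101,
    )
    fit = fit_lr_nested(
        disc_scaled, disc["label"].to_numpy(), disc["patient_id"].to_numpy(),
        plan, best.features, grid=config.grid, seed=config.seed,
    )

    # hierarchy thresholds from discovery out-of-fold scores
    disc_scores = disc[["patient_id", "lesion_id", "slice_index"]].copy()
    disc_scores["score"] = fit.oof_scores
    thresholds = aggregate.optimize_thresholds(
        disc_scores, labels_by_patient.to_dict(), split_tags=disc["split"]
    )
    log.info("thresholds: %s", thresholds.to_dict())

    # evaluate both splits
    def _evaluate(scores_df: pd.DataFrame) -> tuple[dict, pd.DataFrame]:
        lesions, pats = aggregate.classify_hierarchy(scores_df, thresholds)
        truth = pats["patient_id"].map(labels_by_patient).to_numpy()
        stats = aggregate.confusion(pats["patient_pd"].astype(int).to_numpy(), truth)
        roc = aggregate.roc_auc(pats["patient_score"].to_numpy(), truth)
        return (
            {"patient_auc": roc.auc, **stats.to_dict()},
            pats.assign(true_label=truth),
        )

    disc_metrics, disc_pats = _evaluate(disc_scores)
    ext_scores = ext[["patient_id", "lesion_id", "slice_index"]].copy()
    ext_scores["score"] = fit.model.predict_risk(table_scaled.loc[ext.index])
    ext_metrics, ext_pats = _evaluate(ext_scores)

    # survival of predicted risk groups
    surv_metrics = {}
    surv = cohort.clinical.set_index("patient_id")
    for split_name, pats in (("discovery", disc_pats), ("external", ext_pats)):
        for endpoint, tcol, ecol in (("pfs", "pfs_months", "pfs_event"), ("os", "os_months", "os_event")):
            merged = pats.set_index("patient_id").join(surv[[tcol, ecol]])
            hi = merged[merged["patient_pd"]]
            lo = merged[~merged["patient_pd"]]
            key = f"{split_name}_{endpoint}_logrank_p"
            if len(hi) and len(lo) and (hi[ecol].sum() + lo[ecol].sum()) > 0:
                _, p = survival.logrank_test(
                    hi.rename(columns={tcol: "time", ecol: "event"})[["time", "event"]],
                    lo.rename(columns={tcol: "time", ecol: "event"})[["time", "event"]],
                )
                surv_metrics[key] = p
            else:
                surv_metrics[key] = None

    metrics = {
        "seed": config.seed,
        "n_signatures": len(menu),
        "best_signature": best.to_dict(),
        "cv_slice_auc_mean": fit.cv_auc_mean,
        "cv_slice_auc_sd": fit.cv_auc_sd,
        "thresholds": thresholds.to_dict(),
        "discovery": disc_metrics,
        "external": ext_metrics,
        "survival": surv_metrics,
        "filter": {"n_removed": len(report.removed), "n_retained": len(report.retained)},
    }

    predictions = pd.concat(
        [disc_pats.assign(split="discovery"), ext_pats.assign(split="external")],
        ignore_index=True,
    )

    result = PipelineResult(
        signatures=menu,
        best_signature=best,
        model=fit.model,
        thresholds=thresholds,
        metrics=metrics,
        predictions=predictions,
        features=table,
    )
    if config.out_dir:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=2, sort_keys=True, default=str)
    with open(out / "model.json", "w") as fh:
        json.dump(result.model.to_dict(), fh, indent=2, sort_keys=True)
    with open(out / "thresholds.json", "w") as fh:
        json.dump(result.thresholds.to_dict(), fh, indent=2, sort_keys=True)
    with open(out / "signatures.json", "w") as fh:
        json.dump([s.to_dict() for s in result.signatures], fh, indent=2, sort_keys=True)
    result.predictions.to_csv(out / "predictions.csv", index=False)
    log.info("artifacts written to %s", out)
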