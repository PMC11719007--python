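"""Synthetic cohort generator with known planted structure.

Emulates the study conditions of a pembrolizumab-response CT cohort so that
every downstream stage is testable without any private data:

* ~28% of patients progress (PD); the rest achieve disease control (DC);
* each lesion is a soft-edged ellipse in noisy parenchyma, spanning five
  axial slices with radius tapering away from the central slice;
* the PD signal is planted **only in the peritumoral ring zone** — an
  angularly asymmetric halo whose amplitude scales with
  ``ring_contrast_effect`` displaces the ring's optical centroid and shifts
  its radial intensity profile. Core intensities are class-identical, so a
  pipeline that discriminates must be reading peritumoral features;
* clinical covariates are drawn from class-conditional distributions whose
  directionality mirrors the cohort (PD patients: fewer pack-years, more
  metastatic sites, worse performance status);
* survival times are exponential with a configurable hazard ratio between
  the *true* classes (never the predicted ones), independently censored.

All randomness flows from the single integer seed through
``numpy.random.SeedSequence`` spawning, so a fixed seed reproduces the
cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import CTVolume

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_feature_table",
    "generate_survival",
    "DEFAULT_CLINICAL_EFFECTS",
]

# class-conditional (mean_DC, mean_PD, sd) for the numeric clinical covariates
DEFAULT_CLINICAL_EFFECTS: dict[str, tuple[float, float, float]] = {
    "age": (74.0, 70.0, 8.0),
    "pack_years": (45.0, 33.0, 15.0),
    "n_met_sites": (2.6, 3.4, 1.2),
}

# class-conditional level probabilities for the categorical covariates
_CATEGORICAL_EFFECTS: dict[str, dict[str, tuple[float, float]]] = {
    # level: (P(level | DC), P(level | PD))
    "sex": {"F": (0.60, 0.52), "M": (0.40, 0.48)},
    "smoking_status": {"never": (0.03, 0.07), "smoker": (0.93, 0.89), "unknown": (0.04, 0.04)},
    "ecog": {"0-1": (0.56, 0.48), ">1": (0.44, 0.52)},
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative conditions for one synthetic cohort."""

    n_patients: int = 97
    pd_prevalence: float = 28 / 100
    lesions_per_patient: dict[int, float] = field(default_factory=lambda: {1: 0.82, 2: 0.18})
    slices_per_lesion: int = 5
    image_shape: tuple[int, int] = (96, 96)
    pixel_spacing_mm: float = 0.75
    slice_thickness_mm: float = 3.0
    lesion_radius_px: tuple[float, float] = (8.0, 14.0)
    edge_width_px: int = 2
    ring_width_px: int = 8
    ring_contrast_effect: float = 1.5
    noise_sd: float = 0.05  # on the normalized [0,1] scale
    background_hu: float = -100.0
    lesion_hu: float = 60.0
    clinical_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS)
    )
    survival_hazard_ratio: float = 3.0
    censor_rate: float = 0.2
    median_pfs_dc_months: float = 10.0
    median_os_dc_months: float = 16.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pd_prevalence <= 1.0:
            raise ValueError("pd_prevalence must lie in [0, 1]")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.slices_per_lesion < 1:
            raise ValueError("slices_per_lesion must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.survival_hazard_ratio <= 0:
            raise ValueError("survival_hazard_ratio must be positive")
        for name, (_, _, sd) in self.clinical_effects.items():
            if sd <= 0:
                raise ValueError(f"clinical_effects[{name!r}] sd must be positive")
        need = 2 * (max(self.lesion_radius_px) + self.ring_width_px + self.edge_width_px) + 4
        if min(self.image_shape) < need:
            raise ValueError(
                f"image_shape must be at least {need:.0f} px per side to contain "
                "lesion + edge + ring"
            )


@dataclass
class GroundTruth:
    """Planted generative state, for oracle checks downstream."""

    patient_class: dict[str, int]  # 1 = PD
    lesion_masks: dict[tuple[str, str], dict[int, np.ndarray]]  # (patient, lesion) -> slice -> core
    lesion_centres: dict[tuple[str, str], tuple[int, int]]
    survival_group: dict[str, str]  # low | high


@dataclass
class SyntheticCohort:
    volumes: dict[str, CTVolume]  # key "<patient>_<lesion>"
    annotations: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth
    spec: CohortSpec


def _taper(step: int) -> float:
    return {0: 1.0, 1: 0.85, 2: 0.65}.get(abs(step), 0.5)


def _lesion_slice(
    shape: tuple[int, int],
    centre: tuple[float, float],
    radius: float,
    axis_ratio: float,
    angle: float,
    halo_amp_hu: float,
    halo_phase: float,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One axial slice in HU plus the reference core mask."""
    yy, xx = np.indices(shape, dtype=float)
    dy, dx = yy - centre[0], xx - centre[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    rad = np.sqrt((u / radius) ** 2 + (v / (radius * axis_ratio)) ** 2)
    core = rad <= 1.0
    soft = ndimage.gaussian_filter(core.astype(float), sigma=1.5)
    hu = spec.background_hu + (spec.lesion_hu - spec.background_hu) * soft
    if halo_amp_hu != 0.0:
        # asymmetric peritumoral halo: brightens one side of the ring zone,
        # displacing the ring's optical centroid and its radial mass profile
        ring_zone = (rad > 1.0) & (rad <= 1.0 + (spec.ring_width_px + spec.edge_width_px) / radius)
        theta = np.arctan2(v, u)
        angular = 0.5 * (1.0 + np.cos(theta - halo_phase))
        decay = np.clip(1.0 - (rad - 1.0) * radius / (spec.ring_width_px + spec.edge_width_px), 0, 1)
        hu = hu + halo_amp_hu * angular * decay * ring_zone
    hu = hu + rng.normal(0.0, spec.noise_sd * 400.0, size=shape)
    return hu, core


def _sample_lesion_count(spec: CohortSpec, rng: np.random.Generator) -> int:
    ks = sorted(spec.lesions_per_patient)
    ps = np.array([spec.lesions_per_patient[k] for k in ks], dtype=float)
    ps = ps / ps.sum()
    return int(rng.choice(ks, p=ps))


def generate_survival(
    classes: np.ndarray,
    hazard_ratio: float,
    censor_rate: float,
    median_dc_months: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times tied to true class; independent censoring.

    DC hazard is ln2 / median; PD hazard is that times the hazard ratio.
    With probability ``censor_rate`` a record is censored uniformly before
    its event time.
    """
    classes = np.asarray(classes, dtype=int)
    lam0 = np.log(2.0) / median_dc_months
    lam = np.where(classes == 1, lam0 * hazard_ratio, lam0)
    times = rng.exponential(1.0 / lam)
    events = np.ones(len(classes), dtype=bool)
    censor = rng.random(len(classes)) < censor_rate
    times = np.where(censor, times * rng.random(len(classes)), times)
    events[censor] = False
    times = np.maximum(times, 1e-3)
    return times, events


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate volumes, annotations, a clinical table and the ground truth."""
    root = np.random.SeedSequence(spec.seed)
    rng_cohort, rng_clin, rng_surv, rng_img = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    n_pd = int(round(spec.n_patients * spec.pd_prevalence))
    classes = np.zeros(spec.n_patients, dtype=int)
    classes[:n_pd] = 1
    rng_cohort.shuffle(classes)
    patient_ids = [f"P{i:04d}" for i in range(spec.n_patients)]

    # clinical covariates
    clin_rows = []
    for pid, cls in zip(patient_ids, classes):
        row: dict[str, object] = {"patient_id": pid}
        for name, (mu_dc, mu_pd, sd) in spec.clinical_effects.items():
            mu = mu_pd if cls == 1 else mu_dc
            val = rng_clin.normal(mu, sd)
            if name in ("n_met_sites",):
                val = max(0, round(val))
            elif name in ("age", "pack_years"):
                val = max(0.0, round(val, 1))
            row[name] = val
        for cat, levels in _CATEGORICAL_EFFECTS.items():
            names = list(levels)
            probs = np.array([levels[lv][cls] for lv in names])
            row[cat] = rng_clin.choice(names, p=probs / probs.sum())
        row["response"] = "PD" if cls == 1 else "DC"
        clin_rows.append(row)
    clinical = pd.DataFrame(clin_rows)

    # survival tied to the true class
    pfs_t, pfs_e = generate_survival(
        classes, spec.survival_hazard_ratio, spec.censor_rate, spec.median_pfs_dc_months, rng_surv
    )
    os_t, os_e = generate_survival(
        classes, spec.survival_hazard_ratio, spec.censor_rate, spec.median_os_dc_months, rng_surv
    )
    clinical["pfs_months"] = np.round(pfs_t, 3)
    clinical["pfs_event"] = pfs_e.astype(int)
    clinical["os_months"] = np.round(os_t, 3)
    clinical["os_event"] = os_e.astype(int)

    # imaging
    volumes: dict[str, CTVolume] = {}
    ann_rows = []
    lesion_masks: dict[tuple[str, str], dict[int, np.ndarray]] = {}
    lesion_centres: dict[tuple[str, str], tuple[int, int]] = {}
    n_z_pad = 2
    margin = max(spec.lesion_radius_px) + spec.ring_width_px + spec.edge_width_px + 2
    for pid, cls in zip(patient_ids, classes):
        n_lesions = _sample_lesion_count(spec, rng_cohort)
        for li in range(n_lesions):
            lid = f"L{li}"
            rng_les = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 7, int(pid[1:]), li]).generate_state(4)
            )
            r0 = rng_les.uniform(*spec.lesion_radius_px)
            axis_ratio = rng_les.uniform(0.7, 1.0)
            angle = rng_les.uniform(0, np.pi)
            jitter = min(6.0, min(spec.image_shape) / 2 - margin)
            centre = (
                spec.image_shape[0] / 2 + rng_les.uniform(-jitter, jitter),
                spec.image_shape[1] / 2 + rng_les.uniform(-jitter, jitter),
            )
            halo_amp = 0.0
            if cls == 1 and spec.ring_contrast_effect > 0:
                halo_amp = spec.ring_contrast_effect * 15.0 * rng_les.uniform(0.8, 1.2)
            halo_phase = rng_les.uniform(0, 2 * np.pi)

            n_z = spec.slices_per_lesion + 2 * n_z_pad
            central = n_z // 2
            vox = np.empty((n_z, *spec.image_shape))
            masks: dict[int, np.ndarray] = {}
            half = spec.slices_per_lesion // 2
            for z in range(n_z):
                step = z - central
                if abs(step) <= half:
                    hu, core = _lesion_slice(
                        spec.image_shape, centre, r0 * _taper(step), axis_ratio, angle,
                        halo_amp, halo_phase, spec, rng_les,
                    )
                    masks[z] = core
                else:
                    hu = spec.background_hu + rng_les.normal(
                        0.0, spec.noise_sd * 400.0, size=spec.image_shape
                    )
                vox[z] = hu
            vol_id = f"{pid}_{lid}"
            volumes[vol_id] = CTVolume(
                vox,
                (spec.slice_thickness_mm, spec.pixel_spacing_mm, spec.pixel_spacing_mm),
                patient_id=pid,
            )
            ann_rows.append(
                {
                    "patient_id": pid,
                    "lesion_id": lid,
                    "volume_id": vol_id,
                    "central_slice": central,
                    "seed_row": int(round(centre[0])),
                    "seed_col": int(round(centre[1])),
                    "approx_diam_mm": round(2 * r0 * spec.pixel_spacing_mm, 1),
                    "extent_lo": central - half,
                    "extent_hi": central + half,
                }
            )
            lesion_masks[(pid, lid)] = masks
            lesion_centres[(pid, lid)] = (int(round(centre[0])), int(round(centre[1])))

    truth = GroundTruth(
        patient_class={pid: int(c) for pid, c in zip(patient_ids, classes)},
        lesion_masks=lesion_masks,
        lesion_centres=lesion_centres,
        survival_group={pid: ("high" if c == 1 else "low") for pid, c in zip(patient_ids, classes)},
    )
    return SyntheticCohort(
        volumes=volumes,
        annotations=pd.DataFrame(ann_rows),
        clinical=clinical,
        truth=truth,
        spec=spec,
    )


def generate_feature_table(
    n_per_class: int,
    n_features: int,
    informative: int,
    delta: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian two-class feature table: informative features are
    N(-delta/2, 1) vs N(+delta/2, 1) by class; the rest are N(0, 1).
    The theoretical single-feature AUC is Phi(delta / sqrt(2)).
    """
    if n_per_class < 1 or n_features < 1:
        raise ValueError("n_per_class and n_features must be positive")
    if informative > n_features:
        raise ValueError("informative must not exceed n_features")
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n_per_class)
    X = rng.normal(0.0, 1.0, size=(2 * n_per_class, n_features))
    shift = np.where(y == 1, delta / 2.0, -delta / 2.0)
    X[:, :informative] += shift[:, None]
    cols = [f"f{i:03d}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols), y
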