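"""2-D radiomic feature bank: shape, intensity, radial, texture and spectral
features computed per (axial slice, region) pair.

Every feature is registered with an explicit human-readable formula so that
values are reproducible and auditable. Headline features of the risk model:

* ``OD-CentroidDifference`` — distance between the intensity-weighted and
  geometric centroids, normalized by the equivalent radius sqrt(area/pi).
  A bright rim on one side of the region displaces the optical centroid.
* ``RadCentre`` — intensity-weighted mean of the normalized radial position
  r/r_boundary(theta) over mask pixels: 0 means the mass sits at the centre,
  1 means it sits at the rim.

All features are computed on the bounding-box crop of the mask, which makes
them exactly translation invariant. Quantization is fixed at build time
(16 histogram bins, 32 grey levels for co-occurrence) and recorded in the
registry metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from scipy.stats import skew, kurtosis
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops, moments_hu, perimeter

__all__ = [
    "FeatureDefinition",
    "REGIONS",
    "build_registry",
    "registry_names",
    "extract_features",
    "extract_lesion_stack",
    "to_wide",
    "QUANT_LEVELS_GLCM",
    "QUANT_BINS_HIST",
]

REGIONS = ("CORE", "COREEDGE", "RING")

QUANT_BINS_HIST = 16
QUANT_LEVELS_GLCM = 32
N_ANGLES = 360
FFT_PAD = 64

_GLCM_DISTANCES = (1, 2, 3)
_GLCM_ANGLE_NAMES = ("0", "45", "90", "135")
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
_GLCM_PROPS = ("contrast", "dissimilarity", "homogeneity", "energy", "correlation", "ASM")

_PERCENTILES = (5, 10, 25, 75, 90, 95)


@dataclass(frozen=True)
class FeatureDefinition:
    name: str
    family: str  # shape | intensity | radial | texture | spectral
    formula_doc: str


def _glcm_feature_name(d: int, ang: str, prop: str) -> str:
    # the vertical-offset correlation at distance 1 carries its legacy name
    if d == 1 and ang == "90" and prop == "correlation":
        return "V-Correlation"
    return f"GLCM-d{d}-a{ang}-{prop}"


def build_registry() -> dict[str, FeatureDefinition]:
    """The full feature registry, ordered; one entry per feature name."""
    defs: list[FeatureDefinition] = []

    def add(name: str, family: str, doc: str) -> None:
        defs.append(FeatureDefinition(name, family, doc))

    # --- first-order intensity statistics on masked values -------------
    add("Mean", "intensity", "mean of masked intensities")
    add("Median", "intensity", "median of masked intensities")
    add("SD", "intensity", "standard deviation (ddof=0)")
    add("TotalVariance", "intensity", "variance of masked intensities (ddof=0)")
    add("Skewness", "intensity", "Fisher skewness of masked intensities")
    add("Kurtosis", "intensity", "excess kurtosis of masked intensities")
    add("Entropy", "intensity", "Shannon entropy of the 16-bin histogram over [0,1], bits")
    add("Uniformity", "intensity", "sum of squared 16-bin histogram fractions")
    add("Energy", "intensity", "sum of squared masked intensities")
    add("RMS", "intensity", "root mean square of masked intensities")
    add("MAD", "intensity", "mean absolute deviation from the mean")
    add("Min", "intensity", "minimum masked intensity")
    add("Max", "intensity", "maximum masked intensity")
    add("Range", "intensity", "max - min")
    add("IQR", "intensity", "75th - 25th percentile")
    add("CoV", "intensity", "SD / |mean| (0 when mean is 0)")
    for p in _PERCENTILES:
        add(f"P{p}", "intensity", f"{p}th percentile of masked intensities")

    # --- grey-level occupancy ------------------------------------------
    for b in range(1, QUANT_BINS_HIST + 1):
        add(
            f"GrayLevel{b}",
            "intensity",
            f"fraction of masked pixels in bin {b} of a {QUANT_BINS_HIST}-bin "
            "equal-width histogram over [0,1]",
        )

    # --- binary shape ---------------------------------------------------
    add("Area", "shape", "pixel count of the mask")
    add("Perimeter", "shape", "skimage perimeter estimate of the mask")
    add("Circularity", "shape", "4*pi*Area / Perimeter^2")
    add("Solidity", "shape", "Area / convex hull area")
    add("Extent", "shape", "Area / bounding-box area")
    add("Eccentricity", "shape", "eccentricity of the binary second-moment ellipse")
    add("MajAxis", "shape", "major axis length of the binary-mask ellipse fit (px)")
    add("MinAxis", "shape", "minor axis length of the binary-mask ellipse fit (px)")
    add("EquivDiameter", "shape", "diameter of the circle with the mask's area")
    add("AspectRatio", "shape", "MajAxis / MinAxis")
    for k in range(1, 8):
        add(f"HuMoment{k}", "shape", f"log-scaled Hu invariant moment {k} of the binary mask")

    # --- radial boundary signature r(theta) -----------------------------
    rad_doc = (
        f"statistic of the boundary distance r(theta) from the geometric centroid, "
        f"sampled at {N_ANGLES} equal angles (outermost crossing, half-pixel corrected)"
    )
    add("MeanRadius", "radial", "mean of " + rad_doc)
    add("RadSD-Angle", "radial", "SD of " + rad_doc)
    add("RadVarianceAngle", "radial", "variance of " + rad_doc)
    add("RadSkewness-Angle", "radial", "skewness of " + rad_doc)
    add("RadKurtosis-Angle", "radial", "excess kurtosis of " + rad_doc)
    add("MinRadius", "radial", "minimum of " + rad_doc)
    add("MaxRadius", "radial", "maximum of " + rad_doc)
    add("RadRange", "radial", "max - min of r(theta)")
    add("RadCV", "radial", "SD/mean of r(theta)")
    add("RadEntropy-Angle", "radial", "entropy of the 16-bin histogram of r(theta)/max r")

    # --- intensity-weighted geometry ------------------------------------
    add(
        "OD-CentroidDifference",
        "radial",
        "||intensity-weighted centroid - geometric centroid|| / sqrt(area/pi)",
    )
    add(
        "RadCentre",
        "radial",
        "intensity-weighted mean of normalized radial position r/r_boundary(theta) "
        "over mask pixels (0 = mass at centre, 1 = mass at rim)",
    )
    add("ODEccentricity", "radial", "eccentricity of the intensity-weighted second-moment ellipse")
    add("OD-MajAxis", "radial", "major axis of the intensity-weighted ellipse fit (px)")
    add("OD-MinAxis", "radial", "minor axis of the intensity-weighted ellipse fit (px)")
    for k in range(1, 8):
        add(f"OD-HuMoment{k}", "radial", f"log-scaled Hu moment {k} of the masked intensity image")

    # --- grey-level co-occurrence ---------------------------------------
    for d in _GLCM_DISTANCES:
        for ang in _GLCM_ANGLE_NAMES:
            for prop in _GLCM_PROPS:
                add(
                    _glcm_feature_name(d, ang, prop),
                    "texture",
                    f"GLCM {prop} at distance {d}, angle {ang} deg, "
                    f"{QUANT_LEVELS_GLCM}-level quantization within the mask, symmetric",
                )

    # --- spectral --------------------------------------------------------
    for b in range(1, 5):
        add(
            f"FFT{b}",
            "spectral",
            f"fractional spectral energy in radial frequency band {b}/4 of the 2-D FFT "
            f"of the mask-cropped, zero-padded-to-{FFT_PAD}x{FFT_PAD} patch (DC excluded)",
        )
    add("SpectralCentroid", "spectral", "energy-weighted mean normalized frequency radius")
    add("SpectralEntropy", "spectral", "entropy of the 4-band fractional spectral energies")
    for band in ("LL", "LH", "HL", "HH"):
        for stat in ("Mean", "SD", "Energy"):
            add(
                f"Wavelet-{band}-{stat}",
                "spectral",
                f"{stat} of the Haar level-1 {band} sub-band of the padded patch",
            )

    # --- gradient --------------------------------------------------------
    add("GradMean", "texture", "mean Sobel gradient magnitude within the mask")
    add("GradSD", "texture", "SD of Sobel gradient magnitude within the mask")
    add("GradMax", "texture", "max Sobel gradient magnitude within the mask")
    add("GradSkewness", "texture", "skewness of Sobel gradient magnitude within the mask")
    add("LaplacianMean", "texture", "mean Laplacian response within the mask")
    add("LaplacianSD", "texture", "SD of Laplacian response within the mask")

    reg = {d.name: d for d in defs}
    if len(reg) != len(defs):  # pragma: no cover - registry construction guard
        raise RuntimeError("duplicate feature names in registry")
    return reg


_REGISTRY = build_registry()


def registry_names() -> list[str]:
    return list(_REGISTRY)


class MaskTooSmallError(ValueError):
    pass


def _safe(x: float) -> float:
    x = float(x)
    return x if np.isfinite(x) else 0.0


def _hist16(vals: np.ndarray) -> np.ndarray:
    clipped = np.clip(vals, 0.0, 1.0)
    hist, _ = np.histogram(clipped, bins=QUANT_BINS_HIST, range=(0.0, 1.0))
    return hist / max(1, len(vals))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


_RAY_STEP = 0.25


def _radial_signature(mask: np.ndarray) -> np.ndarray:
    """Boundary distance r(theta) at N_ANGLES equal angles from the geometric
    centroid: vectorized ray marching with nearest-neighbour mask lookup,
    taking the outermost in-mask sample per ray (+ half a step for the sample
    extent). Rays that never hit the mask (possible for strongly non-convex
    regions) fall back to the nearest pixel's radius in that direction."""
    rr, cc = np.nonzero(mask)
    cy, cx = rr.mean(), cc.mean()
    rmax = float(np.hypot(rr - cy, cc - cx).max()) + 1.0
    radii = np.arange(0.0, rmax + _RAY_STEP, _RAY_STEP)
    theta = np.linspace(-np.pi, np.pi, N_ANGLES, endpoint=False)
    ys = cy + np.outer(np.sin(theta), radii)
    xs = cx + np.outer(np.cos(theta), radii)
    iy = np.round(ys).astype(int)
    ix = np.round(xs).astype(int)
    inside = (
        (iy >= 0) & (iy < mask.shape[0]) & (ix >= 0) & (ix < mask.shape[1])
    )
    hit = np.zeros_like(inside)
    hit[inside] = mask[iy[inside], ix[inside]]
    any_hit = hit.any(axis=1)
    # outermost crossing: last in-mask sample along each ray
    last = hit.shape[1] - 1 - np.argmax(hit[:, ::-1], axis=1)
    sig = radii[last] + _RAY_STEP / 2.0
    if not any_hit.all():
        # fall back to the farthest mask pixel within the angular bin, or the
        # circularly nearest resolved angle
        sig[~any_hit] = np.nan
        idx = np.arange(N_ANGLES)
        filled = idx[any_hit]
        missing = idx[~any_hit]
        diffs = np.abs(missing[:, None] - filled[None, :])
        diffs = np.minimum(diffs, N_ANGLES - diffs)
        sig[missing] = sig[filled[np.argmin(diffs, axis=1)]]
    return sig


def _weighted_ellipse(rr: np.ndarray, cc: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """(eccentricity, major, minor) of the weighted second-moment ellipse,
    using the same 4*sqrt(eigenvalue) axis convention as regionprops."""
    wsum = w.sum()
    cy, cx = (w * rr).sum() / wsum, (w * cc).sum() / wsum
    dy, dx = rr - cy, cc - cx
    cyy = (w * dy * dy).sum() / wsum
    cxx = (w * dx * dx).sum() / wsum
    cxy = (w * dy * dx).sum() / wsum
    cov = np.array([[cyy, cxy], [cxy, cxx]])
    eigs = np.linalg.eigvalsh(cov)
    lam2, lam1 = max(eigs[0], 0.0), max(eigs[1], 0.0)
    ecc = np.sqrt(1.0 - lam2 / lam1) if lam1 > 0 else 0.0
    return float(ecc), float(4 * np.sqrt(lam1)), float(4 * np.sqrt(lam2))


def _log_hu(hu: np.ndarray) -> np.ndarray:
    return np.array([-np.sign(h) * np.log10(abs(h)) if h != 0 else 0.0 for h in hu])


def extract_features(
    image: np.ndarray, mask: np.ndarray, registry: dict[str, FeatureDefinition] | None = None
) -> dict[str, float]:
    """Compute every registered feature for one (slice image, region mask).

    The image is expected window-normalized to [0, 1]; intensity statistics
    use the raw passed values, occupancy/texture quantization clips to [0, 1].
    """
    if registry is None:
        registry = _REGISTRY
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask must share shape")
    npix = int(mask.sum())
    if npix < 8:
        raise MaskTooSmallError(f"mask too small: {npix} px (< 8), radial statistics undefined")

    # crop to the mask bounding box -> exact translation invariance
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    img = image[r0 : r1 + 1, c0 : c1 + 1]
    msk = mask[r0 : r1 + 1, c0 : c1 + 1]

    out: dict[str, float] = {}
    vals = img[msk]

    # first order
    mean = float(vals.mean())
    sd = float(vals.std())
    out["Mean"] = mean
    out["Median"] = float(np.median(vals))
    out["SD"] = sd
    out["TotalVariance"] = float(vals.var())
    out["Skewness"] = _safe(skew(vals)) if sd > 1e-12 else 0.0
    out["Kurtosis"] = _safe(kurtosis(vals)) if sd > 1e-12 else 0.0
    hist = _hist16(vals)
    out["Entropy"] = _entropy(hist)
    out["Uniformity"] = float((hist**2).sum())
    out["Energy"] = float((vals**2).sum())
    out["RMS"] = float(np.sqrt((vals**2).mean()))
    out["MAD"] = float(np.abs(vals - mean).mean())
    out["Min"] = float(vals.min())
    out["Max"] = float(vals.max())
    out["Range"] = out["Max"] - out["Min"]
    q25, q75 = np.percentile(vals, [25, 75])
    out["IQR"] = float(q75 - q25)
    out["CoV"] = sd / abs(mean) if mean != 0 else 0.0
    for p in _PERCENTILES:
        out[f"P{p}"] = float(np.percentile(vals, p))
    for b in range(1, QUANT_BINS_HIST + 1):
        out[f"GrayLevel{b}"] = float(hist[b - 1])

    # binary shape
    props = regionprops(msk.astype(np.uint8))[0]
    area = float(props.area)
    perim = float(perimeter(msk))
    out["Area"] = area
    out["Perimeter"] = perim
    out["Circularity"] = 4 * np.pi * area / perim**2 if perim > 0 else 1.0
    out["Solidity"] = float(props.solidity)
    out["Extent"] = float(props.extent)
    out["Eccentricity"] = float(props.eccentricity)
    out["MajAxis"] = float(props.axis_major_length)
    out["MinAxis"] = float(props.axis_minor_length)
    out["EquivDiameter"] = float(props.equivalent_diameter_area)
    out["AspectRatio"] = (
        out["MajAxis"] / out["MinAxis"] if out["MinAxis"] > 0 else 1.0
    )
    hu = _log_hu(moments_hu(props.moments_central / props.moments_central[0, 0]))
    for k in range(1, 8):
        out[f"HuMoment{k}"] = _safe(hu[k - 1])

    # radial boundary signature
    sig = _radial_signature(msk)
    out["MeanRadius"] = float(sig.mean())
    out["RadSD-Angle"] = float(sig.std())
    out["RadVarianceAngle"] = float(sig.var())
    out["RadSkewness-Angle"] = _safe(skew(sig)) if sig.std() > 1e-12 else 0.0
    out["RadKurtosis-Angle"] = _safe(kurtosis(sig)) if sig.std() > 1e-12 else 0.0
    out["MinRadius"] = float(sig.min())
    out["MaxRadius"] = float(sig.max())
    out["RadRange"] = out["MaxRadius"] - out["MinRadius"]
    out["RadCV"] = out["RadSD-Angle"] / out["MeanRadius"] if out["MeanRadius"] > 0 else 0.0
    rhist, _ = np.histogram(sig / sig.max(), bins=16, range=(0, 1))
    out["RadEntropy-Angle"] = _entropy(rhist / len(sig))

    # intensity-weighted geometry
    rr, cc = np.nonzero(msk)
    w = np.clip(img[msk], 0.0, None)
    cy, cx = rr.mean(), cc.mean()
    if w.sum() > 0:
        wy, wx = (w * rr).sum() / w.sum(), (w * cc).sum() / w.sum()
    else:
        w = np.ones_like(w)
        wy, wx = cy, cx
    eq_radius = np.sqrt(area / np.pi)
    out["OD-CentroidDifference"] = float(np.hypot(wy - cy, wx - cx) / eq_radius)
    theta_pix = np.arctan2(rr - cy, cc - cx)
    bins_pix = ((theta_pix + np.pi) / (2 * np.pi) * N_ANGLES).astype(int) % N_ANGLES
    r_pix = np.hypot(rr - cy, cc - cx)
    r_norm = r_pix / sig[bins_pix]
    out["RadCentre"] = float((w * r_norm).sum() / w.sum())
    ecc, odmaj, odmin = _weighted_ellipse(rr, cc, w)
    out["ODEccentricity"] = ecc
    out["OD-MajAxis"] = odmaj
    out["OD-MinAxis"] = odmin
    wimg = np.where(msk, np.clip(img, 0.0, None), 0.0)
    if wimg.sum() > 0:
        m = _image_central_moments(wimg)
        odhu = _log_hu(moments_hu(m / m[0, 0]))
    else:
        odhu = np.zeros(7)
    for k in range(1, 8):
        out[f"OD-HuMoment{k}"] = _safe(odhu[k - 1])

    # GLCM
    q = np.zeros(msk.shape, dtype=np.uint8)
    levels = np.clip((np.clip(img, 0.0, 1.0) * QUANT_LEVELS_GLCM).astype(int), 0, QUANT_LEVELS_GLCM - 1)
    q[msk] = levels[msk] + 1  # 0 reserved for background
    glcm = graycomatrix(
        q,
        distances=_GLCM_DISTANCES,
        angles=_GLCM_ANGLES,
        levels=QUANT_LEVELS_GLCM + 1,
        symmetric=True,
        normed=False,
    )
    glcm = glcm[1:, 1:, :, :].astype(float)  # drop background co-occurrences
    sums = glcm.sum(axis=(0, 1), keepdims=True)
    sums[sums == 0] = 1.0
    glcm /= sums
    for prop in _GLCM_PROPS:
        with np.errstate(divide="ignore", invalid="ignore"):
            table = graycoprops(glcm, prop)
        for i, d in enumerate(_GLCM_DISTANCES):
            for j, ang in enumerate(_GLCM_ANGLE_NAMES):
                out[_glcm_feature_name(d, ang, prop)] = _safe(table[i, j])

    # spectral
    patch = np.where(msk, img, 0.0)
    side = max(FFT_PAD, patch.shape[0], patch.shape[1])
    padded = np.zeros((side, side))
    padded[: patch.shape[0], : patch.shape[1]] = patch
    spec = np.abs(np.fft.fftshift(np.fft.fft2(padded))) ** 2
    centre = side // 2
    yy, xx = np.indices(spec.shape)
    rho = np.hypot(yy - centre, xx - centre) / (side / 2.0)
    spec[centre, centre] = 0.0  # exclude DC
    edges = [0.0, 0.25, 0.5, 0.75, np.inf]
    band_e = np.array(
        [spec[(rho >= edges[i]) & (rho < edges[i + 1])].sum() for i in range(4)]
    )
    total = band_e.sum()
    frac = band_e / total if total > 0 else np.zeros(4)
    for b in range(1, 5):
        out[f"FFT{b}"] = float(frac[b - 1])
    out["SpectralCentroid"] = float((spec * rho).sum() / total) if total > 0 else 0.0
    out["SpectralEntropy"] = _entropy(frac)
    coeffs = pywt.dwt2(padded, "haar")
    for band, arr in zip(("LL", "LH", "HL", "HH"), (coeffs[0],) + coeffs[1]):
        out[f"Wavelet-{band}-Mean"] = float(arr.mean())
        out[f"Wavelet-{band}-SD"] = float(arr.std())
        out[f"Wavelet-{band}-Energy"] = float((arr**2).sum())

    # gradient
    gy = ndimage.sobel(img, axis=0)
    gx = ndimage.sobel(img, axis=1)
    gmag = np.hypot(gy, gx)[msk]
    out["GradMean"] = float(gmag.mean())
    out["GradSD"] = float(gmag.std())
    out["GradMax"] = float(gmag.max())
    out["GradSkewness"] = _safe(skew(gmag)) if gmag.std() > 1e-12 else 0.0
    lap = ndimage.laplace(img)[msk]
    out["LaplacianMean"] = float(lap.mean())
    out["LaplacianSD"] = float(lap.std())

    missing = set(registry) - set(out)
    if missing:  # pragma: no cover - registry/extractor consistency guard
        raise RuntimeError(f"extractor missed registered features: {sorted(missing)[:5]}")
    return {name: out[name] for name in registry}


def _image_central_moments(img: np.ndarray) -> np.ndarray:
    """Raw-image central moments up to order 3 (for weighted Hu invariants)."""
    yy, xx = np.indices(img.shape, dtype=float)
    m00 = img.sum()
    cy, cx = (img * yy).sum() / m00, (img * xx).sum() / m00
    mu = np.zeros((4, 4))
    dy, dx = yy - cy, xx - cx
    for p in range(4):
        for q in range(4):
            if p + q <= 3:
                mu[p, q] = (img * dy**p * dx**q).sum()
    return mu


def extract_lesion_stack(
    volume,
    triplets: dict[int, "object"],
    slice_indices: list[int],
    patient_id: str = "",
    lesion_id: str = "",
) -> pd.DataFrame:
    """Extract all features for every (selected slice, region) of one lesion.

    Returns a long-format table with one row per (slice, region); slices
    without a mask triplet are recorded as skipped via a warning, not
    silently dropped.
    """
    import warnings

    rows = []
    voxels = volume.voxels if hasattr(volume, "voxels") else np.asarray(volume)
    for s in slice_indices:
        trip = triplets.get(s)
        if trip is None:
            warnings.warn(f"no mask for slice {s} of lesion {lesion_id}; skipped", stacklevel=2)
            continue
        image = voxels[s]
        for region, mask in (
            ("CORE", trip.core),
            ("COREEDGE", trip.core_plus_edge),
            ("RING", trip.ring),
        ):
            feats = extract_features(image, mask)
            rows.append(
                {"patient_id": patient_id, "lesion_id": lesion_id, "slice_index": s, "region": region}
                | feats
            )
    return pd.DataFrame(rows)


def to_wide(long_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long table to one row per (patient, lesion, slice) with
    ``<feature>_<REGION>`` columns."""
    ids = ["patient_id", "lesion_id", "slice_index"]
    feature_cols = [c for c in long_df.columns if c not in ids + ["region"]]
    wide = long_df.pivot_table(
        index=ids, columns="region", values=feature_cols, aggfunc="first", sort=False
    )
    wide.columns = [f"{feat}_{region}" for feat, region in wide.columns]
    return wide.reset_index()
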