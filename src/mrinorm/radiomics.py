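"""Radiomic feature extraction: 197 features in 10 classes.

The taxonomy matches the standard reference feature set: six texture-matrix
families (GLCM, GLDZM, GLRLM, GLSZM, NGLDM, NGTDM — 136 features) and four
intensity families (intensity-based statistics, intensity histogram,
intensity-volume histogram, local intensity — 61 features).

Per-class counts, fixed for every input including degenerate ones:

=====================  =====
GLCM (25 base x 2D/3D)    50
GLRLM (16 base x 2D/3D)   32
GLSZM                     16
GLDZM                     16
NGLDM                     17
NGTDM                      5
IntensityStats            18
IntensityHistogram        23
IntensityVolumeHistogram  18
LocalIntensity             2
total                    197
=====================  =====

Matrix features are computed on a fixed-bin-number discretization of the
within-mask intensity range (default 32 bins). GLCM and GLRLM carry two
aggregations each: per-slice merged-direction matrices averaged over slices
(``2D``) and a single matrix merged over all 13 3D directions (``3D``).
Features whose value is mathematically undefined on a given input are
reported as NaN and listed in ``FeatureVector.undefined`` — never dropped,
so the vector length is always 197.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal, stats

from .image_io import Volume3D
from . import texture
from .texture import (
    DIRECTIONS_2D, DIRECTIONS_3D, GLCM_FEATURE_NAMES,
    glcm_features, merged_cooccurrence, run_length_matrix,
    size_zone_matrix, distance_zone_matrix, dependence_matrix,
    gray_tone_difference, szm_style_features, ngldm_features, ngtdm_features,
    cooccurrence_matrix, texture_matrices,
)

__all__ = [
    "ExtractionConfig",
    "FeatureVector",
    "FEATURE_CLASSES",
    "CLASS_COUNTS",
    "TEXTURE_CLASSES",
    "INTENSITY_CLASSES",
    "discretize",
    "extract_features",
    "feature_names",
]

TEXTURE_CLASSES = ("GLCM", "GLDZM", "GLRLM", "GLSZM", "NGLDM", "NGTDM")
INTENSITY_CLASSES = ("IntensityStats", "IntensityHistogram",
                     "IntensityVolumeHistogram", "LocalIntensity")
FEATURE_CLASSES = TEXTURE_CLASSES + INTENSITY_CLASSES

CLASS_COUNTS = {
    "GLCM": 50, "GLDZM": 16, "GLRLM": 32, "GLSZM": 16, "NGLDM": 17, "NGTDM": 5,
    "IntensityStats": 18, "IntensityHistogram": 23,
    "IntensityVolumeHistogram": 18, "LocalIntensity": 2,
}


@dataclass(frozen=True)
class ExtractionConfig:
    """Discretization and aggregation settings, snapshotted into every
    feature vector so results are only compared within identical configs."""

    n_bins: int = 32
    glcm_symmetric: bool = True
    ngldm_alpha: int = 0
    #: radius of the intensity-peak sphere in mm (a 1 cm^3 sphere)
    peak_radius_mm: float = 6.2035
    #: volume-fraction / intensity-fraction deciles for the IVH features
    ivh_fractions: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90)

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")


@dataclass
class FeatureVector:
    """One subject's 197 named features with class labels and config."""

    subject_id: str
    features: dict[str, float]
    class_of: dict[str, str]
    undefined: set[str] = field(default_factory=set)
    extraction_config: dict = field(default_factory=dict)

    def by_class(self, cls: str) -> dict[str, float]:
        return {k: v for k, v in self.features.items() if self.class_of[k] == cls}

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in FEATURE_CLASSES}
        for k in self.features:
            counts[self.class_of[k]] += 1
        return counts

    def n_texture(self) -> int:
        return sum(n for c, n in self.class_counts().items() if c in TEXTURE_CLASSES)

    def n_intensity(self) -> int:
        return sum(n for c, n in self.class_counts().items() if c in INTENSITY_CLASSES)


def discretize(vol: Volume3D, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Fixed-bin-number discretization of the within-mask range.

    Returns an integer array with levels 1..n_bins inside the mask and 0
    outside; the within-mask minimum maps to level 1 and the maximum to
    ``n_bins``. A constant region (max == min) is an error.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    mask = np.asarray(mask) > 0.5
    if not mask.any():
        raise ValueError("mask is empty")
    vals = vol.data[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if n_bins > 1 and hi <= lo:
        raise ValueError("constant region: cannot discretize max == min")
    levels = np.zeros(vol.shape, dtype=np.int64)
    if n_bins == 1 or hi <= lo:
        levels[mask] = 1
        return levels
    lv = np.floor(n_bins * (vol.data[mask] - lo) / (hi - lo)).astype(np.int64) + 1
    levels[mask] = np.clip(lv, 1, n_bins)
    return levels


# ---------------------------------------------------------------------------
# intensity families
# ---------------------------------------------------------------------------

def _dispersion_stats(v: np.ndarray) -> dict[str, float]:
    """Shared location/spread block for raw and histogram intensities."""
    n = v.size
    mean = float(np.mean(v))
    var = float(np.var(v, ddof=1)) if n >= 2 else float("nan")
    sd = math.sqrt(var) if var == var and var >= 0 else float("nan")
    p10, q1, med, q3, p90 = (float(np.percentile(v, q)) for q in (10, 25, 50, 75, 90))
    robust = v[(v >= p10) & (v <= p90)]
    out = {
        "mean": mean,
        "variance": var,
        "skewness": float(stats.skew(v, bias=True)) if n >= 3 and var > 0 else float("nan"),
        "kurtosis": (float(stats.kurtosis(v, fisher=False, bias=True))
                     if n >= 4 and var > 0 else float("nan")),
        "median": med,
        "minimum": float(v.min()),
        "percentile10": p10,
        "percentile90": p90,
        "maximum": float(v.max()),
        "interquartile_range": q3 - q1,
        "range": float(v.max() - v.min()),
        "mean_absolute_deviation": float(np.mean(np.abs(v - mean))),
        "robust_mean_absolute_deviation": (
            float(np.mean(np.abs(robust - robust.mean()))) if robust.size else float("nan")),
        "median_absolute_deviation": float(np.mean(np.abs(v - med))),
        "coefficient_of_variation": sd / mean if mean != 0 and sd == sd else float("nan"),
        "quartile_coefficient_of_dispersion": (
            (q3 - q1) / (q3 + q1) if (q3 + q1) != 0 else float("nan")),
    }
    return out


def intensity_statistics(vals: np.ndarray) -> dict[str, float]:
    """18 intensity-based statistics on the raw within-mask values."""
    f = _dispersion_stats(vals)
    f["energy"] = float(np.sum(vals ** 2))
    f["root_mean_square"] = float(np.sqrt(np.mean(vals ** 2)))
    return f


def intensity_histogram_features(levels_in_mask: np.ndarray, n_bins: int
                                 ) -> dict[str, float]:
    """23 discretized-histogram features on levels 1..n_bins."""
    v = levels_in_mask.astype(np.float64)
    f = _dispersion_stats(v)
    hist = np.bincount(levels_in_mask.astype(np.int64), minlength=n_bins + 1)[1:]
    p = hist / hist.sum()
    f["mode"] = float(np.argmax(hist) + 1)  # lowest level on ties
    pos = p[p > 0]
    f["entropy"] = float(-(pos * np.log2(pos)).sum())
    f["uniformity"] = float((p ** 2).sum())
    grad = np.gradient(hist.astype(np.float64)) if n_bins > 1 else np.zeros(1)
    f["maximum_gradient"] = float(grad.max())
    f["maximum_gradient_level"] = float(np.argmax(grad) + 1)
    f["minimum_gradient"] = float(grad.min())
    f["minimum_gradient_level"] = float(np.argmin(grad) + 1)
    return f


def intensity_volume_histogram(vals: np.ndarray, fractions) -> dict[str, float]:
    """18 intensity-volume-histogram features: the volume fraction of voxels
    at or above each fractional intensity decile, and the intensity reached
    by each fractional volume decile."""
    lo, hi = float(vals.min()), float(vals.max())
    f: dict[str, float] = {}
    for x in fractions:
        if hi > lo:
            thr = lo + (x / 100.0) * (hi - lo)
            f[f"volume_fraction_at_intensity_{x}"] = float(np.mean(vals >= thr))
        else:
            f[f"volume_fraction_at_intensity_{x}"] = 1.0
    for x in fractions:
        f[f"intensity_at_volume_{x}"] = float(np.percentile(vals, 100 - x))
    return f


def _sphere_kernel(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    r = [max(1, int(math.floor(radius_mm / s))) for s in spacing]
    grids = np.meshgrid(*[np.arange(-n, n + 1) * s for n, s in zip(r, spacing)],
                        indexing="ij")
    d2 = sum(g ** 2 for g in grids)
    return (d2 <= radius_mm ** 2).astype(np.float64)


def local_intensity_features(vol: Volume3D, mask: np.ndarray,
                             radius_mm: float) -> dict[str, float]:
    """Local and global intensity peak: the mean intensity in a 1 cm^3
    sphere centred on the brightest mask voxel (mean over ties), and the
    maximum sphere-mean over all mask voxels. The sphere may extend beyond
    the mask; only in-image voxels contribute."""
    mask = np.asarray(mask) > 0.5
    kern = _sphere_kernel(radius_mm, vol.spacing_mm)
    num = signal.fftconvolve(vol.data, kern, mode="same")
    den = signal.fftconvolve(np.ones_like(vol.data), kern, mode="same")
    sphere_mean = num / np.maximum(den, 1e-12)
    inmask_vals = vol.data[mask]
    peak_voxels = mask & (vol.data == inmask_vals.max())
    return {
        "local_intensity_peak": float(np.mean(sphere_mean[peak_voxels])),
        "global_intensity_peak": float(np.max(sphere_mean[mask])),
    }


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _slice_averaged(levels: np.ndarray, n_levels: int, builder) -> dict[str, float]:
    """Average per-slice feature dicts over slices with valid matrices."""
    per_slice: list[dict[str, float]] = []
    for k in range(levels.shape[2]):
        sl = levels[:, :, k][:, :, None]
        if not (sl > 0).any():
            continue
        feats = builder(sl)
        if feats is not None:
            per_slice.append(feats)
    if not per_slice:
        return {}
    keys = per_slice[0].keys()
    out = {}
    for k in keys:
        col = np.array([d[k] for d in per_slice])
        finite = col[np.isfinite(col)]
        out[k] = float(finite.mean()) if finite.size else float("nan")
    return out


def extract_features(vol: Volume3D, mask: np.ndarray,
                     config: ExtractionConfig | None = None,
                     subject_id: str = "") -> FeatureVector:
    """Extract the full 197-feature vector for one volume + mask.

    A constant-intensity region cannot be discretized; its matrix features
    are computed on a single-level image and the mathematically undefined
    ones (correlation, coarseness, ...) come back NaN-flagged, preserving
    the count.
    """
    config = config or ExtractionConfig()
    mask = np.asarray(mask) > 0.5
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = vol.data[mask]
    constant = float(vals.max()) <= float(vals.min())

    if constant:
        levels = np.zeros(vol.shape, dtype=np.int64)
        levels[mask] = 1
        n_levels = 1
    else:
        levels = discretize(vol, mask, config.n_bins)
        n_levels = config.n_bins
    n_vox = int(mask.sum())

    feats: dict[str, float] = {}
    class_of: dict[str, str] = {}

    def add(cls: str, prefix: str, d: dict[str, float], expected: list[str]) -> None:
        for name in expected:
            key = f"{prefix}_{name}"
            feats[key] = float(d.get(name, float("nan")))
            class_of[key] = cls

    # --- intensity families -------------------------------------------------
    add("IntensityStats", "stat", intensity_statistics(vals),
        list(intensity_statistics(np.array([0.0, 1.0, 2.0, 4.0])).keys()))
    add("IntensityHistogram", "ih",
        intensity_histogram_features(levels[mask], n_levels),
        list(intensity_histogram_features(np.array([1, 2, 2, 3]), 3).keys()))
    add("IntensityVolumeHistogram", "ivh",
        intensity_volume_histogram(vals, config.ivh_fractions),
        list(intensity_volume_histogram(np.array([0.0, 1.0]), config.ivh_fractions).keys()))
    add("LocalIntensity", "li",
        local_intensity_features(vol, mask, config.peak_radius_mm),
        ["local_intensity_peak", "global_intensity_peak"])

    # --- GLCM: 2D slice-averaged + 3D merged --------------------------------
    def glcm_2d(sl):
        P = merged_cooccurrence(sl, n_levels, DIRECTIONS_2D, config.glcm_symmetric)
        return glcm_features(P) if P is not None else None

    add("GLCM", "glcm_2D", _slice_averaged(levels, n_levels, glcm_2d),
        GLCM_FEATURE_NAMES)
    P3 = merged_cooccurrence(levels, n_levels, DIRECTIONS_3D, config.glcm_symmetric)
    add("GLCM", "glcm_3D", glcm_features(P3) if P3 is not None else {},
        GLCM_FEATURE_NAMES)

    # --- GLRLM: 2D slice-averaged + 3D merged -------------------------------
    rlm_names = [s.format(ax="run", axlong="run_length") for s in texture.SZM_SUFFIXES]

    def rlm_2d(sl):
        M = run_length_matrix(sl, n_levels, DIRECTIONS_2D)
        nv = int((sl > 0).sum())
        return szm_style_features(M, nv, "run", "run_length") if M.sum() else None

    add("GLRLM", "glrlm_2D", _slice_averaged(levels, n_levels, rlm_2d), rlm_names)
    M3 = run_length_matrix(levels, n_levels, DIRECTIONS_3D)
    add("GLRLM", "glrlm_3D", szm_style_features(M3, n_vox, "run", "run_length"),
        rlm_names)

    # --- GLSZM / GLDZM -------------------------------------------------------
    szm_names = [s.format(ax="zone", axlong="zone_size") for s in texture.SZM_SUFFIXES]
    add("GLSZM", "glszm",
        szm_style_features(size_zone_matrix(levels, n_levels), n_vox, "zone", "zone_size"),
        szm_names)
    dzm_names = [s.format(ax="zone", axlong="zone_distance") for s in texture.SZM_SUFFIXES]
    add("GLDZM", "gldzm",
        szm_style_features(distance_zone_matrix(levels, n_levels), n_vox,
                           "zone", "zone_distance"),
        dzm_names)

    # --- NGLDM / NGTDM -------------------------------------------------------
    add("NGLDM", "ngldm",
        ngldm_features(dependence_matrix(levels, n_levels, config.ngldm_alpha), n_vox),
        texture.NGLDM_FEATURE_NAMES)
    s, n = gray_tone_difference(levels, n_levels)
    add("NGTDM", "ngtdm", ngtdm_features(s, n), texture.NGTDM_FEATURE_NAMES)

    undefined = {k for k, v in feats.items() if not np.isfinite(v)}
    return FeatureVector(subject_id=subject_id, features=feats, class_of=class_of,
                         undefined=undefined, extraction_config=asdict(config))


def feature_names(config: ExtractionConfig | None = None) -> list[str]:
    """The fixed, ordered list of 197 feature names."""
    vol = Volume3D(np.arange(64, dtype=np.float64).reshape(4, 4, 4))
    mask = np.ones((4, 4, 4), dtype=np.uint8)
    return list(extract_features(vol, mask, config or ExtractionConfig(n_bins=4)).features)
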