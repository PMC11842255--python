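"""The seven intensity-normalization operators.

Each operator rescales a whole volume using statistics drawn from a stated
region:

================  ==========================================================
method            output voxel
================  ==========================================================
unnormalized      v (identity)
sd_mask           v / sd(mask)
zscore_mask       (v - mean(mask)) / sd(mask)
minmax            (v - min) / (max - min), whole-volume extrema
scaled            v / max, whole-volume maximum
roi_mean          v / mean(roi) for a named reference ROI (bladder, muscle,
                  CSF, tumor, sternum, thorax, ...)
================  ==========================================================

All statistics use the sample (n-1) standard deviation. The transform is
applied to every voxel, background included; only the statistics come from
the stated region. Degenerate inputs (empty mask, zero spread, zero ROI
mean) raise :class:`DegenerateInputError` — no silent NaN/Inf propagation.

``minmax`` and ``scaled`` default to whole-volume extrema; masked variants
are available through ``mask_extrema=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image_io import Volume3D, MaskSet

__all__ = [
    "NormalizationMethod",
    "DegenerateInputError",
    "METHOD_NAMES",
    "unnormalized",
    "sd_mask",
    "zscore_mask",
    "minmax",
    "scaled",
    "roi_mean_normalize",
    "harmonize_units",
    "apply_method",
]

METHOD_NAMES = ("unnormalized", "sd_mask", "zscore_mask", "minmax", "scaled", "roi_mean")


class DegenerateInputError(ValueError):
    """Raised when a normalization statistic is undefined (empty region,
    zero spread, zero reference mean)."""


@dataclass(frozen=True)
class NormalizationMethod:
    """A method name plus, for ``roi_mean``, the reference ROI to use."""

    name: str
    roi_name: str | None = None

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValueError(f"unknown method '{self.name}'; choose from {METHOD_NAMES}")
        if self.name == "roi_mean" and not self.roi_name:
            raise ValueError("roi_mean requires roi_name")

    @property
    def label(self) -> str:
        return f"roi_mean[{self.roi_name}]" if self.name == "roi_mean" else self.name


def _mask_values(vol: Volume3D, mask: np.ndarray, what: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != vol.shape:
        raise ValueError(f"{what} shape {mask.shape} != volume shape {vol.shape}")
    vals = vol.data[mask > 0.5]
    if vals.size == 0:
        raise DegenerateInputError(f"{what} is empty")
    return vals


def unnormalized(vol: Volume3D) -> Volume3D:
    return vol


def sd_mask(vol: Volume3D, organ_mask: np.ndarray) -> Volume3D:
    """Divide every voxel by the within-mask sample SD."""
    vals = _mask_values(vol, organ_mask, "organ mask")
    if vals.size < 2:
        raise DegenerateInputError("organ mask needs >= 2 voxels for an SD")
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise DegenerateInputError("within-mask SD is zero (constant region)")
    return vol.with_data(vol.data / sd)


def zscore_mask(vol: Volume3D, organ_mask: np.ndarray) -> Volume3D:
    """Subtract the within-mask mean and divide by the within-mask sample SD.

    Applied to every voxel; afterwards the within-mask mean is 0 and the
    within-mask SD is 1 to float tolerance. Invariant to any positive affine
    transform of the input — the property that removes scanner gain/offset.
    """
    vals = _mask_values(vol, organ_mask, "organ mask")
    if vals.size < 2:
        raise DegenerateInputError("organ mask needs >= 2 voxels for a z-score")
    mu = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise DegenerateInputError("within-mask SD is zero (constant region)")
    return vol.with_data((vol.data - mu) / sd)


def minmax(vol: Volume3D, mask: np.ndarray | None = None,
           mask_extrema: bool = False) -> Volume3D:
    """Map intensities to [0, 1] by (v - min) / (max - min)."""
    if mask_extrema:
        vals = _mask_values(vol, mask, "mask")
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = float(vol.data.min()), float(vol.data.max())
    if hi <= lo:
        raise DegenerateInputError("constant volume: max == min")
    return vol.with_data((vol.data - lo) / (hi - lo))


def scaled(vol: Volume3D, mask: np.ndarray | None = None,
           mask_extrema: bool = False) -> Volume3D:
    """Divide every voxel by the maximum intensity."""
    if mask_extrema:
        hi = float(_mask_values(vol, mask, "mask").max())
    else:
        hi = float(vol.data.max())
    if hi <= 0:
        raise DegenerateInputError(f"maximum intensity {hi} is not positive")
    return vol.with_data(vol.data / hi)


def roi_mean_normalize(vol: Volume3D, roi: np.ndarray,
                       roi_name: str = "roi") -> Volume3D:
    """Divide every voxel by the mean intensity of a reference ROI."""
    vals = _mask_values(vol, roi, f"ROI '{roi_name}'")
    mu = float(np.mean(vals))
    if mu == 0:
        raise DegenerateInputError(f"ROI '{roi_name}' has zero mean")
    return vol.with_data(vol.data / mu)


def harmonize_units(vol: Volume3D, target_magnitude: float,
                    mask: np.ndarray | None = None) -> tuple[Volume3D, int]:
    """Rescale by a power of ten so the (within-mask) median magnitude matches
    ``target_magnitude``.

    Returns the rescaled volume and the integer exponent k with output =
    input * 10^k. Intended for quantitative maps (ADC) stored in
    inconsistent units across sites. Applying twice is idempotent (the
    second k is 0).
    """
    data = vol.data if mask is None else vol.data[np.asarray(mask) > 0.5]
    med = float(np.median(np.abs(data)))
    if med == 0:
        raise DegenerateInputError("median absolute intensity is zero")
    if target_magnitude <= 0:
        raise ValueError(f"target_magnitude must be positive, got {target_magnitude}")
    k = int(round(math.log10(target_magnitude) - math.log10(med)))
    if k == 0:
        return vol, 0
    return vol.with_data(vol.data * (10.0 ** k)), k


def apply_method(method: NormalizationMethod, vol: Volume3D,
                 masks: MaskSet) -> Volume3D:
    """Dispatch one :class:`NormalizationMethod` on a volume + mask set."""
    if method.name == "unnormalized":
        return unnormalized(vol)
    if method.name == "sd_mask":
        return sd_mask(vol, masks.require_nonempty("organ"))
    if method.name == "zscore_mask":
        return zscore_mask(vol, masks.require_nonempty("organ"))
    if method.name == "minmax":
        return minmax(vol)
    if method.name == "scaled":
        return scaled(vol)
    if method.name == "roi_mean":
        roi = masks.require_nonempty(method.roi_name)  # type: ignore[arg-type]
        return roi_mean_normalize(vol, roi, method.roi_name)  # type: ignore[arg-type]
    raise ValueError(f"unknown method {method.name}")
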