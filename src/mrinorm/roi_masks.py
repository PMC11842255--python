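"""Programmatic reference-ROI construction.

Two constructions are supported: a circular ROI drawn on a single slice
(the bladder / levator-ani style reference region, default radius 10
voxels) and a fluid mask obtained by thresholding an apparent-diffusion-
coefficient (ADC) map for high-diffusion voxels (the CSF reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image_io import Volume3D, GridMismatchError

__all__ = ["CircleSpec", "circular_roi", "csf_mask_from_adc", "EmptyMaskWarning"]

#: Free water diffuses at ~3e-3 mm^2/s while parenchyma sits below 1e-3, so
#: 2e-3 mm^2/s separates fluid from tissue with margin on both sides.
DEFAULT_ADC_THRESHOLD = 2.0e-3


class EmptyMaskWarning(UserWarning):
    """Emitted when a threshold-derived ROI comes out empty."""


@dataclass(frozen=True)
class CircleSpec:
    """A circle on one axial slice, in voxel coordinates.

    ``radius_voxels`` uses the closed-disk rule: voxel (x, y) belongs to the
    ROI iff (x-cx)^2 + (y-cy)^2 <= r^2.
    """

    slice_index: int
    center: tuple[float, float]
    radius_voxels: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_voxels < 0:
            raise ValueError(f"radius_voxels must be >= 0, got {self.radius_voxels}")


def circular_roi(spec: CircleSpec, reference: Volume3D) -> np.ndarray:
    """Rasterize a closed-disk circular ROI on one slice of the reference grid.

    The slice index addresses the third (axial) axis. A circle that would
    exceed the in-plane image bounds is an error, never silently clipped.
    """
    nx, ny, nz = reference.shape
    k = spec.slice_index
    if not (0 <= k < nz):
        raise ValueError(f"slice_index {k} outside volume extent [0, {nz})")
    cx, cy = spec.center
    r = spec.radius_voxels
    if cx - r < 0 or cy - r < 0 or cx + r > nx - 1 or cy + r > ny - 1:
        raise ValueError(
            f"circle center {spec.center} radius {r} exceeds slice bounds "
            f"({nx} x {ny}); refusing to clip")
    xs, ys = np.indices((nx, ny), dtype=np.float64)
    disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
    mask = np.zeros(reference.shape, dtype=np.uint8)
    mask[:, :, k] = disk.astype(np.uint8)
    return mask


def csf_mask_from_adc(adc: Volume3D, brain_mask: np.ndarray,
                      threshold: float = DEFAULT_ADC_THRESHOLD
                      ) -> tuple[np.ndarray, int]:
    """Fluid mask: ADC strictly above threshold, restricted to the brain mask.

    Returns the binary mask and its voxel count. An empty result emits
    :class:`EmptyMaskWarning` (downstream ROI-mean normalization by an empty
    mask fails loudly rather than silently).
    """
    brain_mask = np.asarray(brain_mask)
    if brain_mask.shape != adc.shape:
        raise GridMismatchError(
            f"brain_mask shape {brain_mask.shape} != ADC shape {adc.shape}")
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    mask = ((adc.data > threshold) & (brain_mask > 0.5)).astype(np.uint8)
    count = int(mask.sum())
    if count == 0:
        warnings.warn(
            f"CSF mask empty at ADC threshold {threshold}", EmptyMaskWarning,
            stacklevel=2)
    return mask, count
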