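"""NIfTI volume and mask I/O with one internal grid convention.

All images are held in memory as float64 RAS-oriented arrays with voxel
spacing in millimetres; volumes are written to disk as float32 and masks as
uint8. No resampling is ever performed silently: grids either match (to a
small spacing tolerance) or the operation fails with a typed error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "MaskSet",
    "ImageIOError",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

#: Maximum per-axis spacing discrepancy (mm) tolerated before two grids are
#: declared mismatched.
SPACING_TOL_MM = 1e-4


class ImageIOError(ValueError):
    """Raised for unreadable, non-3D or non-finite image inputs."""


class GridMismatchError(ImageIOError):
    """Raised when a mask or second volume does not share the reference grid."""


@dataclass
class Volume3D:
    """One 3D scalar image.

    Parameters
    ----------
    data
        3D array of finite reals (held as float64).
    spacing_mm
        Voxel spacing along each axis, strictly positive, in mm.
    orientation
        Axis-label triple; the internal convention is RAS.
    units
        Free-text intensity-unit label (e.g. ``"a.u."`` or ``"mm^2/s"``).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: tuple[str, str, str] = ("R", "A", "S")
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ImageIOError(
                f"expected 3D volume, got {self.data.ndim}D with shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ImageIOError("volume contains NaN/Inf voxels")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)  # type: ignore[assignment]
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ImageIOError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Return a copy of this volume carrying new voxel data on the same grid."""
        return Volume3D(np.asarray(data, dtype=np.float64), self.spacing_mm,
                        self.orientation, self.units)

    def same_grid(self, other: "Volume3D", tol_mm: float = SPACING_TOL_MM) -> bool:
        return (self.shape == other.shape
                and all(abs(a - b) <= tol_mm
                        for a, b in zip(self.spacing_mm, other.spacing_mm)))


@dataclass
class MaskSet:
    """Named binary masks sharing one volume grid.

    Standard names: ``organ``, ``tumor``, ``bladder``, ``muscle``, ``csf``,
    ``sternum``, ``thorax``; arbitrary custom names are allowed. Values are
    strictly 0/1 uint8 arrays matching ``shape``.
    """

    shape: tuple[int, int, int]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask)
        if mask.shape != tuple(self.shape):
            raise GridMismatchError(
                f"mask '{name}' shape {mask.shape} does not match volume shape {tuple(self.shape)}"
            )
        self.masks[name] = (mask > 0.5).astype(np.uint8)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return sorted(self.masks)

    def nonempty(self, name: str) -> bool:
        return name in self.masks and bool(self.masks[name].any())

    def require_nonempty(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(f"mask '{name}' not present (have {self.names()})")
        m = self.masks[name]
        if not m.any():
            raise ImageIOError(f"mask '{name}' is empty")
        return m


def _ras_affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI-1/2 volume, reorienting to RAS.

    Rejects non-3D images and images containing non-finite voxels.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise ImageIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise ImageIOError(f"expected 3D image at {path}, got shape {img.shape}")
    img = nib.as_closest_canonical(img)  # RAS+
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ImageIOError(f"volume {path} contains nonfinite voxels")
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data, tuple(float(z) for z in zooms), ("R", "A", "S"),
                    units="a.u.")


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    """Write a volume as float32 NIfTI-1 with a diagonal RAS affine."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), _ras_affine(vol.spacing_mm))
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, reference: Volume3D) -> np.ndarray:
    """Read a binary mask and check it against a reference grid.

    Any strictly-positive convention (0/1, 0/255, probabilities > 0.5) is
    binarized with threshold 0.5. A shape or spacing mismatch beyond
    ``SPACING_TOL_MM`` is an error — masks are never resampled.
    """
    vol = read_volume(path)
    if vol.shape != reference.shape:
        raise GridMismatchError(
            f"mask {path} shape {vol.shape} != reference shape {reference.shape}"
        )
    if not vol.same_grid(reference):
        raise GridMismatchError(
            f"mask {path} spacing {vol.spacing_mm} != reference spacing "
            f"{reference.spacing_mm} beyond {SPACING_TOL_MM} mm"
        )
    return (vol.data > 0.5).astype(np.uint8)


def write_mask(mask: np.ndarray, spacing_mm: tuple[float, float, float],
               path: str | Path) -> Path:
    """Write a binary mask as uint8 NIfTI-1."""
    path = Path(path)
    arr = (np.asarray(mask) > 0.5).astype(np.uint8)
    if arr.ndim != 3:
        raise ImageIOError(f"expected 3D mask, got {arr.ndim}D")
    img = nib.Nifti1Image(arr, _ras_affine(tuple(float(s) for s in spacing_mm)))
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))
    return path
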