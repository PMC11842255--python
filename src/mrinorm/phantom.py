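"""Synthetic multi-cohort MR phantom generator.

Emulates the confound structure of a multi-site, multi-vendor MR study:
each cohort (a site, vendor, field-strength or coil group) imposes a
multiplicative gain and an additive offset on tissue intensities, an
optional smooth coil-sensitivity bump (endorectal-coil analog) multiplies
the signal near a chosen origin, and Rician magnitude noise corrupts the
result. Geometry is deliberately simple — axis-aligned ellipsoids for the
organ, an interior tumor sphere, and disjoint spherical reference ROIs —
because the downstream analyses depend only on intensity statistics, not
anatomy.

Voxel value before noise::

    v(x) = tissue_mean * subject_jitter * cohort_gain * bias(x) + cohort_offset

with ``bias(x) = 1 + (peak_gain - 1) * exp(-d(x, origin)/decay_length)`` and
``d`` the Euclidean distance in mm. Every subject's generating parameters
are recorded as ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import Volume3D, MaskSet, write_volume, write_mask

__all__ = [
    "PhantomConfig",
    "CohortSpec",
    "BiasFieldSpec",
    "CohortManifest",
    "PhantomConfigError",
    "generate_cohorts",
    "generate_subject",
    "apply_rician_noise",
    "apply_sensitivity_field",
    "default_geometry",
    "subject_seed",
]

REFERENCE_ROI_NAMES = ("fluid_roi", "muscle_roi", "bone_roi", "thorax_roi")

DEFAULT_TISSUE_MEANS = {
    "background": 0.0,
    "organ": 100.0,
    "tumor": 140.0,
    "fluid_roi": 180.0,   # bladder/CSF analog: bright fluid
    "muscle_roi": 60.0,   # levator ani analog
    "bone_roi": 30.0,     # sternum analog
    "thorax_roi": 80.0,
}


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration violates its invariants."""


@dataclass
class BiasFieldSpec:
    """Coil-sensitivity analog: a single exponential-decay gain bump."""

    enabled: bool = False
    peak_gain: float = 2.0
    decay_length_mm: float = 20.0
    origin: tuple[float, float, float] | None = None  # default: volume corner

    def validate(self) -> None:
        if self.enabled:
            if self.peak_gain < 1.0:
                raise PhantomConfigError(f"bias_field.peak_gain must be >= 1, got {self.peak_gain}")
            if self.decay_length_mm <= 0:
                raise PhantomConfigError(
                    f"bias_field.decay_length_mm must be positive, got {self.decay_length_mm}")
            if self.origin is not None and not np.all(np.isfinite(self.origin)):
                raise PhantomConfigError(f"bias_field.origin must be finite, got {self.origin}")


@dataclass
class CohortSpec:
    """One cohort's scanner-effect parameters and labels."""

    name: str
    gain: float = 1.0
    offset: float = 0.0
    site: str = "site1"
    vendor: str = "vendorA"
    field_strength: str = "3T"       # one of {"1.5T", "3T"}
    coil: str = "none"               # one of {"ERC", "nERC", "none"}
    noise_sigma: float | None = None  # override config-level sigma
    bias_field: BiasFieldSpec | None = None  # override config-level bias

    def validate(self) -> None:
        if self.gain <= 0:
            raise PhantomConfigError(f"cohort '{self.name}': gain must be > 0, got {self.gain}")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise PhantomConfigError(
                f"cohort '{self.name}': noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.bias_field is not None:
            self.bias_field.validate()


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    cohorts: list[CohortSpec] = field(default_factory=list)
    bias_field: BiasFieldSpec = field(default_factory=BiasFieldSpec)
    noise_sigma: float = 2.0
    noise_model: str = "rician"      # "rician" | "gaussian" (analytic checks)
    n_subjects_per_cohort: int = 20
    #: Relative SD of the per-subject multiplicative jitter on tissue means
    #: (biological between-subject variability).
    subject_jitter_sd: float = 0.05
    #: Global intensity scale (ADC-like phantoms use e.g. 1e-3).
    intensity_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) <= 0 for g in self.grid_shape):
            raise PhantomConfigError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise PhantomConfigError(
                f"voxel_spacing_mm must be positive, got {self.voxel_spacing_mm}")
        if self.noise_sigma < 0:
            raise PhantomConfigError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.noise_model not in ("rician", "gaussian"):
            raise PhantomConfigError(f"noise_model must be rician|gaussian, got {self.noise_model}")
        if self.n_subjects_per_cohort <= 0:
            raise PhantomConfigError(
                f"n_subjects_per_cohort must be positive, got {self.n_subjects_per_cohort}")
        if self.subject_jitter_sd < 0:
            raise PhantomConfigError(
                f"subject_jitter_sd must be >= 0, got {self.subject_jitter_sd}")
        for t, m in self.tissue_means.items():
            if m < 0:
                raise PhantomConfigError(f"tissue_means['{t}'] must be >= 0, got {m}")
        if not self.cohorts:
            raise PhantomConfigError("at least one cohort is required")
        seen = set()
        for c in self.cohorts:
            c.validate()
            if c.name in seen:
                raise PhantomConfigError(f"duplicate cohort name '{c.name}'")
            seen.add(c.name)
        self.bias_field.validate()
        default_geometry(self.grid_shape)  # raises if the grid cannot host the geometry


@dataclass
class CohortManifest:
    """Per-subject cohort labels, file paths and generating truth."""

    frame: pd.DataFrame
    truth: dict[str, dict]
    root: Path | None = None

    MASK_NAMES = ("organ", "tumor") + REFERENCE_ROI_NAMES

    def subjects(self) -> list[str]:
        return list(self.frame["subject_id"])

    def groups(self, axis: str) -> dict[str, list[str]]:
        """Map each label on a comparison axis (site/vendor/field_strength/coil/cohort)
        to its subject ids."""
        out: dict[str, list[str]] = {}
        for _, row in self.frame.iterrows():
            out.setdefault(str(row[axis]), []).append(row["subject_id"])
        return out

    def row(self, subject_id: str) -> pd.Series:
        sel = self.frame[self.frame["subject_id"] == subject_id]
        if sel.empty:
            raise KeyError(f"unknown subject '{subject_id}'")
        return sel.iloc[0]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        frame = pd.read_csv(path)
        truth: dict[str, dict] = {}
        root = path.parent
        if "truth_path" in frame.columns:
            for _, row in frame.iterrows():
                tp = Path(row["truth_path"])
                if tp.exists():
                    truth[row["subject_id"]] = json.loads(tp.read_text())
        return cls(frame=frame, truth=truth, root=root)


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Stable per-subject seed: CRC32 of ``"{master}:{subject_id}"``, < 2^31."""
    return zlib.crc32(f"{master_seed}:{subject_id}".encode()) & 0x7FFFFFFF


def default_geometry(grid_shape: tuple[int, int, int]) -> dict[str, dict]:
    """Place the organ ellipsoid, interior tumor sphere and four reference ROI
    spheres on a grid, scaled to the grid size.

    Raises
    ------
    PhantomConfigError
        If the grid is too small to host disjoint regions.
    """
    nx, ny, nz = (int(g) for g in grid_shape)
    n = min(nx, ny, nz)
    if n < 16:
        raise PhantomConfigError(
            f"grid_shape {grid_shape}: minimum extent 16 voxels required to place "
            "disjoint organ/tumor/reference-ROI geometry")
    c = (nx / 2.0, ny / 2.0, nz / 2.0)
    organ_r = (0.22 * nx, 0.18 * ny, 0.18 * nz)
    tumor_r = min(organ_r) * 0.45
    roi_r = max(1.5, 0.06 * n)
    # reference ROIs in the corners/edges, well clear of the organ ellipsoid
    rois = {
        "fluid_roi": (0.15 * nx, 0.15 * ny, 0.5 * nz),
        "muscle_roi": (0.85 * nx, 0.15 * ny, 0.5 * nz),
        "bone_roi": (0.15 * nx, 0.85 * ny, 0.5 * nz),
        "thorax_roi": (0.85 * nx, 0.85 * ny, 0.5 * nz),
    }
    geom = {
        "organ": {"kind": "ellipsoid", "center": c, "radii": organ_r},
        "tumor": {"kind": "sphere", "center": c, "radius": tumor_r},
    }
    for name, center in rois.items():
        geom[name] = {"kind": "sphere", "center": center, "radius": roi_r}
    return geom


def _region_mask(shape: tuple[int, int, int], spec: dict) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    cx, cy, cz = spec["center"]
    if spec["kind"] == "ellipsoid":
        rx, ry, rz = spec["radii"]
    else:
        rx = ry = rz = spec["radius"]
    q = (((idx[0] - cx) / rx) ** 2 + ((idx[1] - cy) / ry) ** 2
         + ((idx[2] - cz) / rz) ** 2)
    return q <= 1.0


def build_masks(config: PhantomConfig) -> MaskSet:
    """Build the mask set for the configured grid; identical for all subjects."""
    shape = tuple(int(g) for g in config.grid_shape)
    geom = default_geometry(shape)
    organ = _region_mask(shape, geom["organ"])
    tumor = _region_mask(shape, geom["tumor"]) & organ
    ms = MaskSet(shape=shape)
    ms.add("organ", organ)
    ms.add("tumor", tumor)
    for name in REFERENCE_ROI_NAMES:
        roi = _region_mask(shape, geom[name]) & ~organ
        ms.add(name, roi)
    # invariants: tumor strictly inside organ, ROIs disjoint from organ
    if not tumor.any() or not (organ & ~tumor).any():
        raise PhantomConfigError("grid_shape too small: tumor not a strict subset of organ")
    for name in REFERENCE_ROI_NAMES:
        if (ms[name].astype(bool) & organ).any():
            raise PhantomConfigError(f"reference ROI '{name}' overlaps the organ")
        if not ms[name].any():
            raise PhantomConfigError(f"reference ROI '{name}' is empty at grid {shape}")
    return ms


def apply_rician_noise(vol: Volume3D, sigma: float, seed: int) -> Volume3D:
    """Corrupt a magnitude image with Rician noise.

    Each voxel v becomes ``sqrt((v + e1)^2 + e2^2)`` with e1, e2 independent
    N(0, sigma^2). ``sigma=0`` returns the input unchanged; the output is
    nonnegative everywhere.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return vol
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, size=vol.shape)
    e2 = rng.normal(0.0, sigma, size=vol.shape)
    return vol.with_data(np.hypot(vol.data + e1, e2))


def apply_sensitivity_field(vol: Volume3D, peak_gain: float,
                            decay_length_mm: float,
                            origin: tuple[float, float, float]) -> Volume3D:
    """Multiply by ``1 + (peak_gain - 1) * exp(-d(x, origin)/decay_length)``.

    ``origin`` is in voxel coordinates; distances use the voxel spacing so the
    decay length is in mm. ``peak_gain=1`` is the identity.
    """
    if decay_length_mm <= 0:
        raise ValueError(f"decay_length_mm must be positive, got {decay_length_mm}")
    if not np.all(np.isfinite(origin)):
        raise ValueError(f"origin must be finite, got {origin}")
    if peak_gain == 1.0:
        return vol
    idx = np.indices(vol.shape, dtype=np.float64)
    sp = vol.spacing_mm
    d = np.sqrt(((idx[0] - origin[0]) * sp[0]) ** 2
                + ((idx[1] - origin[1]) * sp[1]) ** 2
                + ((idx[2] - origin[2]) * sp[2]) ** 2)
    mult = 1.0 + (peak_gain - 1.0) * np.exp(-d / decay_length_mm)
    return vol.with_data(vol.data * mult)


def generate_subject(config: PhantomConfig, cohort: CohortSpec,
                     subject_id: str, masks: MaskSet | None = None
                     ) -> tuple[Volume3D, MaskSet, dict]:
    """Generate one subject's volume, masks and ground-truth record."""
    if masks is None:
        masks = build_masks(config)
    shape = tuple(int(g) for g in config.grid_shape)
    seed = subject_seed(config.seed, subject_id)
    rng = np.random.default_rng(seed)

    jitter = {}
    data = np.full(shape, config.tissue_means.get("background", 0.0))
    # paint in order so tumor overrides organ
    for tissue in ("organ", "tumor") + REFERENCE_ROI_NAMES:
        mean = config.tissue_means.get(tissue, 0.0)
        j = float(rng.normal(1.0, config.subject_jitter_sd)) if config.subject_jitter_sd else 1.0
        j = max(j, 0.1)
        jitter[tissue] = j
        data[masks[tissue].astype(bool)] = mean * j

    vol = Volume3D(data * config.intensity_scale, config.voxel_spacing_mm)

    bias = cohort.bias_field if cohort.bias_field is not None else config.bias_field
    if bias.enabled:
        origin = bias.origin if bias.origin is not None else (0.0, 0.0, shape[2] / 2.0)
        vol = apply_sensitivity_field(vol, bias.peak_gain, bias.decay_length_mm, origin)

    vol = vol.with_data(vol.data * cohort.gain + cohort.offset * config.intensity_scale)

    sigma = cohort.noise_sigma if cohort.noise_sigma is not None else config.noise_sigma
    sigma = sigma * config.intensity_scale
    if sigma > 0:
        noise_seed = subject_seed(config.seed, subject_id + ":noise")
        if config.noise_model == "rician":
            vol = apply_rician_noise(vol, sigma, noise_seed)
        else:
            nrng = np.random.default_rng(noise_seed)
            vol = vol.with_data(vol.data + nrng.normal(0.0, sigma, size=vol.shape))

    truth = {
        "subject_id": subject_id,
        "cohort": cohort.name,
        "gain": cohort.gain,
        "offset": cohort.offset,
        "noise_sigma": sigma,
        "noise_model": config.noise_model,
        "bias_enabled": bool(bias.enabled),
        "bias_peak_gain": bias.peak_gain if bias.enabled else 1.0,
        "tissue_jitter": jitter,
        "tissue_means": dict(config.tissue_means),
        "intensity_scale": config.intensity_scale,
        "seed": seed,
    }
    return vol, masks, truth


def generate_cohorts(config: PhantomConfig, out_dir: str | Path) -> CohortManifest:
    """Generate all cohorts to ``out_dir`` and return the manifest.

    Writes one ``.nii.gz`` volume and six mask files per subject, one truth
    JSON per subject, and ``manifest.csv``. Identical (config, seed) produces
    bit-identical voxel payloads.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    masks = build_masks(config)
    rows = []
    truths: dict[str, dict] = {}
    for cohort in config.cohorts:
        for i in range(config.n_subjects_per_cohort):
            sid = f"{cohort.name}_{i:03d}"
            vol, _, truth = generate_subject(config, cohort, sid, masks)
            sdir = out_dir / sid
            sdir.mkdir(exist_ok=True)
            vpath = write_volume(vol, sdir / "volume.nii.gz")
            row = {
                "subject_id": sid,
                "cohort": cohort.name,
                "site": cohort.site,
                "vendor": cohort.vendor,
                "field_strength": cohort.field_strength,
                "coil": cohort.coil,
                "volume_path": str(vpath),
            }
            for name in CohortManifest.MASK_NAMES:
                mpath = write_mask(masks[name], config.voxel_spacing_mm,
                                   sdir / f"mask_{name}.nii.gz")
                row[f"{name}_path"] = str(mpath)
            tpath = sdir / "truth.json"
            tpath.write_text(json.dumps(truth, indent=1, sort_keys=True))
            row["truth_path"] = str(tpath)
            rows.append(row)
            truths[sid] = truth
    frame = pd.DataFrame(rows)
    manifest = CohortManifest(frame=frame, truth=truths, root=out_dir)
    manifest.save(out_dir / "manifest.csv")
    return manifest


def config_from_dict(d: dict) -> PhantomConfig:
    """Build a PhantomConfig from a plain dict (e.g. parsed YAML)."""
    d = dict(d)
    cohorts = [CohortSpec(**({"bias_field": BiasFieldSpec(**c.pop("bias_field"))}
                             if isinstance(c.get("bias_field"), dict) else {})
                          | {k: v for k, v in c.items() if k != "bias_field"})
               for c in d.pop("cohorts", [])]
    bias = d.pop("bias_field", None)
    cfg = PhantomConfig(cohorts=cohorts, **{
        k: (tuple(v) if k in ("grid_shape", "voxel_spacing_mm") else v)
        for k, v in d.items()})
    if isinstance(bias, dict):
        cfg.bias_field = BiasFieldSpec(**bias)
    return cfg
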