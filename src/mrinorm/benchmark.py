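"""Study orchestration: normalization x comparison equivalence tables and
radiomic feature-stability ratios.

For each normalization method and each pairwise cohort comparison (sites,
vendors, field strengths, coil usage) the benchmark normalizes every
subject, summarises the within-organ intensity distribution by its four
moments, and runs the TOST equivalence test per moment — yielding the
(method, comparison, moment, pooled SD, p_max) table. The radiomic arm
repeats this per feature: a feature is *stable* under a method when its
per-subject values are statistically equivalent across the cohorts
(p_max < alpha), and stability is aggregated into per-class ratios
(number equivalent / number testable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import Volume3D, MaskSet, read_volume, read_mask
from .phantom import CohortManifest
from .normalize import NormalizationMethod, apply_method, DegenerateInputError
from .dist_stats import (masked_moments, tost, margin_policy, MarginPolicy,
                         MOMENT_NAMES)
from .radiomics import ExtractionConfig, extract_features, FeatureVector

__all__ = [
    "ComparisonPlan",
    "StabilityReport",
    "BenchmarkResults",
    "EquivalenceBenchmark",
    "run_intensity_benchmark",
    "run_radiomic_stability",
    "report",
]

COMPARISON_AXES = ("site", "vendor", "field_strength", "coil")

DEFAULT_METHODS = (
    NormalizationMethod("unnormalized"),
    NormalizationMethod("sd_mask"),
    NormalizationMethod("zscore_mask"),
    NormalizationMethod("minmax"),
    NormalizationMethod("scaled"),
    NormalizationMethod("roi_mean", "fluid_roi"),
    NormalizationMethod("roi_mean", "muscle_roi"),
)


@dataclass
class ComparisonPlan:
    """Which axis to compare, with which methods, moments and margins."""

    axis: str = "site"
    groups: tuple[str, str] | None = None  # None: all pairs of labels on the axis
    methods: tuple[NormalizationMethod, ...] = DEFAULT_METHODS
    moments: tuple[str, ...] = MOMENT_NAMES
    alpha: float = 0.05
    margin: MarginPolicy = field(default_factory=MarginPolicy)
    region: str = "organ"
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    #: restrict analysis to the centre N axial slices (0 = no restriction)
    center_slices: int = 0

    def __post_init__(self) -> None:
        if self.axis not in COMPARISON_AXES + ("cohort",):
            raise ValueError(f"axis must be one of {COMPARISON_AXES}, got '{self.axis}'")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        bad = [m for m in self.moments if m not in MOMENT_NAMES]
        if bad:
            raise ValueError(f"unknown moments {bad}")

    def group_pairs(self, manifest: CohortManifest) -> list[tuple[str, str]]:
        groups = manifest.groups(self.axis)
        if self.groups is not None:
            for g in self.groups:
                if g not in groups or not groups[g]:
                    raise ValueError(f"group '{g}' empty or absent on axis '{self.axis}'")
            return [tuple(self.groups)]  # type: ignore[list-item]
        labels = sorted(groups)
        return [(a, b) for a, b in combinations(labels, 2)]


@dataclass
class StabilityReport:
    """Per (feature class, method, comparison) stability counts."""

    table: pd.DataFrame          # feature-level rows
    by_class: pd.DataFrame       # aggregated ratios
    excluded: pd.DataFrame       # features excluded, with reasons

    def ratio(self, feature_class: str, method: str, comparison: str) -> float:
        sel = self.by_class[(self.by_class["feature_class"] == feature_class)
                            & (self.by_class["method"] == method)
                            & (self.by_class["comparison"] == comparison)]
        return float(sel["ratio"].iloc[0]) if len(sel) else float("nan")


def _load_subject(manifest: CohortManifest, subject_id: str
                  ) -> tuple[Volume3D, MaskSet]:
    row = manifest.row(subject_id)
    vol = read_volume(row["volume_path"])
    ms = MaskSet(shape=vol.shape)
    for name in CohortManifest.MASK_NAMES:
        col = f"{name}_path"
        if col in row and isinstance(row[col], str):
            ms.add(name, read_mask(row[col], vol))
    return vol, ms


def _crop_center_slices(mask: np.ndarray, n_slices: int) -> np.ndarray:
    if n_slices <= 0 or n_slices >= mask.shape[2]:
        return mask
    nz = mask.shape[2]
    lo = (nz - n_slices) // 2
    out = np.zeros_like(mask)
    out[:, :, lo:lo + n_slices] = mask[:, :, lo:lo + n_slices]
    return out


def _normalized_subject_moments(manifest: CohortManifest, plan: ComparisonPlan,
                                subject_ids, method: NormalizationMethod):
    """Yield (subject_id, MomentSummary) after normalization; record failures."""
    summaries, failures = [], []
    for sid in subject_ids:
        try:
            vol, masks = _load_subject(manifest, sid)
            nvol = apply_method(method, vol, masks)
            region = _crop_center_slices(masks.require_nonempty(plan.region),
                                         plan.center_slices)
            summaries.append(masked_moments(nvol, region, sid, plan.region))
        except (DegenerateInputError, KeyError, ValueError) as exc:
            failures.append((sid, method.label, str(exc)))
    return summaries, failures


def moments_table(manifest: CohortManifest, plan: ComparisonPlan,
                  method: NormalizationMethod | None = None) -> pd.DataFrame:
    """Per-subject moment summaries (one row per subject) after applying one
    normalization method (default: the plan's first)."""
    method = method or plan.methods[0]
    summaries, failures = _normalized_subject_moments(
        manifest, plan, manifest.subjects(), method)
    rows = [{"subject_id": s.subject_id, "method": method.label, "region": s.region,
             "mean": s.mean, "variance": s.variance, "skewness": s.skewness,
             "kurtosis": s.kurtosis, "n_voxels": s.n_voxels} for s in summaries]
    table = pd.DataFrame(rows)
    table.attrs["failures"] = failures
    return table


def run_intensity_benchmark(manifest: CohortManifest, plan: ComparisonPlan
                            ) -> pd.DataFrame:
    """The equivalence table: one row per (method, group pair, moment).

    Rows with fewer than two usable subjects per group are marked
    ``not_computable``. Deterministic for a fixed manifest and plan.
    """
    pairs = plan.group_pairs(manifest)
    groups = manifest.groups(plan.axis)
    rows = []
    for method in plan.methods:
        cache: dict[str, list] = {}
        fail_log: list = []
        for label in {g for pair in pairs for g in pair}:
            cache[label], fails = _normalized_subject_moments(
                manifest, plan, groups[label], method)
            fail_log.extend(fails)
        for a, b in pairs:
            for moment in plan.moments:
                va = np.array([s.moment(moment) for s in cache[a]
                               if moment not in s.undefined])
                vb = np.array([s.moment(moment) for s in cache[b]
                               if moment not in s.undefined])
                base = {
                    "method": method.label, "axis": plan.axis,
                    "comparison": f"{a} v {b}", "moment": moment,
                    "n_a": len(va), "n_b": len(vb),
                    "n_failed": len(fail_log),
                }
                if len(va) < 2 or len(vb) < 2:
                    rows.append(base | {"pooled_sd": np.nan, "p_max": np.nan,
                                        "margin": np.nan, "degenerate": False,
                                        "not_computable": True})
                    continue
                margin = margin_policy(va, vb, plan.margin)
                res = tost(va, vb, margin, comparison=(a, b), moment=moment)
                rows.append(base | {"pooled_sd": res.pooled_sd, "p_max": res.p_max,
                                    "margin": margin, "degenerate": res.degenerate,
                                    "not_computable": False})
    return pd.DataFrame(rows)


def compute_feature_table(manifest: CohortManifest, plan: ComparisonPlan,
                          subject_ids=None) -> pd.DataFrame:
    """Per-subject 197-feature table for every method in the plan."""
    subject_ids = list(subject_ids or manifest.subjects())
    rows = []
    class_of: dict[str, str] = {}
    for method in plan.methods:
        for sid in subject_ids:
            try:
                vol, masks = _load_subject(manifest, sid)
                nvol = apply_method(method, vol, masks)
                region = _crop_center_slices(masks.require_nonempty(plan.region),
                                             plan.center_slices)
                fv = extract_features(nvol, region, plan.extraction, sid)
            except (DegenerateInputError, ValueError, KeyError) as exc:
                warnings.warn(f"feature extraction failed for {sid}/{method.label}: {exc}")
                continue
            class_of.update(fv.class_of)
            rows.append({"subject_id": sid, "method": method.label} | fv.features)
    table = pd.DataFrame(rows)
    table.attrs["class_of"] = class_of
    return table


def run_radiomic_stability(manifest: CohortManifest, plan: ComparisonPlan,
                           feature_table: pd.DataFrame | None = None
                           ) -> StabilityReport:
    """TOST per feature x method x comparison; aggregate per feature class.

    A feature is excluded from a comparison (with a logged reason) when it
    is undefined in more than half of either group; otherwise undefined
    values are dropped pairwise before testing.
    """
    if feature_table is None:
        feature_table = compute_feature_table(manifest, plan)
    class_of: dict[str, str] = feature_table.attrs.get("class_of", {})
    feature_cols = [c for c in feature_table.columns
                    if c not in ("subject_id", "method")]
    groups = manifest.groups(plan.axis)
    pairs = plan.group_pairs(manifest)
    rows, excluded = [], []
    for method in sorted(feature_table["method"].unique()):
        mt = feature_table[feature_table["method"] == method]
        for a, b in pairs:
            ta = mt[mt["subject_id"].isin(groups[a])]
            tb = mt[mt["subject_id"].isin(groups[b])]
            for feat in feature_cols:
                va = ta[feat].to_numpy(dtype=float)
                vb = tb[feat].to_numpy(dtype=float)
                bad_a = np.mean(~np.isfinite(va)) if len(va) else 1.0
                bad_b = np.mean(~np.isfinite(vb)) if len(vb) else 1.0
                if bad_a > 0.5 or bad_b > 0.5:
                    excluded.append({"method": method, "comparison": f"{a} v {b}",
                                     "feature": feat,
                                     "reason": "undefined in >half of a group"})
                    continue
                va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
                if len(va) < 2 or len(vb) < 2:
                    excluded.append({"method": method, "comparison": f"{a} v {b}",
                                     "feature": feat, "reason": "fewer than 2 values"})
                    continue
                margin = margin_policy(va, vb, plan.margin)
                res = tost(va, vb, margin, comparison=(a, b), moment=feat)
                rows.append({
                    "method": method, "comparison": f"{a} v {b}", "feature": feat,
                    "feature_class": class_of.get(feat, "unknown"),
                    "p_max": res.p_max, "pooled_sd": res.pooled_sd,
                    "margin": margin, "degenerate": res.degenerate,
                    "stable": bool(res.p_max < plan.alpha),
                })
    table = pd.DataFrame(rows)
    if len(table):
        agg = (table.groupby(["feature_class", "method", "comparison"])
               .agg(n_equivalent=("stable", "sum"), n_tests=("stable", "size"))
               .reset_index())
        agg["ratio"] = agg["n_equivalent"] / agg["n_tests"]
    else:
        agg = pd.DataFrame(columns=["feature_class", "method", "comparison",
                                    "n_equivalent", "n_tests", "ratio"])
    return StabilityReport(table=table, by_class=agg,
                           excluded=pd.DataFrame(excluded))


@dataclass
class BenchmarkResults:
    """Computed equivalence tables, stability report and plan metadata."""

    intensity: pd.DataFrame
    stability: StabilityReport | None
    plans: list[ComparisonPlan]

    def method_ranking(self, alpha: float = 0.05) -> pd.DataFrame:
        """Methods ranked by number of equivalent (p_max < alpha) rows."""
        t = self.intensity[~self.intensity["not_computable"]]
        rank = (t.assign(equivalent=t["p_max"] < alpha)
                .groupby("method")["equivalent"].agg(["sum", "count"])
                .rename(columns={"sum": "n_equivalent", "count": "n_tests"})
                .sort_values("n_equivalent", ascending=False)
                .reset_index())
        return rank

    def summary(self, alpha: float = 0.05) -> str:
        lines = ["Intensity equivalence benchmark", "=" * 34, ""]
        rank = self.method_ranking(alpha)
        lines.append(f"{'method':28s} {'equivalent':>10s} {'tests':>6s}")
        for _, r in rank.iterrows():
            lines.append(f"{r['method']:28s} {int(r['n_equivalent']):10d} "
                         f"{int(r['n_tests']):6d}")
        if self.stability is not None and len(self.stability.by_class):
            lines += ["", "Radiomic stability (ratio equivalent/testable per class)", ""]
            overall = (self.stability.by_class.groupby("feature_class")["ratio"]
                       .mean().sort_values(ascending=False))
            for cls, r in overall.items():
                lines.append(f"{cls:26s} {r:6.2f}")
        elif self.stability is not None:
            lines += ["", "Radiomic stability: no features tested"]
        return "\n".join(lines)


class EquivalenceBenchmark:
    """Orchestrator: run intensity and radiomic-stability benchmarks for a
    manifest over one or several comparison plans."""

    def __init__(self, manifest: CohortManifest,
                 plans: ComparisonPlan | list[ComparisonPlan]):
        self.manifest = manifest
        self.plans = [plans] if isinstance(plans, ComparisonPlan) else list(plans)

    def run(self, radiomics: bool = False) -> BenchmarkResults:
        tables = [run_intensity_benchmark(self.manifest, p) for p in self.plans]
        stability = None
        if radiomics:
            reports = [run_radiomic_stability(self.manifest, p) for p in self.plans]
            stability = StabilityReport(
                table=pd.concat([r.table for r in reports], ignore_index=True),
                by_class=pd.concat([r.by_class for r in reports], ignore_index=True),
                excluded=pd.concat([r.excluded for r in reports], ignore_index=True))
        return BenchmarkResults(intensity=pd.concat(tables, ignore_index=True),
                                stability=stability, plans=self.plans)


def report(results: BenchmarkResults, out_dir: str | Path,
           plots: bool = True) -> dict[str, Path]:
    """Write CSVs, ranking and violin plots; never alters numbers.

    Re-running on the same results reproduces byte-identical CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["intensity"] = out_dir / "intensity_tost.csv"
    results.intensity.to_csv(paths["intensity"], index=False)
    if results.stability is not None:
        paths["stability"] = out_dir / "radiomic_stability.csv"
        results.stability.by_class.to_csv(paths["stability"], index=False)
        paths["stability_detail"] = out_dir / "radiomic_stability_detail.csv"
        results.stability.table.to_csv(paths["stability_detail"], index=False)
    paths["ranking"] = out_dir / "method_ranking.csv"
    results.method_ranking().to_csv(paths["ranking"], index=False)
    paths["summary"] = out_dir / "summary.md"
    paths["summary"].write_text(results.summary() + "\n")
    if plots:
        paths["plot"] = _plot_pmax(results, out_dir / "plots")
    return paths


def _plot_pmax(results: BenchmarkResults, plot_dir: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    t = results.intensity[~results.intensity["not_computable"]]
    methods = sorted(t["method"].unique())
    fig, ax = plt.subplots(figsize=(1.2 * len(methods) + 2, 4))
    data = [t[t["method"] == m]["p_max"].to_numpy() for m in methods]
    if all(len(d) for d in data):
        ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(methods) + 1), methods, rotation=30, ha="right")
    ax.set_ylabel("TOST p_max")
    ax.axhline(0.05, color="crimson", lw=0.8, ls="--")
    fig.tight_layout()
    path = plot_dir / "pmax_by_method.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
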