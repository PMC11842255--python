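# mrinorm

Benchmarking MRI intensity-normalization methods across multi-site cohorts.

Weighted MR image intensities (T2W, T1, T1C, FLAIR, T1nFS) are expressed in
arbitrary, scanner-dependent units: the same tissue imaged at two sites, on
two vendors' scanners, at 1.5 T vs 3 T, or with and without an endorectal
coil can differ by large multiplicative gains and additive offsets. Any
quantitative downstream analysis — intensity statistics, radiomics, machine
learning — silently inherits these confounds unless the images are
normalized first. `mrinorm` is for imaging scientists who need to choose a
normalization method and quantify, rather than assume, how comparable the
resulting intensity distributions are across cohorts.

## What it does

1. **Normalization operators** (applied voxelwise to a whole volume, with
   statistics from a stated region):
   unnormalized, SD (v/σ<sub>mask</sub>), z-score ((v−μ<sub>mask</sub>)/σ<sub>mask</sub>),
   min-max ((v−min)/(max−min)), scaled (v/max), and ROI-mean (v/μ<sub>ROI</sub>
   for a reference region such as bladder, muscle, CSF, tumor, sternum or
   thorax). Plus a power-of-ten unit harmonizer for quantitative maps (ADC)
   stored in inconsistent units.
2. **Equivalence testing.** Per-subject within-mask moments (mean, variance,
   skewness, kurtosis) are compared between cohorts with the two one-sided
   tests (TOST) procedure on the pooled-SD two-sample t statistic: cohorts
   are *equivalent* when both one-sided tests against ±δ reject; the
   reported p is p<sub>max</sub> = max(p<sub>lower</sub>, p<sub>upper</sub>), so
   p<sub>max</sub> < α is the equivalence decision. The margin δ is an
   explicit policy (default: Cohen's d = 0.5 × pooled SD).
3. **Radiomic stability.** A 197-feature extractor (50 GLCM, 32 GLRLM,
   16 GLSZM, 16 GLDZM, 17 NGLDM, 5 NGTDM texture features; 18 intensity
   statistics, 23 intensity-histogram, 18 intensity-volume-histogram,
   2 local-intensity features) runs per subject per method; a feature is
   *stable* under a method when its per-subject values are equivalent
   across cohorts, aggregated into per-class stability ratios.
4. **Synthetic phantoms.** A generator producing multi-cohort MR-like
   volumes with known ground truth — per-cohort gain/offset, an
   exponential-decay coil-sensitivity field, Rician magnitude noise,
   between-subject jitter, and organ/tumor/reference-ROI masks — so the
   whole pipeline can be validated end to end against analytically forced
   answers.

The central mechanism: the within-mask z-score removes any positive affine
(gain/offset) scanner effect exactly, so per-subject masked means become
identically 0 and the TOST comparison is degenerately equivalent
(pooled SD 0, p < 0.001) across every confound axis — while unnormalized
cohorts with a 2× gain are decisively non-equivalent.

## Worked example

```python
import tempfile
from mrinorm.phantom import PhantomConfig, CohortSpec, generate_cohorts
from mrinorm.benchmark import ComparisonPlan, EquivalenceBenchmark

cfg = PhantomConfig(
    grid_shape=(24, 24, 24), n_subjects_per_cohort=10, noise_sigma=2.0, seed=1,
    cohorts=[CohortSpec("A", gain=1.0, site="site1"),
             CohortSpec("B", gain=2.0, offset=10.0, site="site2")])
with tempfile.TemporaryDirectory() as d:
    manifest = generate_cohorts(cfg, d)
    plan = ComparisonPlan(axis="site", moments=("mean", "variance"))
    results = EquivalenceBenchmark(manifest, plan).run()
print(results.intensity[["method", "moment", "pooled_sd", "p_max", "degenerate"]])
```

prints (abridged):

```
              method   moment  pooled_sd  p_max  degenerate
        unnormalized     mean      6.094      1       False
        unnormalized variance      112.6 0.9995       False
             sd_mask     mean      3.015 0.7849       False
             sd_mask variance  1.736e-16      0        True
         zscore_mask     mean  4.819e-16      0        True
         zscore_mask variance  2.427e-16      0        True
              minmax     mean    0.03327 0.7057       False
              scaled     mean    0.03323 0.7649       False
 roi_mean[fluid_roi]     mean    0.03366 0.6418       False
```

Reading the rows: the simulated site-2 scanner doubles every intensity and
adds an offset, so unnormalized cohort means are far apart (pooled SD ≈ 6
in tissue units, p<sub>max</sub> = 1: decisively not equivalent). Z-scoring
forces every subject's masked mean to 0 and masked variance to 1, so both
moments collapse to pooled SD ≈ 0 and degenerate equivalence (p = 0) —
and SD normalization does the same for the variance only. Min-max, scaled
and ROI-mean remove the gain but keep between-subject spread, landing in
between. `results.summary()` ranks the methods by equivalent comparisons.

A `mrinorm` console script exposes the same pipeline
(`simulate`, `normalize`, `roi circle`, `roi csf`, `benchmark`).

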