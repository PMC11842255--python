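# Methods

## The comparison problem

Weighted MR intensities are non-quantitative: a voxel value carries an
arbitrary scanner- and protocol-dependent scale. When cohorts are pooled
across sites, vendors, field strengths or coil configurations, the
between-cohort component of intensity variation is a confound, not a
signal. The benchmark asks, for each candidate normalization method:
after normalizing every subject individually, are the per-subject summary
statistics *statistically equivalent* between cohorts?

Equivalence is the right framing (rather than failing to reject a
difference): the two one-sided tests (TOST) procedure declares two group
means equivalent within ±δ only when both one-sided t-tests reject, and we
report p_max, the larger of the two one-sided p-values, so p_max < α is the
decision rule for every table the benchmark emits.

## Normalization operators

All operators are per-subject ("individual patient level") and voxelwise
over the whole volume; the defining statistics come from a stated region.
Sample (n−1) SDs are used throughout, consistent with the t-test machinery
downstream.

| method | transform | statistics region |
|---|---|---|
| unnormalized | v | — |
| sd_mask | v / σ | organ mask |
| zscore_mask | (v − μ)/σ | organ mask |
| minmax | (v − min)/(max − min) | whole volume |
| scaled | v / max | whole volume |
| roi_mean | v / μ_ROI | named reference ROI |

Design choices that were genuinely open:

* **minmax/scaled extrema** come from the whole volume, not the organ mask.
  Whole-volume extrema are what "scaling all images between 0–1" does
  operationally, and they leave nonzero between-subject spread in masked
  means — matching the observed behaviour that these methods reduce but do
  not annihilate cohort differences. Masked-extrema variants are available
  via `mask_extrema=True`.
* **roi_mean divides** by the reference-region mean (an intensity ratio to
  reference tissue, as in muscle/fat-reference normalization literature)
  rather than subtracting or centering; alternatives are trivial to express
  with the same statistics if needed.
* Degenerate inputs (empty mask, zero spread, zero reference mean) raise a
  typed error; no silent NaN/Inf ever propagates into the statistics.

`harmonize_units` multiplies a quantitative map by the integer power of ten
that brings its median absolute intensity to a target order of magnitude —
the pragmatic fix for ADC maps stored in mm²/s vs µm²/ms vs scanner counts.
It is idempotent (a second application returns exponent 0).

The key analytic property, asserted by tests: `zscore_mask` is invariant to
any positive affine transform of its input, so any purely multiplicative +
additive scanner effect is removed *exactly*, and every subject's
within-mask mean is 0 and SD is 1 by construction.

## Moments and TOST

Per subject and region we compute the sample mean, sample (n−1) variance,
Fisher–Pearson skewness g1, and non-excess sample kurtosis g2 (Gaussian
→ 3). Moments needing more voxels than the region has (or undefined on a
constant region) are flagged undefined and excluded pairwise downstream,
never imputed.

The TOST uses the equal-variance two-sample t statistic with pooled SD
√(((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2)) and df = n_a+n_b−2 (a Welch
variant is available behind a flag; the pooled form is what the reported
"pooled SD" column belongs to). p_lower = P(T > (Δ+δ)/se) tests
H0: Δ ≤ −δ; p_upper = P(T < (Δ−δ)/se) tests H0: Δ ≥ +δ.

**Margin policy.** No equivalence margin is inherent to the comparison
design, and it is the single most consequential free parameter. The default
is Cohen's d = 0.5 — half a pooled SD, a "medium" standardized difference —
with an absolute floor of 10⁻⁶ for degenerate zero-variance groups; an
absolute margin in moment units is also supported. The resolved margin is
recorded in every output row.

**Degenerate zero-variance rule.** Exactly-normalized data (masked means
after z-score; masked variances after SD or z-score normalization) have
zero between-subject spread and a 0/0 t statistic. The rule: when the
pooled SD is zero, equivalence holds with p_max = 0 if |Δ| < δ, else
p_max = 1, flagged `degenerate`. Numerically, "zero" means
pooled SD ≤ 10⁻¹² × max(1, |means|): float summation leaves ~10⁻¹⁶
residue on analytically-zero spreads, and treating that residue as a real
variance would hand the decision to rounding noise.

No multiple-testing correction is applied; each comparison's raw p_max is
reported (correction utilities would sit naturally on the output table).

## Radiomic features

197 features in 10 classes, counts fixed for every input:
GLCM 50 (25 base features × {2D slice-averaged, 3D merged} aggregations),
GLRLM 32 (16 × 2), GLSZM 16, GLDZM 16, NGLDM 17, NGTDM 5 (texture, 136);
intensity statistics 18, intensity histogram 23, intensity-volume histogram
18, local intensity 2 (intensity, 61). Definitions follow the IBSI
reference nomenclature; the intensity-volume histogram uses 9 + 9 decile
features (volume fraction at fractional intensity x, intensity at
fractional volume x, x = 10…90).

Numerical/settings choices:

* **Discretization**: fixed bin number (default 32) over the within-mask
  range — min maps to level 1, max to n_bins. This makes all matrix
  features exactly invariant to adding a constant to the image (asserted by
  a test). The full extraction config is snapshotted into each feature
  vector; feature values are only comparable within identical configs.
* **Aggregation**: GLCM/GLRLM merge the 4 in-plane directions per axial
  slice and average feature values over slices (2D), and merge all 13
  unique 3D directions into one matrix (3D). This is the aggregation pair
  that yields the 50/32 class counts; other schemes change the counts and
  are rejected by the count invariant.
* **Connectivity**: 26-neighbourhoods for zones, dependence and gray-tone
  matrices; city-block distance to the mask border (border voxels at
  distance 1, image boundary counts as outside) for distance zones.
* **Degenerate regions**: a constant region cannot be discretized; it is
  assigned a single level and the mathematically undefined features (GLCM
  correlation, NGTDM coarseness, …) come back NaN, listed in
  `FeatureVector.undefined` — the vector length stays 197. Stability
  testing excludes a feature from a comparison when it is undefined in more
  than half of either group, with a logged reason.

Stability criterion: p_max < 0.05 per feature, raw and uncorrected, with
the same margin policy as the intensity benchmark (cohens_d by default,
since raw feature scales vary over orders of magnitude).

## Synthetic phantom model

Each subject's pre-noise voxel value is

    v(x) = m_t · j_s · g_c · b(x) + o_c

with m_t the tissue's base mean (background 0, organ 100, tumor 140,
fluid ROI 180, muscle ROI 60, bone ROI 30, thorax ROI 80, arbitrary
units), j_s ~ N(1, 0.05²) a per-subject multiplicative jitter (biological
between-subject variability, ~5% CV — typical of within-protocol masked
T2W means), g_c and o_c the cohort's scanner gain and offset, and
b(x) = 1 + (peak_gain − 1)·exp(−d(x, origin)/λ) an exponential-decay
coil-sensitivity bump (d in mm via voxel spacing). Rician magnitude noise
√((v+ε₁)² + ε₂²), ε ~ N(0, σ²), is applied last (Gaussian noise available
for analytic checks); default σ = 2 gives organ SNR ≈ 50, high-field
territory, so noise perturbs but never dominates the cohort effects.

Geometry is axis-aligned: a central organ ellipsoid, an interior tumor
sphere (strictly inside the organ), and four corner reference-ROI spheres
disjoint from the organ. The analyses consume only intensity statistics,
so anatomical realism is deliberately out of scope. What the phantom does
**not** emulate: spatial tissue heterogeneity and partial-volume mixtures,
acquisition-dependent texture (so radiomic stability results on phantoms
validate the pipeline's mechanics and affine-equivariance bookkeeping, not
clinical feature robustness), non-affine scanner effects (B1 shading
beyond the single bump, gradient nonlinearity), and registration error.
Passing tests therefore demonstrate the statistical machinery and the
exact affine-removal property — not that any method fixes real multi-site
data.

Seeding: one master seed; per-subject seeds derived by CRC32 of
`"{master}:{subject_id}"` (kept < 2³¹), so any subject regenerates
independently and identical (config, seed) runs are byte-identical on
disk.

## Reference ROIs

Circular slice ROIs use the closed-disk lattice rule
(x−cx)² + (y−cy)² ≤ r² on one axial slice (default radius 10 voxels),
validated against exhaustive lattice enumeration; circles exceeding the
slice bounds are an error, never clipped. CSF masks threshold an ADC map
strictly above 2.0×10⁻³ mm²/s (free water ≈ 3×10⁻³, parenchyma < 1×10⁻³)
inside a brain mask; the threshold is configurable and the construction is
monotone in it. Organ and tumor masks are inputs, not computed — clinical
segmentation is out of scope.

## Problem sizes

The test suite and the acceptance script run on 24³–32³ grids with 5–30
subjects per cohort. These sizes keep every analytically-forced result
exact (the z-score mechanism is size-independent) while the stochastic
checks (Rayleigh background mean, gain-ratio recovery, TOST oracle sweeps)
are sized so their Monte-Carlo error sits well inside the asserted
tolerances.

## Known limitations

* The margin policy is a modelling choice, not an estimate; equivalence
  conclusions move with δ, which is why δ is printed in every row.
* 2D GLCM/GLRLM aggregation averages features over slices (not matrices
  over slices); both are legitimate conventions and they differ on
  anisotropic textures.
* The histogram-gradient features use a symmetric difference on the level
  histogram, which smooths single-bin spikes relative to a forward
  difference.
* `harmonize_units` assumes the unit error is a pure power of ten.
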