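import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.weightstats import ttost_ind

from mrinorm import Volume3D
from mrinorm.dist_stats import (masked_moments, pooled_sd, tost, margin_policy,
                                MarginPolicy)


def vol_of(values):
    return Volume3D(np.asarray(values, dtype=np.float64).reshape(-1, 1, 1))


def full_mask(v):
    return np.ones(v.shape, dtype=np.uint8)


class TestMaskedMoments:
    def test_symmetric_three_point(self):
        s = masked_moments(vol_of([1.0, 2.0, 3.0]), full_mask(vol_of([0, 0, 0])))
        assert s.mean == 2.0
        assert s.variance == 1.0
        assert s.skewness == pytest.approx(0.0)
        assert "kurtosis" in s.undefined  # n=3 < 4

    def test_constant_region_flags(self):
        s = masked_moments(vol_of([5.0] * 6), full_mask(vol_of([0.0] * 6)))
        assert s.variance == 0.0
        assert s.undefined >= {"skewness", "kurtosis"}

    def test_brute_force_moment_oracle(self):
        vals = np.array([0.0, 0.0, 0.0, 1.0])
        s = masked_moments(vol_of(vals), full_mask(vol_of(vals)))
        assert s.mean == pytest.approx(0.25)
        assert s.variance == pytest.approx(0.25)
        mu = vals.mean()
        m2 = np.mean((vals - mu) ** 2)
        m3 = np.mean((vals - mu) ** 3)
        m4 = np.mean((vals - mu) ** 4)
        assert s.skewness == pytest.approx(m3 / m2 ** 1.5)
        assert s.kurtosis == pytest.approx(m4 / m2 ** 2)

    def test_empty_mask_errors(self):
        v = vol_of([1.0, 2.0])
        with pytest.raises(ValueError, match="empty"):
            masked_moments(v, np.zeros(v.shape, dtype=np.uint8))


class TestPooledSd:
    def test_equal_sds_any_sizes(self):
        assert pooled_sd(2.0, 5, 2.0, 17) == pytest.approx(2.0)

    def test_two_by_two_arithmetic(self):
        assert pooled_sd(0.0, 2, 2.0, 2) == pytest.approx(np.sqrt(2.0))

    def test_matches_brute_force_from_raw_samples(self, rng):
        for _ in range(20):
            a = rng.normal(0, 3, size=rng.integers(2, 30))
            b = rng.normal(1, 5, size=rng.integers(2, 30))
            sp = pooled_sd(a.std(ddof=1), len(a), b.std(ddof=1), len(b))
            direct = np.sqrt((np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
                             / (len(a) + len(b) - 2))
            assert sp == pytest.approx(direct, rel=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            pooled_sd(1.0, 1, 1.0, 5)


class TestTost:
    def test_boundary_mean_diff_equals_margin(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a - 0.5  # diff exactly +0.5
        res = tost(a, b, margin=0.5)
        assert res.p_upper == pytest.approx(0.5)
        assert res.p_max >= 0.5

    def test_degenerate_identical_zeros(self):
        res = tost([0.0, 0.0, 0.0], [0.0, 0.0], margin=0.01)
        assert res.degenerate
        assert res.p_max == 0.0

    def test_degenerate_separated_constants(self):
        res = tost([0.0, 0.0], [5.0, 5.0], margin=0.01)
        assert res.degenerate
        assert res.p_max == 1.0

    def test_direct_t_cdf_oracle(self):
        a = np.array([0.10, 0.20, 0.30])
        b = np.array([0.12, 0.22, 0.32])
        margin = 0.5
        res = tost(a, b, margin)
        diff = a.mean() - b.mean()
        sp = np.sqrt((np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / 4)
        se = sp * np.sqrt(1 / 3 + 1 / 3)
        p_lower = sps.t.sf((diff + margin) / se, 4)
        p_upper = sps.t.cdf((diff - margin) / se, 4)
        assert res.p_lower == pytest.approx(p_lower, abs=1e-12)
        assert res.p_upper == pytest.approx(p_upper, abs=1e-12)

    def test_oracle_against_statsmodels_100_instances(self, rng):
        """Independent library oracle: equal-variance TOST p-values agree to 1e-10."""
        for _ in range(100):
            n_a, n_b = rng.integers(2, 25, size=2)
            a = rng.normal(rng.normal(), 1 + rng.random(), size=n_a)
            b = rng.normal(rng.normal(), 1 + rng.random(), size=n_b)
            margin = 0.1 + 2 * rng.random()
            res = tost(a, b, margin)
            pv, (t1, p1, _), (t2, p2, _) = ttost_ind(a, b, -margin, margin,
                                                     usevar="pooled")
            assert res.p_max == pytest.approx(pv, abs=1e-10)
            assert res.p_lower == pytest.approx(p1, abs=1e-10)
            assert res.p_upper == pytest.approx(p2, abs=1e-10)

    def test_group_swap_symmetry(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.3, 2, 14)
        r1 = tost(a, b, 0.7)
        r2 = tost(b, a, 0.7)
        assert r1.p_lower == pytest.approx(r2.p_upper, abs=1e-14)
        assert r1.p_upper == pytest.approx(r2.p_lower, abs=1e-14)
        assert r1.p_max == pytest.approx(r2.p_max, abs=1e-14)

    def test_margin_monotonicity(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.4, 1, 12)
        p_prev = None
        for margin in (0.1, 0.3, 0.7, 1.5, 3.0):
            p = tost(a, b, margin).p_max
            if p_prev is not None:
                assert p <= p_prev + 1e-15  # enlarging the margin never raises p_max
            p_prev = p

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tost([1.0, 2.0], [1.0, 2.0], margin=0.0)
        with pytest.raises(ValueError):
            tost([1.0], [1.0, 2.0], margin=0.5)


class TestMarginPolicy:
    def test_absolute(self):
        assert margin_policy([1, 2], [3, 4], MarginPolicy(None, 0.3)) == 0.3

    def test_cohens_d(self):
        # pooled sd 2 -> margin d * 2
        a = np.array([0.0, 4.0])  # sd 2*sqrt(2)... build exact pooled sd 2
        a = np.array([1.0, 3.0, 5.0])  # sd 2
        b = np.array([2.0, 4.0, 6.0])  # sd 2
        assert margin_policy(a, b, MarginPolicy(cohens_d=0.5)) == pytest.approx(1.0)

    def test_zero_sd_falls_back_to_floor(self):
        m = margin_policy([1.0, 1.0], [1.0, 1.0], MarginPolicy(cohens_d=0.5, floor=1e-6))
        assert m == 1e-6

    def test_exactly_one_policy(self):
        with pytest.raises(ValueError):
            MarginPolicy(cohens_d=0.5, absolute=0.3)


def test_zscore_pipeline_forces_degenerate_equivalence(rng):
    """Per-subject within-mask means after z-score are all ~0, so TOST between
    any two cohorts is degenerate with p_max = 0."""
    from mrinorm.normalize import zscore_mask
    mask = np.zeros((10, 10, 10), dtype=np.uint8)
    mask[2:8, 2:8, 2:8] = 1
    means = {"A": [], "B": []}
    for grp, gain in (("A", 1.0), ("B", 2.5)):
        for _ in range(6):
            v = Volume3D(rng.random((10, 10, 10)) * 100 * gain + 7)
            z = zscore_mask(v, mask)
            means[grp].append(z.data[mask > 0].mean())
    res = tost(means["A"], means["B"], margin=1e-6)
    assert res.degenerate
    assert res.p_max == 0.0
    assert res.pooled_sd <= 1e-12
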