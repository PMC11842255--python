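"""Per-subject intensity-moment summaries and TOST equivalence testing.

The equivalence machinery is the two one-sided tests (TOST) procedure built
on the classical equal-variance two-sample t-test: two cohorts' per-subject
summaries are declared equivalent when both one-sided tests against the
margins -delta and +delta reject. The reported p-value is the larger of the
two one-sided p-values (``p_max``), so ``p_max < alpha`` is the equivalence
decision.

Because no equivalence margin is given by the comparison design itself, the
margin is an explicit policy: either an absolute value in the units of the
compared moment, or a Cohen's-d multiple of the two groups' pooled SD
(default d = 0.5, with an absolute floor for degenerate zero-variance
groups). The chosen margin is always recorded in the result.

Exactly-normalized data (e.g. per-subject means after within-mask z-score)
have zero between-subject spread; the t statistic is then 0/0. The
degenerate rule replaces it: with pooled SD ~ 0, equivalence holds with
``p_max = 0`` when the absolute mean difference is below the margin, else
``p_max = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .image_io import Volume3D

__all__ = [
    "MomentSummary",
    "TOSTResult",
    "MOMENT_NAMES",
    "masked_moments",
    "pooled_sd",
    "tost",
    "margin_policy",
    "MarginPolicy",
]

MOMENT_NAMES = ("mean", "variance", "skewness", "kurtosis")

#: Pooled SDs at or below this absolute tolerance are treated as exactly zero
#: in the degenerate TOST branch (float arithmetic leaves ~1e-17 residue on
#: analytically-zero spreads).
ZERO_SD_TOL = 1e-12


@dataclass
class MomentSummary:
    """Within-mask intensity moments for one subject and region.

    ``variance`` is the sample (n-1) variance; ``skewness`` is the
    Fisher-Pearson sample coefficient g1; ``kurtosis`` is non-excess sample
    kurtosis g2 (a Gaussian tends to 3). Moments that need more voxels than
    the region has, or that are undefined on a constant region, are NaN with
    the corresponding flag in ``undefined``.
    """

    subject_id: str
    region: str
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    n_voxels: int
    undefined: frozenset[str] = frozenset()

    def moment(self, name: str) -> float:
        if name not in MOMENT_NAMES:
            raise KeyError(f"unknown moment '{name}'")
        return getattr(self, name)


@dataclass
class TOSTResult:
    comparison: tuple[str, str]
    moment: str
    margin: float
    p_lower: float
    p_upper: float
    p_max: float
    pooled_sd: float
    n_a: int
    n_b: int
    mean_diff: float = 0.0
    degenerate: bool = False

    def equivalent(self, alpha: float = 0.05) -> bool:
        return self.p_max < alpha


def masked_moments(vol: Volume3D, mask: np.ndarray,
                   subject_id: str = "", region: str = "organ") -> MomentSummary:
    """Sample moments of the voxel intensities inside a mask."""
    mask = np.asarray(mask)
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    vals = vol.data[mask > 0.5]
    n = int(vals.size)
    if n == 0:
        raise ValueError(f"mask '{region}' is empty")
    undefined: set[str] = set()
    mean = float(np.mean(vals))
    if n >= 2:
        variance = float(np.var(vals, ddof=1))
    else:
        variance, undefined = float("nan"), undefined | {"variance"}
    constant = n >= 2 and variance == 0.0
    if n >= 3 and not constant:
        skewness = float(stats.skew(vals, bias=True))
    else:
        skewness = float("nan")
        undefined |= {"skewness"}
    if n >= 4 and not constant:
        kurtosis = float(stats.kurtosis(vals, fisher=False, bias=True))
    else:
        kurtosis = float("nan")
        undefined |= {"kurtosis"}
    if constant:
        variance = 0.0
    return MomentSummary(subject_id, region, mean, variance, skewness,
                         kurtosis, n, frozenset(undefined))


def pooled_sd(s_a: float, n_a: int, s_b: float, n_b: int) -> float:
    """Two-group pooled sample SD:
    sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2))."""
    if n_a < 2 or n_b < 2:
        raise ValueError(f"both groups need n >= 2, got n_a={n_a}, n_b={n_b}")
    if s_a < 0 or s_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    return float(np.sqrt(((n_a - 1) * s_a ** 2 + (n_b - 1) * s_b ** 2)
                         / (n_a + n_b - 2)))


@dataclass(frozen=True)
class MarginPolicy:
    """Equivalence-margin policy: Cohen's-d multiple of the pooled SD, or an
    absolute margin; ``floor`` is the fallback when the pooled SD is zero."""

    cohens_d: float | None = 0.5
    absolute: float | None = None
    floor: float = 1e-6

    def __post_init__(self) -> None:
        if (self.cohens_d is None) == (self.absolute is None):
            raise ValueError("specify exactly one of cohens_d or absolute")
        if self.floor <= 0:
            raise ValueError(f"floor must be positive, got {self.floor}")


def margin_policy(values_a, values_b, policy: MarginPolicy) -> float:
    """Resolve a margin policy to a positive margin for two samples."""
    if policy.absolute is not None:
        if policy.absolute <= 0:
            raise ValueError(f"absolute margin must be positive, got {policy.absolute}")
        return float(policy.absolute)
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("cohens_d policy needs n >= 2 per group")
    sp = pooled_sd(float(np.std(a, ddof=1)), a.size, float(np.std(b, ddof=1)), b.size)
    margin = policy.cohens_d * sp
    if margin <= policy.floor:
        return float(policy.floor)
    return float(margin)


def tost(values_a, values_b, margin: float,
         comparison: tuple[str, str] = ("A", "B"), moment: str = "mean",
         welch: bool = False) -> TOSTResult:
    """Two one-sided equal-variance t-tests of equivalence within ±margin.

    Tests H0: diff <= -margin (p_lower) and H0: diff >= +margin (p_upper)
    with diff = mean_a - mean_b, pooled-SD standard error and
    df = n_a + n_b - 2 (Welch variant available via ``welch=True``).
    Returns both p-values and ``p_max = max(p_lower, p_upper)``.
    """
    if margin <= 0:
        raise ValueError(f"margin must be positive, got {margin}")
    a = np.asarray(values_a, dtype=np.float64).ravel()
    b = np.asarray(values_b, dtype=np.float64).ravel()
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError(f"both groups need n >= 2 finite values, got {a.size}, {b.size}")
    n_a, n_b = int(a.size), int(b.size)
    diff = float(np.mean(a) - np.mean(b))
    s_a, s_b = float(np.std(a, ddof=1)), float(np.std(b, ddof=1))
    sp = pooled_sd(s_a, n_a, s_b, n_b)

    scale = max(1.0, abs(float(np.mean(a))), abs(float(np.mean(b))))
    if sp <= ZERO_SD_TOL * scale:
        # exactly-normalized data: zero between-subject spread
        p = 0.0 if abs(diff) < margin else 1.0
        return TOSTResult(comparison, moment, margin, p, p, p, sp,
                          n_a, n_b, diff, degenerate=True)

    if welch:
        se = float(np.sqrt(s_a ** 2 / n_a + s_b ** 2 / n_b))
        num = (s_a ** 2 / n_a + s_b ** 2 / n_b) ** 2
        den = ((s_a ** 2 / n_a) ** 2 / (n_a - 1) + (s_b ** 2 / n_b) ** 2 / (n_b - 1))
        df = num / den
    else:
        se = sp * float(np.sqrt(1.0 / n_a + 1.0 / n_b))
        df = n_a + n_b - 2
    t_lower = (diff + margin) / se
    t_upper = (diff - margin) / se
    p_lower = float(stats.t.sf(t_lower, df))   # H0: diff <= -margin
    p_upper = float(stats.t.cdf(t_upper, df))  # H0: diff >= +margin
    return TOSTResult(comparison, moment, margin, p_lower, p_upper,
                      max(p_lower, p_upper), sp, n_a, n_b, diff)
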