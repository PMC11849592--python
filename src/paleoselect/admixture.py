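"""Admixture-informed neutrality tests for a focal allele-frequency trajectory.

Two complementary tests ask whether the frequency observed in an admixed
offspring population is compatible with neutral inheritance from its two
parental populations:

1. *Expected-range binomial test.*  The parental 95% CI bounds are mixed by
   the ancestry proportions, ``f_exp_lower = fx_lower*a_x + fy_lower*a_y``
   (likewise for the upper bound), and two one-sided binomial tests are run
   against the observed offspring allele count — a deficit test against the
   lower bound and an excess test against the upper bound.  The smaller of
   the two p-values is kept.  Because no multiple-testing correction is
   applied to that minimum, the test is slightly anti-conservative; the
   calibration suite quantifies this.

2. *Empirical outlier test.*  The difference ``F_exp - F_obs`` (point
   estimates) is computed for thousands of variants in putatively neutral
   regions; its 2.5% and 97.5% percentiles serve as significance thresholds
   for the focal variant's delta.  Drift, bottlenecks and admixture noise are
   absorbed into the empirical null by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from paleoselect.popfreq import FrequencyEstimate, estimate_frequency


class UnderpoweredNullError(ValueError):
    """Too few neutral variants to form an empirical null distribution."""


@dataclass(frozen=True)
class AdmixtureEvent:
    """Two-way admixture: offspring = a_x * parent_x + a_y * parent_y."""

    parent_x: str
    parent_y: str
    a_x: float
    a_y: float

    def __post_init__(self) -> None:
        if self.a_x < 0 or self.a_y < 0:
            raise ValueError("ancestry proportions must be non-negative")
        if abs(self.a_x + self.a_y - 1.0) > 1e-9:
            raise ValueError("ancestry proportions must sum to 1")


@dataclass(frozen=True)
class ExpectedRange:
    """Frequency range expected in the offspring under neutral admixture."""

    f_exp_lower: float
    f_exp_upper: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_exp_lower <= self.f_exp_upper <= 1:
            raise ValueError("need 0 <= f_exp_lower <= f_exp_upper <= 1")


@dataclass(frozen=True)
class AdmixtureTestResult:
    """Outcome of the two one-sided binomial tests against an expected range."""

    p_low: float
    p_high: float
    p_min: float
    observed: FrequencyEstimate
    range: ExpectedRange

    @property
    def significant(self) -> bool:
        return self.p_min < 0.05


def expected_range(
    fx: FrequencyEstimate, fy: FrequencyEstimate, event: AdmixtureEvent
) -> ExpectedRange:
    """Mix the parental CI bounds by ancestry proportion.

    Linear in ``a_x`` and monotone in each parental bound; with ``a_x = 1``
    the range collapses to parent x's confidence interval.
    """
    return ExpectedRange(
        f_exp_lower=fx.ci_lower * event.a_x + fy.ci_lower * event.a_y,
        f_exp_upper=fx.ci_upper * event.a_x + fy.ci_upper * event.a_y,
    )


def admixture_binomial_test(
    observed_k: int, observed_n: int, range_: ExpectedRange
) -> AdmixtureTestResult:
    """Two one-sided binomial tests of an observed allele count.

    ``p_low`` is the inclusive lower-tail mass P(X <= k | n, f_exp_lower) and
    detects a deficit below the expected range; ``p_high`` is the inclusive
    upper-tail mass P(X >= k | n, f_exp_upper) and detects an excess above
    it.  The minimum of the two is reported, significant below 0.05 — the
    reading under which significance corresponds to the observed CI falling
    outside the expected range.
    """
    if observed_n < 1:
        raise ValueError("observed_n must be >= 1")
    if not 0 <= observed_k <= observed_n:
        raise ValueError("need 0 <= observed_k <= observed_n")
    p_low = float(
        stats.binom.cdf(observed_k, observed_n, range_.f_exp_lower)
    )
    # inclusive upper tail: P(X >= k) = sf(k - 1)
    p_high = float(
        stats.binom.sf(observed_k - 1, observed_n, range_.f_exp_upper)
    )
    p_low = min(p_low, 1.0)
    p_high = min(p_high, 1.0)
    return AdmixtureTestResult(
        p_low=p_low,
        p_high=p_high,
        p_min=min(p_low, p_high),
        observed=estimate_frequency(observed_k, observed_n),
        range=range_,
    )


@dataclass(frozen=True)
class NeutralDeltaDistribution:
    """Empirical null of F_exp - F_obs over neutral variants."""

    deltas: np.ndarray
    lower_threshold: float
    upper_threshold: float

    def __post_init__(self) -> None:
        if self.lower_threshold > self.upper_threshold:
            raise ValueError("lower_threshold must be <= upper_threshold")

    def quantile_of(self, delta: float) -> float:
        """Empirical quantile of ``delta`` within the null (midrank)."""
        d = np.asarray(self.deltas)
        return float(((d < delta).sum() + 0.5 * (d == delta).sum()) / len(d))


class OutlierClass(str, Enum):
    NEUTRAL = "neutral"
    SIGNIFICANT_LOW = "significant_low"
    SIGNIFICANT_HIGH = "significant_high"


def neutral_delta_distribution(
    parental_x: Sequence[FrequencyEstimate],
    parental_y: Sequence[FrequencyEstimate],
    offspring: Sequence[FrequencyEstimate],
    event: AdmixtureEvent,
    lower_percentile: float = 2.5,
    upper_percentile: float = 97.5,
    min_variants: int = 100,
    interpolation: str = "linear",
) -> NeutralDeltaDistribution:
    """Empirical null from per-variant F_exp - F_obs on neutral variants.

    ``F_exp`` mixes the parental *point* estimates by ancestry (CI bounds play
    no role here); ``F_obs`` is the offspring point estimate.  Thresholds are
    the requested percentiles, linearly interpolated between order statistics
    by default (``interpolation="nearest"`` selects nearest-rank instead).
    """
    if not len(parental_x) == len(parental_y) == len(offspring):
        raise ValueError("parental and offspring estimate lists must align")
    if len(offspring) < min_variants:
        raise UnderpoweredNullError(
            f"only {len(offspring)} neutral variants; need >= {min_variants}"
        )
    f_exp = np.array([fx.freq * event.a_x + fy.freq * event.a_y
                      for fx, fy in zip(parental_x, parental_y)])
    f_obs = np.array([fo.freq for fo in offspring])
    deltas = f_exp - f_obs
    method = {"linear": "linear", "nearest": "nearest"}[interpolation]
    lo, hi = np.percentile(deltas, [lower_percentile, upper_percentile], method=method)
    return NeutralDeltaDistribution(
        deltas=deltas, lower_threshold=float(lo), upper_threshold=float(hi)
    )


def deltas_to_distribution(
    deltas: np.ndarray,
    lower_percentile: float = 2.5,
    upper_percentile: float = 97.5,
    interpolation: str = "linear",
) -> NeutralDeltaDistribution:
    """Build a null directly from a precomputed delta vector."""
    deltas = np.asarray(deltas, dtype=float)
    method = {"linear": "linear", "nearest": "nearest"}[interpolation]
    lo, hi = np.percentile(deltas, [lower_percentile, upper_percentile], method=method)
    return NeutralDeltaDistribution(
        deltas=deltas, lower_threshold=float(lo), upper_threshold=float(hi)
    )


def empirical_outlier_test(
    focal_delta: float, null: NeutralDeltaDistribution
) -> tuple[OutlierClass, float]:
    """Classify a focal delta against the empirical neutral null.

    Returns the classification (strictly outside a threshold is significant)
    and the focal delta's empirical quantile within the null.
    """
    quantile = null.quantile_of(focal_delta)
    if focal_delta < null.lower_threshold:
        return OutlierClass.SIGNIFICANT_LOW, quantile
    if focal_delta > null.upper_threshold:
        return OutlierClass.SIGNIFICANT_HIGH, quantile
    return OutlierClass.NEUTRAL, quantile
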