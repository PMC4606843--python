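"""Closed-form power, sample-size and item-count functions.

Four tests on scale scores of parallel items are covered, each with power
expressed directly in terms of Cronbach alpha ``C_a``:

* ``ALPHA_TEST`` — significance of ``C_a`` itself against a zero null, via
  the Fisher z-transform of the test-retest correlation (which equals
  ``C_a`` for parallel items).
* ``PRE_POST`` — paired comparison of pre- vs post-intervention means in one
  group of ``N`` subjects:
  ``phi = Phi(|D| * sqrt(N / (2*(1/C_a - 1))) - z_{1-a/2})``.
* ``BETWEEN_WITHIN`` — difference of pre-post changes between two groups of
  ``N`` subjects each (group x time interaction); same form with a factor-4
  denominator.
* ``TWO_SAMPLE`` — cross-sectional mean comparison between two groups of
  ``N`` subjects each: ``phi = Phi(|D| * sqrt(C_a*N/2) - z_{1-a/2})``.

``D`` is the effect size standardized by the true-score SD ``sigma_mu``.
Because the true-score variance is held fixed, every power function
increases with ``C_a`` and, for a given ``C_a``, does not depend on the
number of items ``k``.  By the convention used throughout, the vanishing
probability mass in the opposite rejection tail is dropped, so power at a
null effect equals ``alpha/2``; ``both_tails=True`` restores the exact
two-sided value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

from scipy.stats import norm

from .reliability import DomainError

__all__ = [
    "Design",
    "DesignSpec",
    "PowerResult",
    "SampleSizeResult",
    "ItemsResult",
    "InfeasibleDesignError",
    "z_pair",
    "power_alpha_test",
    "power_prepost",
    "power_between_within",
    "power_two_sample",
    "samplesize_prepost",
    "samplesize_between_within",
    "samplesize_two_sample",
    "items_required",
    "power_rho_parameterized",
    "theoretical_power",
]

logger = logging.getLogger(__name__)


class Design(str, Enum):
    """The four supported comparison designs."""

    ALPHA_TEST = "alpha"
    PRE_POST = "prepost"
    BETWEEN_WITHIN = "bw"
    TWO_SAMPLE = "ts"


class InfeasibleDesignError(DomainError):
    """No finite number of items can reach the requested power at this N."""


@dataclass(frozen=True)
class DesignSpec:
    """A comparison design for power analysis.

    ``n`` is the *total* number of subjects for ``ALPHA_TEST`` and
    ``PRE_POST`` and the number of subjects *per group* for
    ``BETWEEN_WITHIN`` and ``TWO_SAMPLE``.  ``delta_std`` is the mean shift
    divided by the true-score SD; it is ignored for ``ALPHA_TEST``.
    """

    design: Design
    delta_std: float
    n: int
    c_alpha: float
    alpha_level: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "design", Design(self.design))
        if not 0.0 < self.alpha_level < 1.0:
            raise DomainError(f"alpha_level must lie in (0, 1), got {self.alpha_level}")
        if not 0.0 < self.c_alpha <= 1.0:
            raise DomainError(f"c_alpha must lie in (0, 1], got {self.c_alpha}")
        n_min = 4 if self.design is Design.ALPHA_TEST else 2
        if not float(self.n).is_integer() or self.n < n_min:
            raise DomainError(
                f"{self.design.value} design needs integer n >= {n_min}, got {self.n}"
            )


@dataclass(frozen=True)
class PowerResult:
    """A theoretical power value together with the design that produced it."""

    power: float
    design: DesignSpec


class SampleSizeResult(NamedTuple):
    """Continuous sample-size solution and its conservative ceiling."""

    n: int
    n_continuous: float


@dataclass(frozen=True)
class ItemsResult:
    """Required item count: conservative ceiling plus the continuous solution.

    For the between-within design the published item-count formula carries a
    factor 2 where self-consistent inversion of the power function gives a
    factor 4; both values are reported (``k_continuous_printed`` is None for
    the other designs, where the two coincide).
    """

    k: int
    k_continuous: float
    k_continuous_printed: float | None = None


def z_pair(alpha_level: float, power: float) -> float:
    """Quantile sum ``z = Phi^-1(1 - alpha/2) + Phi^-1(power)`` used by all
    sample-size formulas."""
    if not 0.0 < alpha_level < 1.0:
        raise DomainError(f"alpha_level must lie in (0, 1), got {alpha_level}")
    if not 0.0 < power < 1.0:
        raise DomainError(f"power must lie in (0, 1), got {power}")
    return float(norm.ppf(1.0 - alpha_level / 2.0) + norm.ppf(power))


def power_alpha_test(
    c_alpha: float, n: int, alpha_level: float = 0.05, both_tails: bool = False
) -> float:
    """Power of the two-tailed Fisher-z test that Cronbach alpha is zero.

    The test-retest correlation of parallel-item scale scores equals
    ``C_a``, so a sample of ``n`` paired administrations supports the usual
    correlation test: with ``z(r) = arctanh(r)`` the statistic
    ``sqrt(n-3) * z(r)`` is approximately standard normal, with mean shift
    ``sqrt(n-3) * (arctanh(C_a) + C_a/(2*(n-1)))`` under the alternative
    (the second term is the small-sample bias of the transform).

    Requires ``n >= 4`` (the z-variance is ``1/(n-3)``) and ``C_a < 1``.
    """
    if not 0.0 <= c_alpha < 1.0:
        raise DomainError(f"c_alpha must lie in [0, 1) for the Fisher z test, got {c_alpha}")
    if not float(n).is_integer() or n <= 3:
        raise DomainError(f"Fisher z test needs integer n >= 4, got {n}")
    _check_alpha_level(alpha_level)
    z_crit = norm.ppf(1.0 - alpha_level / 2.0)
    shift = math.sqrt(n - 3) * (math.atanh(c_alpha) + c_alpha / (2.0 * (n - 1)))
    power = 1.0 - norm.cdf(z_crit - shift)
    if both_tails:
        power += norm.cdf(-z_crit - shift)
    return float(power)


def power_prepost(
    delta_std: float,
    c_alpha: float,
    n: int,
    alpha_level: float = 0.05,
    both_tails: bool = False,
) -> float:
    """Power of the paired pre-post test for ``n`` subjects in total.

    ``phi = Phi(|D| * sqrt(N / (2*(1/C_a - 1))) - z_{1-a/2})``; independent
    of the number of items for a given ``C_a``.  ``C_a = 1`` is rejected:
    the paired difference then has zero variance and the test degenerates.
    """
    if not 0.0 < c_alpha < 1.0:
        raise DomainError(f"pre-post power needs c_alpha in (0, 1), got {c_alpha}")
    _check_n(n, 2)
    ncp = abs(delta_std) * math.sqrt(n / (2.0 * (1.0 / c_alpha - 1.0)))
    return _one_tail_power(ncp, alpha_level, both_tails)


def power_between_within(
    delta_std: float,
    c_alpha: float,
    n_per_group: int,
    alpha_level: float = 0.05,
    both_tails: bool = False,
) -> float:
    """Power of the group-by-time interaction test, ``n_per_group`` subjects per arm.

    ``phi = Phi(|D| * sqrt(N / (4*(1/C_a - 1))) - z_{1-a/2})``.
    """
    if not 0.0 < c_alpha < 1.0:
        raise DomainError(f"between-within power needs c_alpha in (0, 1), got {c_alpha}")
    _check_n(n_per_group, 2)
    ncp = abs(delta_std) * math.sqrt(n_per_group / (4.0 * (1.0 / c_alpha - 1.0)))
    return _one_tail_power(ncp, alpha_level, both_tails)


def power_two_sample(
    delta_std: float,
    c_alpha: float,
    n_per_group: int,
    alpha_level: float = 0.05,
    both_tails: bool = False,
) -> float:
    """Power of the cross-sectional two-group comparison, ``n_per_group`` per arm.

    ``phi = Phi(|D| * sqrt(C_a * N / 2) - z_{1-a/2})``.  ``C_a = 1`` is the
    classical error-free two-sample normal test and is allowed.
    """
    if not 0.0 < c_alpha <= 1.0:
        raise DomainError(f"two-sample power needs c_alpha in (0, 1], got {c_alpha}")
    _check_n(n_per_group, 2)
    ncp = abs(delta_std) * math.sqrt(c_alpha * n_per_group / 2.0)
    return _one_tail_power(ncp, alpha_level, both_tails)


def samplesize_prepost(
    delta_std: float, c_alpha: float, alpha_level: float = 0.05, target_power: float = 0.8
) -> SampleSizeResult:
    """Total N for the pre-post design: ``N = 2*(1/C_a - 1) * z^2 / D^2``."""
    if delta_std == 0.0:
        raise DomainError("delta_std must be nonzero for sample-size determination")
    if not 0.0 < c_alpha < 1.0:
        raise DomainError(f"pre-post sample size needs c_alpha in (0, 1), got {c_alpha}")
    z = z_pair(alpha_level, target_power)
    n_cont = 2.0 * (1.0 / c_alpha - 1.0) * z ** 2 / delta_std ** 2
    return SampleSizeResult(math.ceil(n_cont), n_cont)


def samplesize_between_within(
    delta_std: float, c_alpha: float, alpha_level: float = 0.05, target_power: float = 0.8
) -> SampleSizeResult:
    """Per-group N for the between-within design: ``N = 4*(1/C_a - 1) * z^2 / D^2``."""
    if delta_std == 0.0:
        raise DomainError("delta_std must be nonzero for sample-size determination")
    if not 0.0 < c_alpha < 1.0:
        raise DomainError(f"between-within sample size needs c_alpha in (0, 1), got {c_alpha}")
    z = z_pair(alpha_level, target_power)
    n_cont = 4.0 * (1.0 / c_alpha - 1.0) * z ** 2 / delta_std ** 2
    return SampleSizeResult(math.ceil(n_cont), n_cont)


def samplesize_two_sample(
    delta_std: float, c_alpha: float, alpha_level: float = 0.05, target_power: float = 0.8
) -> SampleSizeResult:
    """Per-group N for the two-sample design: ``N = 2 * z^2 / (C_a * D^2)``."""
    if delta_std == 0.0:
        raise DomainError("delta_std must be nonzero for sample-size determination")
    if not 0.0 < c_alpha <= 1.0:
        raise DomainError(f"two-sample sample size needs c_alpha in (0, 1], got {c_alpha}")
    z = z_pair(alpha_level, target_power)
    n_cont = 2.0 * z ** 2 / (c_alpha * delta_std ** 2)
    return SampleSizeResult(math.ceil(n_cont), n_cont)


def items_required(
    design: Design | str,
    rho: float,
    n: int,
    delta_std: float,
    alpha_level: float = 0.05,
    target_power: float = 0.8,
    formula: str = "consistent",
) -> ItemsResult:
    """Number of items needed to reach ``target_power`` at fixed ``n`` and ``rho``.

    * ``PRE_POST``: ``k = 2*(1/rho - 1) * z^2 / (N * D^2)``.
    * ``BETWEEN_WITHIN``: the published formula has numerator factor 2, but
      inverting the between-within power function in ``k`` gives factor 4
      (consistent with the per-group sample-size formula).  The consistent
      value is returned by default; ``formula="printed"`` selects the
      published one, and both continuous solutions are always carried on the
      result.
    * ``TWO_SAMPLE``: ``k = [2*(1/rho - 1) * z^2 / D^2] / (N - 2*z^2/D^2)``,
      feasible only when ``N > 2*z^2/D^2`` — with too few subjects no number
      of items can reach the target (power is bounded by the error-free
      limit).
    """
    design = Design(design)
    if design is Design.ALPHA_TEST:
        raise DomainError("items_required is undefined for the alpha-significance test")
    if not 0.0 < rho < 1.0:
        raise DomainError(f"items_required needs rho in (0, 1), got {rho}")
    if delta_std == 0.0:
        raise DomainError("delta_std must be nonzero")
    if formula not in ("consistent", "printed"):
        raise DomainError(f"formula must be 'consistent' or 'printed', got {formula!r}")
    _check_n(n, 2)
    z2 = z_pair(alpha_level, target_power) ** 2
    base = 2.0 * (1.0 / rho - 1.0) * z2 / delta_std ** 2
    printed_cont: float | None = None
    if design is Design.PRE_POST:
        k_cont = base / n
    elif design is Design.BETWEEN_WITHIN:
        printed_cont = base / n
        k_cont = 2.0 * base / n
        if formula == "printed":
            k_cont, printed_cont = printed_cont, k_cont
        else:
            logger.info(
                "between-within items: consistent k=%.4f (printed-formula value %.4f)",
                k_cont,
                printed_cont,
            )
    else:  # TWO_SAMPLE
        denom = n - 2.0 * z2 / delta_std ** 2
        if denom <= 0.0:
            raise InfeasibleDesignError(
                f"two-sample design infeasible: need n > {2.0 * z2 / delta_std ** 2:.2f} "
                f"per group to reach power {target_power} at any item count"
            )
        k_cont = base / denom
    return ItemsResult(max(1, math.ceil(k_cont)), k_cont, printed_cont)


def power_rho_parameterized(
    design: Design | str,
    delta_std: float,
    rho: float,
    k: int,
    n: int,
    alpha_level: float = 0.05,
) -> float:
    """Power expressed in ``(rho, k)`` instead of Cronbach alpha.

    Algebraically identical to the alpha-parameterized functions after
    ``C_a = k*rho/(1 + rho*(k-1))``: any two instruments with equal alpha
    have equal power regardless of their item counts.
    """
    design = Design(design)
    if not 0.0 < rho <= 1.0:
        raise DomainError(f"rho must lie in (0, 1], got {rho}")
    if not k > 0:
        raise DomainError(f"k must be positive, got {k}")
    # real-valued k is allowed so the item-count formulas invert exactly,
    # including continuous solutions below one item
    c_alpha = k * rho / (1.0 + rho * (k - 1))
    if design is Design.ALPHA_TEST:
        return power_alpha_test(c_alpha, n, alpha_level)
    if design is Design.PRE_POST:
        return power_prepost(delta_std, c_alpha, n, alpha_level)
    if design is Design.BETWEEN_WITHIN:
        return power_between_within(delta_std, c_alpha, n, alpha_level)
    return power_two_sample(delta_std, c_alpha, n, alpha_level)


def theoretical_power(spec: DesignSpec, both_tails: bool = False) -> PowerResult:
    """Dispatch a :class:`DesignSpec` to its closed-form power function."""
    if spec.design is Design.ALPHA_TEST:
        p = power_alpha_test(spec.c_alpha, spec.n, spec.alpha_level, both_tails)
    elif spec.design is Design.PRE_POST:
        p = power_prepost(spec.delta_std, spec.c_alpha, spec.n, spec.alpha_level, both_tails)
    elif spec.design is Design.BETWEEN_WITHIN:
        p = power_between_within(
            spec.delta_std, spec.c_alpha, spec.n, spec.alpha_level, both_tails
        )
    else:
        p = power_two_sample(spec.delta_std, spec.c_alpha, spec.n, spec.alpha_level, both_tails)
    return PowerResult(power=p, design=spec)


def _one_tail_power(ncp: float, alpha_level: float, both_tails: bool) -> float:
    _check_alpha_level(alpha_level)
    z_crit = norm.ppf(1.0 - alpha_level / 2.0)
    power = norm.cdf(ncp - z_crit)
    if both_tails:
        power += norm.cdf(-ncp - z_crit)
    return float(power)


def _check_alpha_level(alpha_level: float) -> None:
    if not 0.0 < alpha_level < 1.0:
        raise DomainError(f"alpha_level must lie in (0, 1), got {alpha_level}")


def _check_n(n: float, minimum: int) -> None:
    # any positive real n is allowed: the closed forms are continuous in N and
    # the sample-size/power duality must hold for the continuous solution even
    # when it falls below a practical design size (DesignSpec enforces the
    # integer minimums for simulation)
    if not n > 0:
        raise DomainError(f"n must be positive, got {n}")
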