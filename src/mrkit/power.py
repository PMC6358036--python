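"""Instrument strength and statistical power for two-sample MR.

The first-stage F statistic gauges weak-instrument bias risk from the
variance explained (R^2) and the genetic-association sample size; F <= 10
is the conventional warning threshold.  Power for detecting a causal odds
ratio in a binary-outcome two-sample MR follows the standard normal
approximation for the IVW/Wald z-test with a standardized exposure:

    power = Phi(|ln OR| * sqrt(n * R^2 * K * (1-K)) - z_{1-alpha/2})

where n is the outcome-study size and K its case fraction.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from .exceptions import MrKitError

__all__ = ["f_statistic", "mr_power_binary", "min_detectable_or", "WEAK_INSTRUMENT_F"]

#: conventional weak-instrument threshold
WEAK_INSTRUMENT_F = 10.0


def f_statistic(r2: float, n: float, k: int | None = None, form: str = "single") -> float:
    """First-stage F statistic from reported R^2 and sample size.

    ``form='single'`` uses the single-regressor expression
    ``F = r2 (n - 2) / (1 - r2)``; ``form='multi'`` uses
    ``F = r2 (n - 1 - k) / (k (1 - r2))`` and requires ``k``.
    """
    if not 0.0 < r2 < 1.0:
        raise MrKitError(f"r2 must lie in (0, 1) (got {r2})")
    if n <= 2:
        raise MrKitError(f"sample size must exceed 2 (got {n})")
    if form == "single":
        return float(r2 * (n - 2) / (1.0 - r2))
    if form == "multi":
        if k is None or k < 1:
            raise MrKitError("multi-instrument form requires k >= 1")
        if n <= k + 1:
            raise MrKitError("sample size must exceed k + 1")
        return float(r2 * (n - 1 - k) / (k * (1.0 - r2)))
    raise MrKitError(f"unknown F-statistic form {form!r}")


def is_weak_instrument(f_value: float) -> bool:
    return f_value <= WEAK_INSTRUMENT_F


def _validate_power_inputs(n_total, case_fraction, r2, alpha):
    if n_total <= 0:
        raise MrKitError("n_total must be positive")
    if not 0.0 < case_fraction < 1.0:
        raise MrKitError(f"case_fraction must lie in (0, 1) (got {case_fraction})")
    if not 0.0 < r2 < 1.0:
        raise MrKitError(f"r2 must lie in (0, 1) (got {r2})")
    if not 0.0 < alpha < 1.0:
        raise MrKitError(f"alpha must lie in (0, 1) (got {alpha})")


def mr_power_binary(
    n_total: float,
    case_fraction: float,
    r2: float,
    or_alt: float,
    alpha: float = 0.05,
) -> float:
    """Power to detect a causal OR (per SD of exposure) with a binary outcome.

    Symmetric in ``or_alt`` vs ``1/or_alt``; at ``or_alt = 1`` the two-sided
    test rejects with probability ``alpha/2`` on each side (``alpha/2``
    reported, the upper tail).
    """
    _validate_power_inputs(n_total, case_fraction, r2, alpha)
    if or_alt <= 0:
        raise MrKitError(f"or_alt must be positive (got {or_alt})")
    b = abs(np.log(or_alt))
    ncp = b * np.sqrt(n_total * r2 * case_fraction * (1.0 - case_fraction))
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(ncp - z_crit))


def min_detectable_or(
    n_total: float,
    case_fraction: float,
    r2: float,
    target_power: float = 0.8,
    alpha: float = 0.05,
) -> float:
    """Smallest OR >= 1 detectable at ``target_power`` (monotone root-finding)."""
    _validate_power_inputs(n_total, case_fraction, r2, alpha)
    if not 0.0 < target_power < 1.0:
        raise MrKitError(f"target_power must lie in (0, 1) (got {target_power})")
    # closed-form inversion, then a bracketing solve for robustness
    scale = np.sqrt(n_total * r2 * case_fraction * (1.0 - case_fraction))
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    b0 = (z_crit + stats.norm.ppf(target_power)) / scale
    if b0 <= 0:
        return 1.0

    def gap(b):
        return mr_power_binary(n_total, case_fraction, r2, float(np.exp(b)), alpha) - target_power

    lo, hi = b0 * 0.5, b0 * 2.0
    while gap(lo) > 0 and lo > 1e-12:
        lo *= 0.5
    while gap(hi) < 0 and hi < 50:
        hi *= 2.0
    b = optimize.brentq(gap, lo, hi, xtol=1e-12, rtol=1e-14)
    return float(np.exp(b))


def power_monte_carlo(
    n_total: float,
    case_fraction: float,
    r2: float,
    or_alt: float,
    alpha: float = 0.05,
    n_reps: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo check of the analytic power formula.

    Simulates the Wald z-statistic under the alternative, ``z ~ N(ncp, 1)``,
    and reports the two-sided rejection rate.  Kept in the package so the
    analytic formula can be cross-validated anywhere, not just in tests.
    """
    _validate_power_inputs(n_total, case_fraction, r2, alpha)
    rng = np.random.default_rng(seed)
    ncp = np.log(or_alt) * np.sqrt(n_total * r2 * case_fraction * (1.0 - case_fraction))
    z = rng.standard_normal(int(n_reps)) + ncp
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    # count rejections in the direction of the alternative (matching the
    # one-tail analytic approximation; the opposite tail is negligible away
    # from the null and exactly alpha/2 at it)
    if ncp >= 0:
        return float(np.mean(z > z_crit))
    return float(np.mean(z < -z_crit))
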