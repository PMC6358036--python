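"""Pleiotropy and heterogeneity diagnostics for multi-instrument MR.

When several SNPs instrument the same exposure, their per-SNP causal
estimates should agree up to sampling error if all instruments are valid.
This module provides the standard battery run on such analyses:

* Cochran's Q heterogeneity test across Wald ratios;
* MR-Egger regression, whose free intercept estimates average directional
  pleiotropy (consistent under the InSIDE assumption), together with the
  I2_GX reliability statistic quantifying regression dilution from
  exposure-side measurement error;
* the weighted median (valid while >= 50% of weight comes from valid
  instruments) and the weighted mode (valid while the largest homogeneous
  cluster is valid), both with parametric-bootstrap SEs;
* funnel-plot data and subset sensitivity reruns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data import Z_95, HarmonizedInstrumentSet, MrEstimate
from .estimators import (
    IVWEstimator,
    MaximumLikelihoodMR,
    WaldRatioEstimator,
    _extract,
    _finalize,
    _MrEstimatorBase,
    wald_ratio,
    wald_se_delta,
)
from .exceptions import EstimationError, MrKitError

__all__ = [
    "HeterogeneityResult",
    "EggerResult",
    "cochran_q",
    "i2_gx",
    "egger",
    "weighted_median",
    "weighted_mode",
    "funnel_data",
    "subset_rerun",
    "EggerRegression",
    "WeightedMedianEstimator",
    "WeightedModeEstimator",
]


class HeterogeneityResult:
    """Cochran's Q statistic with its chi-square p-value."""

    def __init__(self, Q: float, df: int, p: float):
        self.Q = float(Q)
        self.df = int(df)
        self.p = float(p)

    def __repr__(self):
        return f"HeterogeneityResult(Q={self.Q:.4g}, df={self.df}, p={self.p:.4g})"


class EggerResult:
    """MR-Egger slope, intercept (average directional pleiotropy), and I2_GX."""

    def __init__(self, slope, slope_se, intercept, intercept_se, intercept_p, i2_gx, n_snps):
        self.slope = float(slope)
        self.slope_se = float(slope_se)
        self.intercept = float(intercept)
        self.intercept_se = float(intercept_se)
        self.intercept_p = float(intercept_p)
        self.i2_gx = float(i2_gx)
        self.n_snps = int(n_snps)

    @property
    def slope_ci(self) -> tuple[float, float]:
        return (self.slope - Z_95 * self.slope_se, self.slope + Z_95 * self.slope_se)


def _per_snp_arrays(per_snp_estimates):
    arr = np.asarray([(float(t), float(s)) for t, s in per_snp_estimates], dtype=float)
    if arr.size == 0:
        raise EstimationError("no per-SNP estimates supplied")
    thetas, ses = arr[:, 0], arr[:, 1]
    if np.any(ses <= 0):
        raise EstimationError("per-SNP SEs must be > 0")
    return thetas, ses


def cochran_q(per_snp_estimates, pooled: float) -> HeterogeneityResult:
    """Cochran's Q against a pooled estimate: ``Q = sum w_j (t_j - pooled)^2``."""
    thetas, ses = _per_snp_arrays(per_snp_estimates)
    k = thetas.size
    if k < 2:
        raise EstimationError(f"Cochran's Q needs >= 2 instruments (got {k})")
    w = 1.0 / ses**2
    Q = float(np.sum(w * (thetas - pooled) ** 2))
    return HeterogeneityResult(Q, k - 1, float(stats.chi2.sf(Q, k - 1)))


def i2_gx(gamma_hats, sigma_xs) -> float:
    """Exposure-instrument reliability statistic in [0, 1].

    ``Q_GX`` is the precision-weighted spread of the exposure effects; values
    near 1 mean the spread dwarfs measurement error, so MR-Egger suffers
    little regression dilution.
    """
    g = np.asarray(gamma_hats, dtype=float)
    sx = np.asarray(sigma_xs, dtype=float)
    if g.size < 2:
        raise EstimationError(f"I2_GX needs >= 2 instruments (got {g.size})")
    if np.any(sx <= 0):
        raise EstimationError("sigma_x values must be > 0")
    w = 1.0 / sx**2
    gbar = float(np.sum(w * g) / np.sum(w))
    q_gx = float(np.sum((g - gbar) ** 2 * w))
    if q_gx <= 0:
        return 0.0
    return max(0.0, (q_gx - (g.size - 1)) / q_gx)


class EggerRegression(_MrEstimatorBase):
    """MR-Egger: weighted regression of outcome on exposure effects with intercept.

    Instruments are automatically oriented so every exposure effect is >= 0
    before fitting (the intercept is orientation-dependent; this is the
    standard convention).  Weights are ``1/sigma_y^2`` and the coefficient
    covariance is the known-variance (fixed-effect) ``(X'WX)^-1``.

    Fitted attributes: ``theta_`` (slope), ``se_``, ``intercept_``,
    ``intercept_se_``, ``intercept_p_``, ``i2_gx_``.
    """

    method_label = "egger"

    def __init__(self, delta_order: int = 1):
        self.delta_order = delta_order

    def fit(self, X, y=None):
        gamma, sx, Gamma, sy, snp_ids, meta = _extract(X)
        k = gamma.size
        if k < 3:
            raise EstimationError(f"MR-Egger needs >= 3 instruments (got {k})")
        flip = np.where(gamma < 0, -1.0, 1.0)
        g, G = gamma * flip, Gamma * flip
        design = np.column_stack([np.ones(k), g])
        w = 1.0 / sy**2
        xtw = design.T * w
        normal = xtw @ design
        coef = np.linalg.solve(normal, xtw @ G)
        cov = np.linalg.inv(normal)
        self.intercept_ = float(coef[0])
        self.intercept_se_ = float(np.sqrt(cov[0, 0]))
        self.intercept_p_ = float(2.0 * stats.norm.sf(abs(self.intercept_ / self.intercept_se_)))
        self.i2_gx_ = i2_gx(g, sx)
        extras = {
            "intercept": self.intercept_,
            "intercept_se": self.intercept_se_,
            "intercept_p": self.intercept_p_,
            "i2_gx": self.i2_gx_,
            "n_reoriented": int(np.sum(flip < 0)),
        }
        return _finalize(self, float(coef[1]), float(np.sqrt(cov[1, 1])), meta, k, extras)

    def to_egger_result(self) -> EggerResult:
        return EggerResult(
            self.theta_, self.se_, self.intercept_, self.intercept_se_,
            self.intercept_p_, self.i2_gx_, self.n_snps_,
        )


def egger(instruments: HarmonizedInstrumentSet) -> EggerResult:
    """MR-Egger regression on a harmonized instrument set."""
    return EggerRegression().fit(instruments).to_egger_result()


def _weighted_median_core(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def _weighted_median_rows(R: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized weighted median of each row of R (weights per column)."""
    idx = np.argsort(R, axis=1, kind="stable")
    Rs = np.take_along_axis(R, idx, axis=1)
    wn = weights / np.sum(weights)
    ws = np.take_along_axis(np.broadcast_to(wn, R.shape), idx, axis=1)
    S = np.cumsum(ws, axis=1) - ws / 2.0
    k = R.shape[1]
    j = np.clip(np.sum(S < 0.5, axis=1), 1, k - 1)
    rows = np.arange(R.shape[0])
    s0, s1 = S[rows, j - 1], S[rows, j]
    r0, r1 = Rs[rows, j - 1], Rs[rows, j]
    frac = np.clip((0.5 - s0) / np.where(s1 > s0, s1 - s0, 1.0), 0.0, 1.0)
    return r0 + frac * (r1 - r0)


def _silverman_bandwidth(ratios: np.ndarray, phi: float) -> float:
    k = ratios.size
    sd = float(np.std(ratios, ddof=1))
    q75, q25 = np.percentile(ratios, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return phi * 0.9 * spread * k ** (-0.2)


def _weighted_mode_core(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    if np.ptp(ratios) == 0.0:
        return float(ratios[0])
    h = _silverman_bandwidth(ratios, phi)
    if h <= 0:
        return float(ratios[np.argmax(weights)])
    grid = np.linspace(ratios.min(), ratios.max(), 512)
    wn = weights / np.sum(weights)
    dens = wn @ np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)
    # np.argmax returns the first maximum: ties break to the smallest estimate
    return float(grid[np.argmax(dens)])


class _RatioRobustBase(_MrEstimatorBase):
    """Shared plumbing: ratios + weights from a set, parametric-bootstrap SE."""

    def _ratios(self, X):
        gamma, sx, Gamma, sy, snp_ids, meta = _extract(X)
        if gamma.size < 3:
            raise EstimationError(
                f"{self.method_label} estimator needs >= 3 instruments (got {gamma.size})"
            )
        ratios = wald_ratio(Gamma, gamma)
        ses = wald_se_delta(Gamma, sy, gamma, sx, order=1)
        return ratios, ses, meta

    def _bootstrap_se(self, point_fn, ratios, ses, weights) -> float:
        rng = np.random.default_rng(self.random_state)
        B = int(self.n_bootstrap)
        samples = ratios[None, :] + ses[None, :] * rng.standard_normal((B, ratios.size))
        estimates = point_fn(samples, weights)
        return float(np.std(estimates, ddof=1))


class WeightedMedianEstimator(_RatioRobustBase):
    """Weighted median of per-SNP Wald ratios (Bowden-style).

    Consistent while valid instruments carry at least half the
    inverse-variance weight.  SE by parametric bootstrap (``n_bootstrap``
    resamples of each ratio from ``N(ratio_j, se_j^2)``, seeded).
    """

    method_label = "weighted_median"

    def __init__(self, n_bootstrap: int = 1000, random_state: int = 0):
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, X, y=None):
        ratios, ses, meta = self._ratios(X)
        w = 1.0 / ses**2
        theta = _weighted_median_core(ratios, w)
        se = self._bootstrap_se(_weighted_median_rows, ratios, ses, w)
        return _finalize(self, theta, se, meta, ratios.size, {"ratios": ratios, "ratio_ses": ses})


class WeightedModeEstimator(_RatioRobustBase):
    """Mode of the inverse-variance-weighted kernel density of Wald ratios.

    Normal kernel; bandwidth = ``bandwidth_factor`` times the modified
    Silverman rule ``0.9 min(sd, IQR/1.349) k^(-1/5)`` on the ratios.
    Density ties break to the smallest estimate.
    """

    method_label = "weighted_mode"

    def __init__(self, bandwidth_factor: float = 1.0, n_bootstrap: int = 1000, random_state: int = 0):
        self.bandwidth_factor = bandwidth_factor
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.bandwidth_factor <= 0:
            raise EstimationError("bandwidth_factor must be > 0")
        ratios, ses, meta = self._ratios(X)
        w = 1.0 / ses**2
        theta = _weighted_mode_core(ratios, w, self.bandwidth_factor)

        def rows(samples, weights):
            return np.array(
                [_weighted_mode_core(row, weights, self.bandwidth_factor) for row in samples]
            )

        se = self._bootstrap_se(rows, ratios, ses, w)
        return _finalize(self, theta, se, meta, ratios.size, {"ratios": ratios, "ratio_ses": ses})


def _estimate_from_pairs(per_snp_estimates, point_fn, method, n_bootstrap, random_state, **kw):
    thetas, ses = _per_snp_arrays(per_snp_estimates)
    if thetas.size < 3:
        raise EstimationError(f"{method} estimator needs >= 3 instruments (got {thetas.size})")
    w = 1.0 / ses**2
    theta = point_fn(thetas, w, **kw)
    rng = np.random.default_rng(random_state)
    samples = thetas[None, :] + ses[None, :] * rng.standard_normal((int(n_bootstrap), thetas.size))
    if point_fn is _weighted_median_core:
        boots = _weighted_median_rows(samples, w)
    else:
        boots = np.array([point_fn(row, w, **kw) for row in samples])
    se = float(np.std(boots, ddof=1))
    return MrEstimate(
        method=method, theta=float(theta), se=se,
        ci_low=float(theta) - Z_95 * se, ci_high=float(theta) + Z_95 * se,
        n_snps=thetas.size,
    )


def weighted_median(per_snp_estimates, n_bootstrap: int = 1000, random_state: int = 0) -> MrEstimate:
    """Weighted median over (ratio, se) pairs with a bootstrap SE."""
    return _estimate_from_pairs(
        per_snp_estimates, _weighted_median_core, "weighted_median", n_bootstrap, random_state
    )


def weighted_mode(
    per_snp_estimates, bandwidth_factor: float = 1.0, n_bootstrap: int = 1000, random_state: int = 0
) -> MrEstimate:
    """Weighted kernel-mode over (ratio, se) pairs with a bootstrap SE."""
    if bandwidth_factor <= 0:
        raise EstimationError("bandwidth_factor must be > 0")
    return _estimate_from_pairs(
        per_snp_estimates, _weighted_mode_core, "weighted_mode", n_bootstrap, random_state,
        phi=bandwidth_factor,
    )


def funnel_data(per_snp_estimates, snp_ids=None) -> pd.DataFrame:
    """Per-SNP estimate vs precision (1/se), the funnel plot's underlying data."""
    thetas, ses = _per_snp_arrays(per_snp_estimates)
    return pd.DataFrame(
        {
            "snp_id": list(snp_ids) if snp_ids is not None else list(range(thetas.size)),
            "theta": thetas,
            "precision": 1.0 / ses,
        }
    )


_SUBSET_METHODS = {
    "wald": lambda inst, seed: WaldRatioEstimator().fit(inst),
    "ivw": lambda inst, seed: IVWEstimator().fit(inst),
    "ml": lambda inst, seed: MaximumLikelihoodMR().fit(inst),
    "egger": lambda inst, seed: EggerRegression().fit(inst),
    "weighted_median": lambda inst, seed: WeightedMedianEstimator(random_state=seed).fit(inst),
    "weighted_mode": lambda inst, seed: WeightedModeEstimator(random_state=seed).fit(inst),
}


def subset_rerun(
    instruments: HarmonizedInstrumentSet,
    keep_ids,
    methods=("ivw", "egger", "weighted_median", "weighted_mode"),
    random_state: int = 0,
) -> pd.DataFrame:
    """Recompute the named estimators on a subset of instruments.

    Output schema matches full-set results for side-by-side comparison; a
    method that cannot run on the subset (e.g. k < 3) yields an error row
    rather than aborting the rerun.
    """
    sub = instruments.subset(list(keep_ids))
    rows = []
    for method in methods:
        if method not in _SUBSET_METHODS:
            raise MrKitError(f"unknown method {method!r}")
        row = {"method": method, "n_snps": len(sub)}
        try:
            est = _SUBSET_METHODS[method](sub, random_state)
            row.update(
                theta=est.theta_, se=est.se_, ci_low=est.ci_low_, ci_high=est.ci_high_, error=""
            )
        except MrKitError as exc:
            row.update(theta=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows, columns=["method", "n_snps", "theta", "se", "ci_low", "ci_high", "error"])
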