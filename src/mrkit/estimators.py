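"""Causal-effect estimators for two-sample Mendelian randomization.

Given harmonized per-SNP effects :math:`(\\hat\\gamma_j, \\sigma_{xj})` on the
exposure and :math:`(\\hat\\Gamma_j, \\sigma_{yj})` on the outcome, the causal
effect :math:`\\theta` of the exposure on the outcome is estimated by

* per-SNP Wald ratios :math:`\\hat\\theta_j = \\hat\\Gamma_j/\\hat\\gamma_j`
  with delta-method SEs,
* their fixed-effects inverse-variance-weighted (IVW) meta-analysis,
* a generalization of IVW that weights by the full outcome covariance
  :math:`\\Omega_{jk} = \\sigma_{yj}\\sigma_{yk}\\rho_{jk}` when instruments
  are correlated through LD, and
* joint maximum likelihood over :math:`(\\gamma_1..\\gamma_k, \\theta)`,
  which propagates the exposure-side uncertainty exactly.

Estimators follow the scikit-learn protocol: configure in ``__init__``,
``fit`` on a :class:`~mrkit.data.HarmonizedInstrumentSet` (or a DataFrame
with the same columns), read fitted attributes ``theta_``, ``se_``,
``ci_low_``, ``ci_high_``.  Module-level functions wrap the classes and
return :class:`~mrkit.data.MrEstimate` records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from sklearn.base import BaseEstimator

from .data import Z_95, HarmonizedInstrumentSet, LdMatrix, MrEstimate, OddsRatioResult
from .exceptions import ConvergenceError, EstimationError, ScaleError

__all__ = [
    "wald_ratio",
    "wald_se_delta",
    "WaldRatioEstimator",
    "IVWEstimator",
    "MaximumLikelihoodMR",
    "ivw_fixed",
    "ivw_correlated",
    "max_likelihood",
    "to_odds_ratio",
]


def wald_ratio(Gamma_hat, gamma_hat, snp_id: str | None = None):
    """Per-SNP causal estimate: outcome effect over exposure effect."""
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    if np.any(gamma_hat == 0):
        raise EstimationError(
            f"zero exposure effect for SNP {snp_id or 'unknown'}: Wald ratio undefined"
        )
    return np.asarray(Gamma_hat, dtype=float) / gamma_hat


def wald_se_delta(Gamma_hat, sigma_y, gamma_hat, sigma_x, order: int = 1):
    """Delta-method SE of the Wald ratio.

    First order: ``sqrt(sy^2/g^2 + G^2 sx^2/g^4)``; second order adds
    ``sx^2 sy^2 / g^4``.
    """
    if order not in (1, 2):
        raise EstimationError(f"delta-method order must be 1 or 2 (got {order})")
    g = np.asarray(gamma_hat, dtype=float)
    if np.any(g == 0):
        raise EstimationError("zero exposure effect: delta-method SE undefined")
    G = np.asarray(Gamma_hat, dtype=float)
    sx = np.asarray(sigma_x, dtype=float)
    sy = np.asarray(sigma_y, dtype=float)
    var = sy**2 / g**2 + G**2 * sx**2 / g**4
    if order == 2:
        var = var + sx**2 * sy**2 / g**4
    return np.sqrt(var)


def _extract(X):
    """Pull (gamma, sigma_x, Gamma, sigma_y, snp_ids, meta) out of the input."""
    if isinstance(X, HarmonizedInstrumentSet):
        df = X.table
        meta = dict(exposure=X.exposure, exposure_unit=X.exposure_unit, outcome_scale=X.outcome_scale)
    elif isinstance(X, pd.DataFrame):
        df = X
        meta = dict(exposure="exposure", exposure_unit="raw", outcome_scale="log-odds")
    else:
        raise TypeError(
            "X must be a HarmonizedInstrumentSet or a DataFrame with columns "
            "snp_id, gamma_hat, sigma_x, Gamma_hat, sigma_y"
        )
    for col in ("gamma_hat", "sigma_x", "Gamma_hat", "sigma_y"):
        if col not in df.columns:
            raise EstimationError(f"instrument table missing column {col!r}")
    gamma = df["gamma_hat"].to_numpy(dtype=float)
    sx = df["sigma_x"].to_numpy(dtype=float)
    Gamma = df["Gamma_hat"].to_numpy(dtype=float)
    sy = df["sigma_y"].to_numpy(dtype=float)
    if gamma.size == 0:
        raise EstimationError("no instruments supplied")
    if not np.all(np.isfinite(np.concatenate([gamma, sx, Gamma, sy]))):
        raise EstimationError("non-finite values in instrument table")
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise EstimationError("standard errors must be > 0")
    snp_ids = df["snp_id"].tolist() if "snp_id" in df.columns else list(map(str, range(gamma.size)))
    return gamma, sx, Gamma, sy, snp_ids, meta


def _aligned_rho(ld: LdMatrix | np.ndarray | None, snp_ids, k):
    if ld is None:
        return None
    if isinstance(ld, LdMatrix):
        if ld.snp_ids != list(snp_ids):
            raise EstimationError(
                "LD matrix SNP order does not match instruments; call align_ld_matrix first"
            )
        return ld.rho
    rho = np.asarray(ld, dtype=float)
    if rho.shape != (k, k):
        raise EstimationError(f"LD matrix shape {rho.shape} does not match k={k}")
    return rho


def _finalize(est, theta, se, meta, n_snps, extras):
    est.theta_ = float(theta)
    est.se_ = float(se)
    est.ci_low_ = est.theta_ - Z_95 * est.se_
    est.ci_high_ = est.theta_ + Z_95 * est.se_
    est.n_snps_ = int(n_snps)
    est.extras_ = extras
    est.meta_ = meta
    return est


class _MrEstimatorBase(BaseEstimator):
    """Shared result plumbing for MR estimators."""

    method_label = "mr"

    def to_result(self) -> MrEstimate:
        """Package fitted attributes as an :class:`MrEstimate`."""
        return MrEstimate(
            method=self.method_label,
            theta=self.theta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            n_snps=self.n_snps_,
            extras=self.extras_,
            exposure=self.meta_["exposure"],
            exposure_unit=self.meta_["exposure_unit"],
            outcome_scale=self.meta_["outcome_scale"],
        )


class WaldRatioEstimator(_MrEstimatorBase):
    """Single-instrument causal estimate (ratio of coefficients).

    Parameters
    ----------
    delta_order : {1, 2}
        Order of the delta-method SE.
    """

    method_label = "wald"

    def __init__(self, delta_order: int = 1):
        self.delta_order = delta_order

    def fit(self, X, y=None):
        gamma, sx, Gamma, sy, snp_ids, meta = _extract(X)
        if gamma.size != 1:
            raise EstimationError(
                f"Wald estimator requires exactly one instrument (got {gamma.size})"
            )
        theta = float(wald_ratio(Gamma[0], gamma[0], snp_ids[0]))
        se = float(wald_se_delta(Gamma[0], sy[0], gamma[0], sx[0], order=self.delta_order))
        return _finalize(self, theta, se, meta, 1, {"snp_id": snp_ids[0]})


class IVWEstimator(_MrEstimatorBase):
    """Fixed-effects inverse-variance-weighted meta-analysis of Wald ratios.

    With ``weighting='delta'`` per-SNP weights are ``1/se_j^2`` from the
    delta-method Wald SE; ``weighting='simple'`` uses the common
    exposure-error-ignoring simplification ``se_j = sigma_yj/|gamma_j|``
    (equivalently weighted least squares of Gamma on gamma through the
    origin with weights ``1/sigma_y^2``).

    When an aligned LD matrix is passed to ``fit`` the estimator becomes the
    correlated-instruments generalization
    ``theta = (g' Om^-1 G)/(g' Om^-1 g)``, ``se = (g' Om^-1 g)^-1/2`` with
    ``Om = diag(sy) rho diag(sy)``.  A one-shot diagonal ridge
    (``ridge_eps * trace/k``) is applied if ``Om`` is numerically singular.
    """

    method_label = "ivw"

    def __init__(
        self,
        weighting: str = "delta",
        delta_order: int = 1,
        ridge_tol: float = 1e-10,
        ridge_eps: float = 1e-8,
    ):
        self.weighting = weighting
        self.delta_order = delta_order
        self.ridge_tol = ridge_tol
        self.ridge_eps = ridge_eps

    def _per_snp(self, gamma, sx, Gamma, sy, snp_ids):
        ratios = wald_ratio(Gamma, gamma)
        if self.weighting == "delta":
            ses = wald_se_delta(Gamma, sy, gamma, sx, order=self.delta_order)
        elif self.weighting == "simple":
            ses = sy / np.abs(gamma)
        else:
            raise EstimationError(f"unknown IVW weighting {self.weighting!r}")
        return ratios, ses

    def fit(self, X, y=None, ld=None):
        gamma, sx, Gamma, sy, snp_ids, meta = _extract(X)
        k = gamma.size
        if ld is None:
            ratios, ses = self._per_snp(gamma, sx, Gamma, sy, snp_ids)
            w = 1.0 / ses**2
            theta = float(np.sum(w * ratios) / np.sum(w))
            se = float(np.sum(w) ** -0.5)
            extras = {"ratios": ratios, "ratio_ses": ses, "weights": w, "snp_ids": snp_ids}
            self.method_label = "ivw"
            return _finalize(self, theta, se, meta, k, extras)
        rho = _aligned_rho(ld, snp_ids, k)
        omega = np.outer(sy, sy) * rho
        eigvals = np.linalg.eigvalsh(omega)
        ridged = False
        if eigvals[0] < self.ridge_tol * eigvals[-1]:
            omega = omega + np.eye(k) * (self.ridge_eps * np.trace(omega) / k)
            eigvals = np.linalg.eigvalsh(omega)
            ridged = True
        if eigvals[0] <= 0:
            raise EstimationError(
                "outcome covariance not positive definite after regularization "
                f"(condition number {eigvals[-1] / max(eigvals[0], 1e-300):.3g})"
            )
        cho = linalg.cho_factor(omega)
        oinv_g = linalg.cho_solve(cho, gamma)
        denom = float(gamma @ oinv_g)
        theta = float(oinv_g @ Gamma) / denom
        se = denom**-0.5
        extras = {
            "snp_ids": snp_ids,
            "ridged": ridged,
            "omega_condition": float(eigvals[-1] / eigvals[0]),
        }
        self.method_label = "ivw_correlated"
        return _finalize(self, theta, se, meta, k, extras)


class MaximumLikelihoodMR(_MrEstimatorBase):
    """Joint maximum-likelihood estimate of the causal effect.

    Models ``gamma_hat_j ~ N(gamma_j, sigma_xj^2)`` and
    ``Gamma_hat ~ N(theta*gamma, Omega)`` (``Omega`` diagonal without LD),
    maximizing over the k true exposure effects and ``theta`` by
    quasi-Newton started at ``gamma = gamma_hat``, ``theta = IVW``.  The SE
    comes from the observed information (inverse Hessian) at the optimum, so
    exposure-side uncertainty is propagated exactly.
    """

    method_label = "ml"

    def __init__(self, gtol: float = 1e-8, max_iter: int = 1000):
        self.gtol = gtol
        self.max_iter = max_iter

    def fit(self, X, y=None, ld=None):
        gamma_hat, sx, Gamma_hat, sy, snp_ids, meta = _extract(X)
        k = gamma_hat.size
        rho = _aligned_rho(ld, snp_ids, k)
        omega = np.diag(sy**2) if rho is None else np.outer(sy, sy) * rho
        eigvals = np.linalg.eigvalsh(omega)
        if eigvals[0] < 1e-10 * eigvals[-1]:
            omega = omega + np.eye(k) * (1e-8 * np.trace(omega) / k)
        oinv = np.linalg.inv(omega)

        # parameterize the true exposure effects as gamma = gamma_hat + sx*a
        # with a in SE units: the problem stays well-conditioned for any sx,
        # and the theta entry of the inverse Hessian is invariant under this
        # linear reparameterization
        def unpack(x):
            return gamma_hat + sx * x[:k], x[k]

        def nll(x):
            g, th = unpack(x)
            ry = Gamma_hat - th * g
            return 0.5 * float(x[:k] @ x[:k] + ry @ oinv @ ry)

        def grad(x):
            g, th = unpack(x)
            oy = oinv @ (Gamma_hat - th * g)
            return np.concatenate([x[:k] - th * sx * oy, [-float(g @ oy)]])

        theta0 = IVWEstimator(weighting="delta").fit(
            pd.DataFrame(
                {"snp_id": snp_ids, "gamma_hat": gamma_hat, "sigma_x": sx,
                 "Gamma_hat": Gamma_hat, "sigma_y": sy}
            )
        ).theta_ if k > 1 else float(Gamma_hat[0] / gamma_hat[0])
        def hessian(x):
            g, th = unpack(x)
            h_aa = np.eye(k) + th**2 * (sx[:, None] * oinv * sx[None, :])
            h_at = sx * (oinv @ (2.0 * th * g - Gamma_hat))
            h_tt = float(g @ oinv @ g)
            return np.block([[h_aa, h_at[:, None]], [h_at[None, :], np.array([[h_tt]])]])

        x0 = np.concatenate([np.zeros(k), [theta0]])
        gnorm0 = float(np.max(np.abs(grad(x0))))
        res = optimize.minimize(
            nll, x0, jac=grad, method="BFGS",
            options={"gtol": self.gtol, "maxiter": self.max_iter},
        )
        x = res.x
        # Newton polish with the analytic Hessian: the likelihood is smooth
        # and near-quadratic, so this drives the gradient to machine scale
        # even when BFGS stops early on precision loss.
        n_newton = 0
        for _ in range(50):
            gvec = grad(x)
            if np.max(np.abs(gvec)) <= self.gtol:
                break
            try:
                step = np.linalg.solve(hessian(x), gvec)
            except np.linalg.LinAlgError:
                break
            if nll(x - step) >= nll(x) and np.max(np.abs(gvec)) < 1e3 * self.gtol:
                break
            x = x - step
            n_newton += 1
        gnorm = float(np.max(np.abs(grad(x))))
        if gnorm > max(self.gtol * max(1.0, gnorm0), 1e3 * self.gtol):
            raise ConvergenceError(
                f"likelihood optimizer did not converge (gradient norm {gnorm:.3g})",
                gradient_norm=gnorm,
            )
        g, theta = unpack(x)
        # observed information at the optimum
        cov = np.linalg.inv(hessian(x))
        se = float(np.sqrt(cov[-1, -1]))
        extras = {
            "converged": True,
            "gradient_norm": gnorm,
            "n_iter": int(res.nit) + n_newton,
            "gamma_mle": g,
            "correlated": rho is not None,
        }
        return _finalize(self, float(theta), se, meta, k, extras)


def ivw_fixed(instruments, weighting: str = "delta", delta_order: int = 1) -> MrEstimate:
    """Fixed-effects IVW meta-analysis of per-SNP Wald ratios."""
    return IVWEstimator(weighting=weighting, delta_order=delta_order).fit(instruments).to_result()


def ivw_correlated(instruments, ld, weighting: str = "delta") -> MrEstimate:
    """IVW generalized to LD-correlated instruments (aligned ``ld`` required)."""
    return IVWEstimator(weighting=weighting).fit(instruments, ld=ld).to_result()


def max_likelihood(instruments, ld=None, gtol: float = 1e-8) -> MrEstimate:
    """Likelihood-based causal estimate (optionally with outcome LD covariance)."""
    return MaximumLikelihoodMR(gtol=gtol).fit(instruments, ld=ld).to_result()


def to_odds_ratio(estimate: MrEstimate, scale: str = "unit") -> OddsRatioResult:
    """Express a log-odds causal estimate as an OR with 95% CI.

    ``scale='unit'`` exponentiates per exposure unit; ``scale='percent10'``
    rescales a per-log-unit effect to a 10% relative increase in the
    exposure, ``OR = exp(theta * ln 1.1) = 1.1^theta``.
    """
    if estimate.outcome_scale != "log-odds":
        raise ScaleError(
            f"odds ratios require a log-odds outcome (got {estimate.outcome_scale!r})"
        )
    if scale == "unit":
        factor = 1.0
        label = f"per unit ({estimate.exposure_unit})"
    elif scale == "percent10":
        if estimate.exposure_unit != "log":
            raise ScaleError(
                "percent10 scaling requires exposure effects per natural-log unit "
                f"(got unit {estimate.exposure_unit!r})"
            )
        factor = float(np.log(1.1))
        label = "per 10% relative increase"
    else:
        raise ScaleError(f"unknown OR scale {scale!r}")
    point = float(np.exp(estimate.theta * factor))
    low = float(np.exp((estimate.theta - Z_95 * estimate.se) * factor))
    high = float(np.exp((estimate.theta + Z_95 * estimate.se) * factor))
    return OddsRatioResult(point, min(low, high), max(low, high), label)
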