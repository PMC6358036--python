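"""Seeded Monte-Carlo calibration benchmarks for the estimators.

Each function fixes a simulation design (the "study conditions"), runs the
generator and an estimator across replicates, and returns summary numbers
with Monte-Carlo standard errors.  The designs:

``null_ivw_calibration``
    a 30-instrument urate-like arm (R^2 = 0.07, exposure GWAS n = 110,347,
    case-control outcome n = 54,162 with case fraction 0.314) at a true
    null, checking that the mean IVW OR is 1 and 95% CIs cover at ~95%;

``q_type1_rate``
    the same design, checking Cochran's Q rejects at its nominal level;

``egger_intercept_recovery``
    directional pleiotropy (mean 0.02, sd 0.005) under InSIDE with an
    essentially noise-free exposure stage (n_exp = 5e6, so I2_GX ~ 1):
    MR-Egger's intercept should recover the mean pleiotropy and its slope
    the causal effect, while plain IVW is biased by ~ mean(alpha)/mean(gamma);

``weighted_median_robustness``
    40% of 30 instruments invalid with large directional pleiotropy (about
    8 ratio-SEs) but under half the weight, from two large continuous-trait
    GWAS (n = 2e6 each) so instruments are precise enough for the weighted
    median's asymptotic validity condition to bite.
"""

from __future__ import annotations

import numpy as np

from .diagnostics import EggerRegression, _weighted_median_core, cochran_q
from .estimators import IVWEstimator, wald_ratio, wald_se_delta
from .simulate import OUTCOME_DESIGN, STUDY_ARMS, SimulationConfig, simulate_two_sample

__all__ = [
    "null_ivw_calibration",
    "q_type1_rate",
    "egger_intercept_recovery",
    "weighted_median_robustness",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


def _urate_like(seed: int, theta: float = 0.0, **overrides) -> SimulationConfig:
    base = dict(STUDY_ARMS["urate"], **OUTCOME_DESIGN)
    base.pop("exposure_unit")
    base.update(overrides)
    return SimulationConfig(theta=theta, exposure="urate-like", seed=seed, **base)


def null_ivw_calibration(n_reps: int = 500, seed: int = 0) -> dict:
    """Mean IVW OR and 95% CI coverage on the urate-like arm at theta = 0."""
    ors = np.empty(n_reps)
    covered = np.empty(n_reps, dtype=bool)
    for i, child in enumerate(_child_seeds(seed, n_reps)):
        study = simulate_two_sample(_urate_like(child))
        est = IVWEstimator().fit(study.to_instrument_set())
        ors[i] = np.exp(est.theta_)
        covered[i] = est.ci_low_ <= 0.0 <= est.ci_high_
    return {
        "mean_or": float(np.mean(ors)),
        "mc_se_or": float(np.std(ors, ddof=1) / np.sqrt(n_reps)),
        "coverage": float(np.mean(covered)),
        "n_reps": n_reps,
    }


def q_type1_rate(n_reps: int = 2000, seed: int = 0, alpha: float = 0.05) -> dict:
    """Cochran's Q rejection rate under homogeneity (no pleiotropy, theta = 0).

    Q is computed on the standard heterogeneity weights 1/(sigma_y/gamma)^2
    (the exposure-error term of the delta SE is correlated with the squared
    residual and would make Q conservative).
    """
    reject = np.empty(n_reps, dtype=bool)
    for i, child in enumerate(_child_seeds(seed, n_reps)):
        study = simulate_two_sample(_urate_like(child))
        inst = study.to_instrument_set()
        est = IVWEstimator(weighting="simple").fit(inst)
        pairs = list(zip(est.extras_["ratios"], est.extras_["ratio_ses"]))
        reject[i] = cochran_q(pairs, est.theta_).p < alpha
    rate = float(np.mean(reject))
    return {
        "type1_rate": rate,
        "mc_se": float(np.sqrt(rate * (1 - rate) / n_reps)),
        "alpha": alpha,
        "n_reps": n_reps,
    }


def egger_intercept_recovery(n_reps: int = 500, seed: int = 0, theta: float = 0.5) -> dict:
    """MR-Egger vs IVW under directional pleiotropy with InSIDE held."""
    pleiotropy_mean, pleiotropy_sd = 0.02, 0.005
    gamma_mean, gamma_sd = 0.075, 0.02
    intercepts = np.empty(n_reps)
    slopes = np.empty(n_reps)
    ivw_thetas = np.empty(n_reps)
    for i, child in enumerate(_child_seeds(seed, n_reps)):
        config = SimulationConfig(
            k=30, theta=theta, gamma_mean=gamma_mean, gamma_sd=gamma_sd,
            n_exp=5_000_000, maf_range=(0.1, 0.5),
            pleiotropy="directional", pleiotropy_mean=pleiotropy_mean,
            pleiotropy_sd=pleiotropy_sd, inside_violated=False,
            seed=child, **OUTCOME_DESIGN,
        )
        inst = simulate_two_sample(config).to_instrument_set()
        eg = EggerRegression().fit(inst)
        intercepts[i] = eg.intercept_
        slopes[i] = eg.theta_
        ivw_thetas[i] = IVWEstimator().fit(inst).theta_
    return {
        "theta": theta,
        "true_mean_pleiotropy": pleiotropy_mean,
        "mean_intercept": float(np.mean(intercepts)),
        "mc_se_intercept": float(np.std(intercepts, ddof=1) / np.sqrt(n_reps)),
        "mean_slope": float(np.mean(slopes)),
        "mc_se_slope": float(np.std(slopes, ddof=1) / np.sqrt(n_reps)),
        "mean_ivw_theta": float(np.mean(ivw_thetas)),
        "mc_se_ivw": float(np.std(ivw_thetas, ddof=1) / np.sqrt(n_reps)),
        "expected_ivw_bias": pleiotropy_mean / gamma_mean,
        "n_reps": n_reps,
    }


def weighted_median_robustness(n_reps: int = 500, seed: int = 0, theta: float = 0.5) -> dict:
    """Weighted-median bias with 40% invalid instruments under half the weight."""
    estimates = np.empty(n_reps)
    invalid_weight = np.empty(n_reps)
    for i, child in enumerate(_child_seeds(seed, n_reps)):
        config = SimulationConfig(
            k=30, theta=theta, gamma_mean=0.12, gamma_sd=0.02,
            n_exp=2_000_000, n_out=2_000_000, maf_range=(0.1, 0.4),
            case_fraction=None,
            pleiotropy="directional", pleiotropy_mean=0.01, pleiotropy_sd=0.002,
            pleiotropy_fraction=0.4, inside_violated=False, seed=child,
        )
        study = simulate_two_sample(config)
        inst = study.to_instrument_set()
        ratios = wald_ratio(inst.Gamma_hat, inst.gamma_hat)
        ses = wald_se_delta(inst.Gamma_hat, inst.sigma_y, inst.gamma_hat, inst.sigma_x)
        w = 1.0 / ses**2
        estimates[i] = _weighted_median_core(ratios, w)
        invalid_weight[i] = np.sum(w[study.truth["pleiotropic"]]) / np.sum(w)
    return {
        "theta": theta,
        "bias": float(np.mean(estimates) - theta),
        "mc_se": float(np.std(estimates, ddof=1) / np.sqrt(n_reps)),
        "mean_invalid_weight": float(np.mean(invalid_weight)),
        "n_reps": n_reps,
    }
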