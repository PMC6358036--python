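"""Wald ratio, IVW (plain and LD-correlated), maximum likelihood, OR scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_instruments
from mrkit.data import LdMatrix
from mrkit.estimators import (
    IVWEstimator,
    MaximumLikelihoodMR,
    WaldRatioEstimator,
    ivw_correlated,
    ivw_fixed,
    max_likelihood,
    to_odds_ratio,
    wald_ratio,
    wald_se_delta,
)
from mrkit.exceptions import EstimationError, ScaleError
from mrkit.simulate import SimulationConfig, simulate_two_sample


class TestWaldRatio:
    @pytest.mark.parametrize(
        "Gamma, gamma, expected", [(0.02, 0.04, 0.5), (0.0, 0.04, 0.0), (-0.03, 0.06, -0.5)]
    )
    def test_ratio(self, Gamma, gamma, expected):
        assert wald_ratio(Gamma, gamma) == pytest.approx(expected)

    def test_zero_exposure_effect_names_snp(self):
        with pytest.raises(EstimationError, match="rs77"):
            wald_ratio(0.02, 0.0, snp_id="rs77")

    def test_first_order_delta_se(self):
        se = wald_se_delta(0.02, 0.01, 0.04, 0.005, order=1)
        assert se == pytest.approx(np.sqrt(0.0625 + 0.00390625), rel=1e-12)
        assert se == pytest.approx(0.2577, abs=5e-5)

    def test_exact_instrument_limit(self):
        assert wald_se_delta(0.02, 0.01, 0.04, 0.0) == pytest.approx(0.25, rel=1e-12)

    def test_second_order_adds_product_term(self):
        first = wald_se_delta(0.02, 0.01, 0.04, 0.005, order=1)
        second = wald_se_delta(0.02, 0.01, 0.04, 0.005, order=2)
        extra = 0.005**2 * 0.01**2 / 0.04**4
        assert second**2 - first**2 == pytest.approx(extra, rel=1e-10)


class TestIVW:
    def test_single_instrument_reduces_to_wald(self):
        inst = make_instruments([0.04], [0.005], [0.02], [0.01])
        est = IVWEstimator().fit(inst)
        wald = WaldRatioEstimator().fit(inst)
        assert est.theta_ == pytest.approx(wald.theta_)
        assert est.se_ == pytest.approx(wald.se_)

    def test_two_instrument_worked_example(self, toy_instruments):
        est = ivw_fixed(toy_instruments)
        assert est.theta == pytest.approx(0.34, abs=1e-9)
        assert est.se == pytest.approx(0.08944, abs=1e-5)
        assert est.ci_low == pytest.approx(0.34 - 1.96 * est.se)

    def test_replicated_instruments_shrink_se(self):
        k = 4
        inst = make_instruments([0.1] * k, [1e-12] * k, [0.05] * k, [0.02] * k)
        est = IVWEstimator().fit(inst)
        assert est.theta_ == pytest.approx(0.5)
        single = make_instruments([0.1], [1e-12], [0.05], [0.02])
        assert est.se_ == pytest.approx(IVWEstimator().fit(single).se_ / np.sqrt(k))

    def test_matches_wls_through_origin(self, urate_like_study):
        """With sigma_y-only weights, IVW equals WLS of Gamma on gamma through 0."""
        import statsmodels.api as sm

        inst = urate_like_study.to_instrument_set()
        est = IVWEstimator(weighting="simple").fit(inst)
        wls = sm.WLS(inst.Gamma_hat, inst.gamma_hat, weights=1.0 / inst.sigma_y**2).fit()
        assert est.theta_ == pytest.approx(wls.params[0], rel=1e-10)

    def test_zero_instruments_error(self):
        import pandas as pd

        with pytest.raises(EstimationError):
            IVWEstimator().fit(
                pd.DataFrame(columns=["snp_id", "gamma_hat", "sigma_x", "Gamma_hat", "sigma_y"])
            )


class TestCorrelatedIVW:
    def test_identity_matches_uncorrelated(self, instruments):
        ld = LdMatrix(instruments.snp_ids, np.eye(len(instruments)))
        plain = IVWEstimator(weighting="simple").fit(instruments)
        corr = IVWEstimator().fit(instruments, ld=ld)
        assert corr.theta_ == pytest.approx(plain.theta_, rel=1e-10)
        assert corr.se_ == pytest.approx(plain.se_, rel=1e-10)

    def test_duplicated_snp_adds_no_information(self):
        rho = np.array([[1.0, 1.0 - 1e-6], [1.0 - 1e-6, 1.0]])
        inst = make_instruments([0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.02, 0.02])
        ld = LdMatrix(["rs0", "rs1"], rho)
        est = IVWEstimator().fit(inst, ld=ld)
        assert est.theta_ == pytest.approx(0.5, rel=1e-6)
        single = make_instruments([0.1], [0.01], [0.05], [0.02])
        assert est.se_ == pytest.approx(IVWEstimator(weighting="simple").fit(single).se_, rel=1e-3)

    def test_positive_correlation_inflates_se(self):
        k = 4
        rho = np.full((k, k), 0.3)
        np.fill_diagonal(rho, 1.0)
        inst = make_instruments([0.1] * k, [0.01] * k, [0.05, 0.04, 0.06, 0.05], [0.02] * k)
        ld = LdMatrix([f"rs{i}" for i in range(k)], rho)
        corr = IVWEstimator().fit(inst, ld=ld)
        ident = IVWEstimator().fit(inst, ld=LdMatrix([f"rs{i}" for i in range(k)], np.eye(k)))
        assert corr.se_ > ident.se_

    def test_misordered_ld_rejected(self, instruments):
        ld = LdMatrix(instruments.snp_ids[::-1], np.eye(len(instruments)))
        with pytest.raises(EstimationError, match="align"):
            IVWEstimator().fit(instruments, ld=ld)


class TestMaximumLikelihood:
    def test_single_instrument_equals_wald(self):
        inst = make_instruments([0.04], [0.005], [0.02], [0.01])
        est = MaximumLikelihoodMR().fit(inst)
        assert est.theta_ == pytest.approx(0.5, abs=1e-10)

    def test_negligible_exposure_error_matches_ivw(self, urate_like_study):
        inst = urate_like_study.to_instrument_set()
        inst.table["sigma_x"] = 1e-8 * np.abs(inst.table["gamma_hat"])
        ml = MaximumLikelihoodMR().fit(inst)
        ivw = ivw_fixed(inst)
        assert ml.theta_ == pytest.approx(ivw.theta, rel=1e-4)

    def test_parameter_recovery_at_theta_half(self):
        """ML is unbiased for the causal effect across seeded replicates."""
        n_reps = 200
        thetas = np.empty(n_reps)
        seeds = np.random.SeedSequence(314).generate_state(n_reps)
        for i, s in enumerate(seeds):
            study = simulate_two_sample(SimulationConfig(theta=0.5, seed=int(s) & 0x7FFFFFFF))
            thetas[i] = MaximumLikelihoodMR().fit(study.to_instrument_set()).theta_
        mc_se = thetas.std(ddof=1) / np.sqrt(n_reps)
        assert abs(thetas.mean() - 0.5) < 3 * mc_se

    def test_correlated_outcome_covariance_accepted(self):
        study = simulate_two_sample(SimulationConfig(k=4, ld_block=(4, 0.3), seed=9))
        inst = study.to_instrument_set()
        est = MaximumLikelihoodMR().fit(inst, ld=study.ld)
        assert est.extras_["correlated"] and np.isfinite(est.se_)

    def test_reports_convergence_metadata(self, instruments):
        est = MaximumLikelihoodMR().fit(instruments)
        assert est.extras_["converged"]
        assert est.extras_["gradient_norm"] < 1e-6


class TestInvariances:
    @given(c=st.floats(0.1, 10.0, allow_nan=False))
    @settings(max_examples=20, deadline=None)
    def test_exposure_rescaling_equivariance(self, c, ):
        """Multiplying exposure betas/SEs by c divides theta by c, z unchanged."""
        rng = np.random.default_rng(7)
        k = 10
        gamma = rng.uniform(0.05, 0.2, k)
        inst = make_instruments(gamma, 0.05 * gamma, 0.5 * gamma + rng.normal(0, 0.01, k),
                                np.full(k, 0.01))
        scaled = make_instruments(
            c * inst.gamma_hat, c * inst.sigma_x, inst.Gamma_hat, inst.sigma_y
        )
        for make in (lambda x: IVWEstimator().fit(x), lambda x: MaximumLikelihoodMR().fit(x)):
            base, alt = make(inst), make(scaled)
            assert alt.theta_ == pytest.approx(base.theta_ / c, rel=1e-6)
            assert alt.theta_ / alt.se_ == pytest.approx(base.theta_ / base.se_, rel=1e-6)

    def test_orientation_invariance(self, urate_like_study):
        """Flipping any SNP's orientation allele leaves estimates unchanged."""
        study = simulate_two_sample(SimulationConfig(k=6, ld_block=(3, 0.25), seed=13))
        inst = study.to_instrument_set()
        flipped = inst.flip_snp(inst.snp_ids[2]).flip_snp(inst.snp_ids[4])
        # align the simulated LD matrix through the sign-flip rule
        from mrkit.io import align_ld_matrix

        ld0 = align_ld_matrix(study.ld, inst)
        ld1 = align_ld_matrix(study.ld, flipped)
        for fit0, fit1 in [
            (IVWEstimator().fit(inst), IVWEstimator().fit(flipped)),
            (IVWEstimator().fit(inst, ld=ld0), IVWEstimator().fit(flipped, ld=ld1)),
            (MaximumLikelihoodMR().fit(inst, ld=ld0), MaximumLikelihoodMR().fit(flipped, ld=ld1)),
        ]:
            assert fit1.theta_ == pytest.approx(fit0.theta_, rel=1e-9)
            assert fit1.se_ == pytest.approx(fit0.se_, rel=1e-9)


class TestOddsRatio:
    def test_null_effect_gives_unit_or(self):
        est = ivw_fixed(make_instruments([0.1], [1e-12], [0.0], [0.02]))
        assert to_odds_ratio(est, "unit").or_point == pytest.approx(1.0)

    def test_percent10_definition(self):
        est = ivw_fixed(
            make_instruments([0.1], [1e-12], [0.1], [0.02], exposure_unit="log")
        )
        assert est.theta == pytest.approx(1.0)
        assert to_odds_ratio(est, "percent10").or_point == pytest.approx(1.10)

    def test_unit_scale_shape(self):
        est = ivw_fixed(make_instruments([1.0], [1e-12], [0.0296], [0.0347]))
        orr = to_odds_ratio(est, "unit")
        assert orr.or_point == pytest.approx(1.030, abs=5e-4)
        assert orr.or_low == pytest.approx(np.exp(0.0296 - 1.96 * est.se), rel=1e-6)
        assert orr.or_high == pytest.approx(np.exp(0.0296 + 1.96 * est.se), rel=1e-6)

    def test_percent10_requires_log_units(self):
        est = ivw_fixed(make_instruments([0.1], [1e-12], [0.05], [0.02], exposure_unit="raw"))
        with pytest.raises(ScaleError):
            to_odds_ratio(est, "percent10")

    def test_requires_log_odds_outcome(self):
        est = ivw_fixed(make_instruments([0.1], [1e-12], [0.05], [0.02], outcome_scale="unit"))
        with pytest.raises(ScaleError):
            to_odds_ratio(est, "unit")
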