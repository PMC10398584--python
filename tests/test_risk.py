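"""Risk engine: REACH form, horizon conversion, rate-ratio sampling, RRR/ARR."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidsim import (
    RateRatioModel,
    ReachParameters,
    convert_horizon,
    default_reach_parameters,
    reach_20month_risk,
    relative_risk_reduction,
    risk_outcomes,
    sample_rate_ratio,
)
from lipidsim.errors import ConfigurationError, DomainError, MissingCovariateError
from lipidsim.risk import REACH_COVARIATES


def _covariates(**overrides):
    covs = dict(age=68.0, female=0, current_smoker=0, former_smoker=1,
                diabetes=1, bmi=28.0, n_vascular_beds=1, event_past_year=0,
                chf=0, af=0, statin=1, aspirin=1, region_high_risk=0)
    covs.update(overrides)
    return covs


class TestReach:
    def test_null_coefficients_give_baseline_only(self):
        params = ReachParameters(
            coefficients={k: 0.0 for k in REACH_COVARIATES},
            baseline_survival=0.95, lp_offset=0.0)
        got = reach_20month_risk(_covariates(), params)
        assert got == pytest.approx(1.0 - 0.95, abs=1e-14)

    def test_brute_force_linear_predictor(self):
        """Independent evaluation of the configured formula."""
        params = default_reach_parameters()
        covs = _covariates()
        lp = sum(params.coefficients[k] * covs[k] for k in REACH_COVARIATES)
        expected = 1.0 - params.baseline_survival ** np.exp(lp - params.lp_offset)
        assert reach_20month_risk(covs, params) == pytest.approx(expected, abs=1e-10)

    def test_additional_vascular_bed_never_decreases_risk(self):
        params = default_reach_parameters()
        risks = [reach_20month_risk(_covariates(n_vascular_beds=b), params)
                 for b in (1, 2, 3)]
        assert risks == sorted(risks)

    def test_adverse_binary_covariates_increase_risk(self):
        params = default_reach_parameters()
        base = reach_20month_risk(_covariates(), params)
        for cov in ("diabetes", "chf", "af", "event_past_year", "current_smoker"):
            worse = reach_20month_risk(_covariates(**{cov: 1}), params)
            assert worse >= base or _covariates()[cov] == 1

    def test_missing_covariate_named(self):
        covs = _covariates()
        covs["bmi"] = None
        with pytest.raises(MissingCovariateError, match="bmi"):
            reach_20month_risk(covs)

    def test_incomplete_coefficient_config_rejected(self):
        with pytest.raises(ConfigurationError, match="missing"):
            ReachParameters(coefficients={"age": 0.03})


class TestConvertHorizon:
    def test_examples(self):
        assert convert_horizon(0.0) == 0.0
        assert convert_horizon(0.1, 20, 120) == pytest.approx(1 - 0.9**6, abs=1e-12)
        assert convert_horizon(0.1, 20, 120) == pytest.approx(0.468559, abs=1e-6)
        assert convert_horizon(0.37, 20, 20) == pytest.approx(0.37, abs=1e-15)
        assert convert_horizon(1.0) == 1.0

    @settings(deadline=None, max_examples=300)
    @given(r=st.floats(0.0, 0.999999), h=st.floats(1.0, 240.0),
           s=st.floats(1.0, 240.0))
    def test_closed_form_property(self, r, h, s):
        assert convert_horizon(r, s, h) == pytest.approx(
            1.0 - (1.0 - r) ** (h / s), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            convert_horizon(1.5)
        with pytest.raises(DomainError):
            convert_horizon(0.5, -1, 120)


class TestRateRatio:
    def test_degenerate_ci_gives_constant_draws(self):
        model = RateRatioModel(0.78, 0.78, 0.78)
        rng = np.random.default_rng(0)
        draws = sample_rate_ratio(model, rng, size=1000)
        assert np.allclose(draws, 0.78)

    def test_quantiles_match_model(self):
        model = RateRatioModel()
        rng = np.random.default_rng(1)
        draws = sample_rate_ratio(model, rng, size=200_000)
        assert np.all(draws > 0)
        q = np.quantile(draws, [0.025, 0.5, 0.975])
        assert q[1] == pytest.approx(model.rr_per_mmol, abs=0.002)
        assert q[0] == pytest.approx(model.ci_lower, abs=0.002)
        assert q[2] == pytest.approx(model.ci_upper, abs=0.002)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ConfigurationError):
            RateRatioModel(0.78, 0.80, 0.76)


class TestRrrAndOutcomes:
    def test_examples(self):
        assert relative_risk_reduction(0.78, 0.0) == 0.0
        assert relative_risk_reduction(1.0, 3.0) == 0.0
        assert relative_risk_reduction(0.78, 2.0) == pytest.approx(0.3916, abs=1e-12)

    def test_monotone_in_delta(self):
        deltas = np.linspace(0, 4, 50)
        rrr = relative_risk_reduction(0.78, deltas)
        assert np.all(np.diff(rrr) > 0)

    def test_negative_delta_rejected(self):
        with pytest.raises(DomainError):
            relative_risk_reduction(0.78, -0.5)

    def test_outcomes_example(self):
        # baseline 36%, RRR 24% -> residual 27.36%, ARR 8.64%
        est = risk_outcomes(0.36, 0.76, 1.0)  # rr^1 = 0.76 -> RRR 0.24
        assert est.rrr == pytest.approx(0.24, abs=1e-12)
        assert est.residual_risk == pytest.approx(0.2736, abs=1e-12)
        assert est.arr == pytest.approx(0.0864, abs=1e-12)

    def test_zero_baseline(self):
        est = risk_outcomes(0.0, 0.78, 2.0)
        assert est.residual_risk == 0.0 and est.arr == 0.0

    def test_full_rrr_limit(self):
        est = risk_outcomes(0.4, 1e-300, 1.0)
        assert est.residual_risk == pytest.approx(0.0, abs=1e-12)
        assert est.arr == pytest.approx(0.4, abs=1e-12)

    def test_negative_delta_floored(self):
        est = risk_outcomes(0.3, 0.78, -0.2)
        assert est.delta_ldl == 0.0 and est.rrr == 0.0

    @settings(deadline=None, max_examples=200)
    @given(baseline=st.floats(0.0, 1.0), rr=st.floats(0.01, 1.0),
           delta=st.floats(0.0, 5.0))
    def test_conservation_residual_plus_arr(self, baseline, rr, delta):
        est = risk_outcomes(baseline, rr, delta)
        assert est.residual_risk + est.arr == pytest.approx(baseline, abs=1e-15)
        assert 0.0 <= est.residual_risk <= baseline <= 1.0
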