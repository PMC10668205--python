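"""Parameter registry, rate conversion, and distribution fitting."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from htncea.parameters import (
    DistributionSpec,
    ParameterSet,
    fit_beta_from_interval,
    fit_gamma_from_mean_cv,
    fit_lognormal_from_ci,
    load_parameters,
    rate_to_prob,
    set_input,
)


class TestRateToProb:
    @pytest.mark.parametrize(
        "rate, rr, cycle, expected",
        [
            (0.0, 1.0, 1.0, 0.0),
            (2.9, 1.0, 1.0, -math.expm1(-0.0029)),
            (2.9, 0.85, 1.0, -math.expm1(-0.0029 * 0.85)),
            (55.1, 1.0, 1.0, -math.expm1(-0.0551)),
        ],
    )
    def test_exponential_form(self, rate, rr, cycle, expected):
        assert rate_to_prob(rate, rr, cycle) == pytest.approx(expected, abs=1e-12)

    def test_printed_magnitudes_stay_small(self, base_params):
        # the largest published input (recurrent stroke, stage 2) gives < 6%/cycle
        from htncea.parameters import RATE_EVENTS

        for stage in ("stage1", "stage2"):
            for event in RATE_EVENTS:
                rate = base_params.rates[stage][event].mean
                assert rate_to_prob(rate) < 0.06

    @pytest.mark.parametrize("rate, rr, cycle", [(-1, 1, 1), (1, 0, 1), (1, -2, 1), (1, 1, 0)])
    def test_domain_errors(self, rate, rr, cycle):
        with pytest.raises(ValueError):
            rate_to_prob(rate, rr, cycle)

    @given(
        rate=st.floats(0.01, 100),
        rr=st.floats(0.1, 2.0),
        t1=st.floats(0.1, 5.0),
        t2=st.floats(0.1, 5.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_and_composable(self, rate, rr, t1, t2):
        p = rate_to_prob(rate, rr, t1)
        assert 0 < p < 1
        assert rate_to_prob(rate * 1.1, rr, t1) > p
        assert rate_to_prob(rate, rr * 1.1, t1) > p
        assert rate_to_prob(rate, rr, t1 * 1.1) > p
        # survival composes exactly under the constant-hazard form
        combined = rate_to_prob(rate, rr, t1 + t2)
        split = 1 - (1 - p) * (1 - rate_to_prob(rate, rr, t2))
        assert combined == pytest.approx(split, rel=1e-12)


class TestGammaFit:
    @pytest.mark.parametrize(
        "mean, cv, shape, scale",
        [
            (88.92, 0.25, 16.0, 5.5575),
            (1.0, 0.25, 16.0, 0.0625),
            (3249.55, 0.25, 16.0, 203.096875),
        ],
    )
    def test_method_of_moments(self, mean, cv, shape, scale):
        spec = fit_gamma_from_mean_cv(mean, cv)
        assert spec.family == "gamma"
        assert spec.a == pytest.approx(shape, rel=1e-12)
        assert spec.b == pytest.approx(scale, rel=1e-12)
        # mean and CV are exact in closed form
        assert spec.mean() == pytest.approx(mean, rel=1e-12)
        sd = math.sqrt(spec.a) * spec.b
        assert sd / spec.mean() == pytest.approx(cv, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fit_gamma_from_mean_cv(-5.0)


class TestBetaFit:
    def test_symmetric_interval_gives_equal_shapes(self):
        sigma = 0.05
        spec = fit_beta_from_interval(0.5, 0.5 - 1.96 * sigma, 0.5 + 1.96 * sigma)
        assert spec.a == pytest.approx(spec.b, rel=1e-6)

    @pytest.mark.parametrize(
        "mean, lo, hi",
        [
            (0.90, 0.79, 0.95),       # hypertension utility
            (0.2408, 0.2172, 0.2552), # annual progression frequency
            (0.0029, 0.0026, 0.0032), # stage-1 stroke rate on proportion scale
        ],
    )
    def test_mean_exact_and_quantiles_match(self, mean, lo, hi):
        spec = fit_beta_from_interval(mean, lo, hi)
        assert spec.mean() == pytest.approx(mean, abs=1e-9)
        # independent check by evaluating the fitted CDF at the target bounds
        q_lo, q_hi = stats.beta.ppf([0.025, 0.975], spec.a, spec.b)
        assert abs(q_lo - lo) <= max(0.1 * lo, 0.005)
        assert abs(q_hi - hi) <= max(0.1 * hi, 0.005)

    def test_degenerate_interval_collapses_to_point(self):
        spec = fit_beta_from_interval(0.4, 0.4, 0.4)
        assert spec.family == "point"
        rng = np.random.default_rng(0)
        assert spec.sample(rng) == 0.4

    def test_mean_outside_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_from_interval(0.9, 0.1, 0.5)


class TestLognormalFit:
    def test_median_and_interval(self):
        spec = fit_lognormal_from_ci(0.85, 0.68, 1.06)
        assert math.exp(spec.a) == pytest.approx(0.85)
        q = stats.lognorm.ppf([0.025, 0.975], spec.b, scale=math.exp(spec.a))
        # the fitted interval has the printed width, centred on the median
        assert q[1] / q[0] == pytest.approx(1.06 / 0.68, rel=1e-9)


@pytest.mark.parametrize(
    "spec",
    [
        fit_beta_from_interval(0.90, 0.79, 0.95),
        fit_gamma_from_mean_cv(275.38, 0.25),
        fit_lognormal_from_ci(0.61, 0.53, 0.70),
    ],
    ids=["beta", "gamma", "lognormal"],
)
def test_sampling_round_trip(spec):
    """10^6 draws recover the analytic mean within 3 Monte-Carlo SEs."""
    rng = np.random.default_rng(42)
    x = spec.sample(rng, 1_000_000)
    se = x.std(ddof=1) / math.sqrt(x.size)
    assert abs(x.mean() - spec.mean()) < 3 * se


class TestLoadParameters:
    def test_shipped_defaults_match_published_inputs(self, base_params):
        assert base_params.rates["stage1"].stroke.mean == 2.9
        assert base_params.rates["stage1"].stroke.ci_low == 2.6
        assert base_params.rates["stage2"].recurrent_stroke.mean == 55.1
        assert base_params.relative_risks["stage1"].progression.mean == 0.61
        assert base_params.costs["drug"].mean == 88.92
        assert base_params.costs["stroke_first_year"].mean == 3249.55
        assert base_params.utilities["post_mi"].mean == 0.88
        assert base_params.discount_rate.mean == 0.05
        assert base_params.wtp_per_gdp == 10438.66
        assert base_params.productivity_window_years == 10

    def test_repo_fixture_matches_packaged_file(self, base_params):
        from pathlib import Path

        repo_fixture = Path(__file__).resolve().parents[1] / "params" / "table1_base_case.json"
        assert load_parameters(repo_fixture) == base_params

    def test_missing_key_is_named(self, base_params, tmp_path):
        raw = base_params.model_dump()
        del raw["discount_rate"]
        path = tmp_path / "p.json"
        path.write_text(json.dumps(raw))
        with pytest.raises(Exception, match="discount_rate"):
            load_parameters(path)

    def test_inverted_ci_rejected(self, base_params, tmp_path):
        raw = base_params.model_dump()
        raw["rates"]["stage1"]["stroke"]["ci_low"] = 5.0  # above the mean 2.9
        path = tmp_path / "p.json"
        path.write_text(json.dumps(raw))
        with pytest.raises(Exception, match="ci_low"):
            load_parameters(path)

    def test_malformed_file_reports_location(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text("{broken")
        with pytest.raises(json.JSONDecodeError):
            load_parameters(path)

    def test_yaml_round_trip(self, base_params, tmp_path):
        import yaml

        path = tmp_path / "p.yaml"
        path.write_text(yaml.safe_dump(base_params.model_dump()))
        assert load_parameters(path) == base_params


class TestSetInput:
    @pytest.mark.parametrize(
        "name, value",
        [
            ("rate.stage1.stroke", 3.5),
            ("rr.stage1.progression", 0.5),
            ("progression", 0.2),
            ("cost.productivity", 300.0),
            ("utility.post_stroke", 0.7),
            ("discount_rate", 0.0),
        ],
    )
    def test_named_paths(self, base_inputs, name, value):
        out = set_input(base_inputs, name, value)
        # base untouched, copy updated
        assert out is not base_inputs
        if name == "rate.stage1.stroke":
            assert out.rates[("stage1", "stroke")] == value
            assert base_inputs.rates[("stage1", "stroke")] == 2.9

    def test_unknown_name(self, base_inputs):
        with pytest.raises(KeyError):
            set_input(base_inputs, "cost.unknown_thing", 1.0)
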