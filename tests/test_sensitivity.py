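"""Tornado, probabilistic sensitivity analysis, CEAC, and scenario runs."""

import math

import numpy as np
import pytest

from htncea.engine import Arm, RunConfig, solve_cohort
from htncea.sensitivity import (
    PSAResult,
    build_psa_samplers,
    ceac,
    default_tornado_parameters,
    default_wtp_grid,
    one_way_tornado,
    psa_t_tests,
    run_psa,
    run_scenarios,
)
from htncea.sensitivity import _apply_draw


@pytest.fixture(scope="module")
def small_psa(base_params):
    return run_psa(base_params, RunConfig(horizon_years=15), n_draws=400, seed=5)


class TestTornado:
    def test_degenerate_range_has_zero_width(self, base_params, base_inputs, cfg8):
        p = base_inputs.progression_prob
        entries = one_way_tornado(base_params, [("progression", p, p)], cfg8)
        assert len(entries) == 1
        assert entries[0].range_width == 0.0

    def test_discount_rate_varied_at_printed_bounds(self, base_params, cfg8):
        entries = one_way_tornado(base_params, [("discount_rate", 0.0, 0.08)], cfg8)
        e = entries[0]
        assert e.low_input == 0.0 and e.high_input == 0.08
        assert np.isfinite(e.outcome_low) and np.isfinite(e.outcome_high)
        assert e.range_width > 0

    def test_ordering_invariant_to_listing_order(self, base_params, cfg8):
        varied = default_tornado_parameters(base_params)[:8]
        a = one_way_tornado(base_params, varied, cfg8)
        b = one_way_tornado(base_params, varied[::-1], cfg8)
        assert [e.parameter for e in a] == [e.parameter for e in b]
        # sorted by descending swing
        widths = [e.range_width for e in a]
        assert widths == sorted(widths, reverse=True)

    def test_unknown_parameter_name(self, base_params, cfg8):
        with pytest.raises(KeyError):
            one_way_tornado(base_params, [("cost.nonexistent", 0.0, 1.0)], cfg8)


class TestPSA:
    def test_base_values_through_draw_plumbing(self, base_params, cfg15):
        """Applying a draw equal to the base-case values reproduces the
        base-case results exactly (point-mass limit of the PSA)."""
        base = base_params.to_inputs()
        samplers = build_psa_samplers(base_params)
        names = [n for n, _ in samplers]
        values = []
        for name, _ in samplers:
            parts = name.split(".")
            if parts[0] == "rate":
                values.append(base.rates[(parts[1], parts[2])] / 1000.0)
            elif parts[0] == "rr":
                values.append(base.rr[(parts[1], parts[2])])
            elif parts[0] == "progression":
                values.append(base.progression_prob)
            elif parts[0] == "cost":
                values.append(base.costs[parts[1]])
            else:
                values.append(base.utilities[parts[1]])
        rebuilt = _apply_draw(base, names, np.array(values))
        for arm in Arm:
            a = solve_cohort(base, arm, cfg15)
            b = solve_cohort(rebuilt, arm, cfg15)
            assert b.discounted_qalys == pytest.approx(a.discounted_qalys, rel=1e-12)
            assert b.discounted_cost == pytest.approx(a.discounted_cost, rel=1e-12)

    def test_sampled_draws_respect_domains(self, small_psa):
        assert small_psa.n_draws == 400
        assert (small_psa.cost > 0).all()
        assert (small_psa.qaly > 0).all()

    def test_psa_means_near_base_case(self, base_params, small_psa, cfg15):
        """Draw means approximate the base-case cohort values (the model is
        nearly linear over the sampled parameter ranges)."""
        for k, arm in enumerate((Arm.DRUG, Arm.NON_DRUG)):
            base = solve_cohort(base_params, arm, cfg15)
            se_cost = small_psa.cost[:, k].std(ddof=1) / math.sqrt(small_psa.n_draws)
            se_qaly = small_psa.qaly[:, k].std(ddof=1) / math.sqrt(small_psa.n_draws)
            assert abs(small_psa.cost[:, k].mean() - base.discounted_cost) < 5 * se_cost
            assert abs(small_psa.qaly[:, k].mean() - base.discounted_qalys) < 5 * se_qaly

    def test_same_seed_same_draws(self, base_params):
        cfg = RunConfig(horizon_years=8)
        a = run_psa(base_params, cfg, n_draws=50, seed=9)
        b = run_psa(base_params, cfg, n_draws=50, seed=9)
        np.testing.assert_array_equal(a.cost, b.cost)
        np.testing.assert_array_equal(a.qaly, b.qaly)

    def test_microsim_inner_evaluator_runs(self, base_params):
        cfg = RunConfig(horizon_years=8, n_individuals=500, seed=2)
        psa = run_psa(base_params, cfg, n_draws=5, seed=2, inner="microsim")
        assert psa.cost.shape == (5, 2)


class TestCEAC:
    def test_matches_brute_force_nmb_classification(self, small_psa, base_params):
        curve = ceac(small_psa, default_wtp_grid(base_params))
        for wtp, prob in zip(curve["wtp"], curve["probability"]):
            wins = sum(
                1
                for dc, de in zip(small_psa.delta_cost, small_psa.delta_qaly)
                if wtp * de - dc > 0
            )
            assert prob == wins / small_psa.n_draws

    def test_zero_threshold_counts_cost_savings(self, small_psa):
        curve = ceac(small_psa, [0.0])
        assert curve["probability"][0] == (small_psa.delta_cost < 0).mean()

    def test_all_dominant_draws_give_probability_one(self):
        psa = PSAResult(
            cost=np.array([[1.0, 2.0], [3.0, 5.0]]),
            qaly=np.array([[2.0, 1.0], [2.5, 2.0]]),
        )
        curve = ceac(psa, [0.0, 1e4, 1e6])
        assert (curve["probability"] == 1.0).all()

    def test_rejects_bad_grid(self, small_psa):
        with pytest.raises(ValueError):
            ceac(small_psa, [])
        with pytest.raises(ValueError):
            ceac(small_psa, [-1.0])


class TestTTests:
    def test_identical_samples_give_null_result(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        psa = PSAResult(cost=np.column_stack([x, x]), qaly=np.column_stack([x, x]))
        res = psa_t_tests(psa)
        assert res["cost"]["t"] == pytest.approx(0.0)
        assert res["cost"]["p"] == pytest.approx(1.0)

    def test_matches_textbook_welch_formula(self):
        a = np.array([10.0, 12.0, 9.0, 11.0, 13.0])
        b = np.array([8.0, 7.5, 9.0, 8.2, 7.9])
        psa = PSAResult(cost=np.column_stack([a, b]), qaly=np.column_stack([a, b]))
        res = psa_t_tests(psa)
        # brute-force Welch statistic
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        from scipy import stats

        p = 2 * stats.t.sf(abs(t), df)
        assert res["cost"]["t"] == pytest.approx(t, rel=1e-12)
        assert res["cost"]["p"] == pytest.approx(p, rel=1e-9)

    def test_zero_variance_everywhere_is_degenerate(self):
        c = np.ones((5, 2))
        psa = PSAResult(cost=c, qaly=c.copy())
        with pytest.raises(ValueError):
            psa_t_tests(psa)

    def test_nominal_type_i_error_under_null(self):
        """Welch test on equal-mean normal samples rejects ~5% at alpha=0.05."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            a = rng.normal(10.0, 2.0, size=30)
            b = rng.normal(10.0, 3.0, size=30)
            psa = PSAResult(cost=np.column_stack([a, b]), qaly=np.column_stack([a, b]))
            if psa_t_tests(psa)["cost"]["p"] < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_rep <= 0.065


class TestScenarios:
    def test_published_scenario_set(self, base_params):
        results = run_scenarios(base_params)
        by_name = {r.name: r for r in results}
        eight = by_name["8-year horizon"]
        assert eight.comparison.verdict == "icer"
        assert eight.comparison.icer > 0
        assert by_name["15-year horizon"].comparison.verdict == "dominant"
        assert by_name["55-year horizon"].comparison.verdict == "dominant"
        # excluding productivity preserves the 15-year verdict
        assert by_name["15-year, productivity excluded"].comparison.verdict == "dominant"
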