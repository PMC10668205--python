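"""Scenario, one-way (tornado), and probabilistic sensitivity analyses.

The probabilistic sensitivity analysis samples every uncertain input from its
fitted distribution - beta for event rates (on the per-person-year proportion
scale), the progression probability and utilities; gamma (CV 25%) for costs;
lognormal for relative risks - and re-evaluates both strategy arms per draw.
The inner evaluator defaults to the deterministic cohort solver, so the draw
spread reflects parameter (second-order) uncertainty only; an option nests an
inner microsimulation instead.  Cost-effectiveness at a willingness-to-pay
threshold is judged by the incremental net monetary benefit, which is well
defined in every quadrant of the cost-effectiveness plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .economics import ArmResult, CEComparison, compare
from .engine import Arm, RunConfig, run_microsimulation, solve_cohort
from .parameters import (
    COST_ITEMS,
    RATE_EVENTS,
    RR_ENDPOINTS,
    STAGES,
    UTILITY_STATES,
    DistributionSpec,
    ModelInputs,
    ParameterSet,
    as_inputs,
    fit_beta_from_interval,
    fit_gamma_from_mean_cv,
    fit_lognormal_from_ci,
    set_input,
)

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "ScenarioResult",
    "default_tornado_parameters",
    "one_way_tornado",
    "build_psa_samplers",
    "run_psa",
    "ceac",
    "default_wtp_grid",
    "psa_t_tests",
    "run_scenarios",
]


# ---------------------------------------------------------------------------
# One-way (tornado) analysis
# ---------------------------------------------------------------------------

@dataclass
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    outcome_low: float    # incremental NMB at the low input
    outcome_high: float   # incremental NMB at the high input
    icer_low: float | None
    icer_high: float | None

    @property
    def range_width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def default_tornado_parameters(params: ParameterSet) -> list[tuple[str, float, float]]:
    """(name, low, high) triples for every printed uncertainty interval:
    rates and relative risks at their 95% CI bounds, costs at +/-25%,
    utilities at their published ranges, and the discount rate at 0%-8%."""
    out: list[tuple[str, float, float]] = []
    for stage in STAGES:
        for event in RATE_EVENTS:
            est = params.rates[stage][event]
            out.append((f"rate.{stage}.{event}", est.ci_low, est.ci_high))
    out.append(("progression", params.progression.ci_low, params.progression.ci_high))
    for endpoint in RR_ENDPOINTS:
        est = params.relative_risks["stage1"][endpoint]
        if est is not None:
            out.append((f"rr.stage1.{endpoint}", est.ci_low, est.ci_high))
    for item in COST_ITEMS:
        c = params.costs[item]
        out.append((f"cost.{item}", c.low, c.high))
    for state in UTILITY_STATES:
        u = params.utilities[state]
        out.append((f"utility.{state}", u.ci_low, u.ci_high))
    out.append(("discount_rate", params.discount_rate.ci_low, params.discount_rate.ci_high))
    return out


def _incremental(inputs: ModelInputs, config: RunConfig, wtp: float) -> CEComparison:
    drug = solve_cohort(inputs, Arm.DRUG, config)
    non_drug = solve_cohort(inputs, Arm.NON_DRUG, config)
    return compare(drug, non_drug, wtp)


def one_way_tornado(
    params: ParameterSet | ModelInputs,
    varied: list[tuple[str, float, float]],
    config: RunConfig,
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis over ``varied`` (name, low, high) triples.

    Each parameter is set to its low and high value in turn, all others held
    at base case, and both arms re-evaluated with the cohort solver.  Entries
    are returned sorted by descending outcome range; the ranking outcome is
    the incremental net monetary benefit at ``wtp`` (1x GDP per capita by
    default), with the ICER also recorded per entry.
    """
    base = as_inputs(params)
    if wtp is None:
        wtp = base.wtp_per_gdp
    entries = []
    for name, low, high in varied:
        if low > high:
            raise ValueError(f"{name}: low bound exceeds high bound")
        cmp_lo = _incremental(set_input(base, name, low), config, wtp)
        cmp_hi = _incremental(set_input(base, name, high), config, wtp)
        entries.append(
            TornadoEntry(
                parameter=name,
                low_input=low,
                high_input=high,
                outcome_low=cmp_lo.nmb,
                outcome_high=cmp_hi.nmb,
                icer_low=cmp_lo.icer,
                icer_high=cmp_hi.icer,
            )
        )
    entries.sort(key=lambda e: (-e.range_width, e.parameter))
    return entries


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Paired (cost, QALY) draws per arm across parameter samples.

    ``cost`` and ``qaly`` have shape (n_draws, 2) with columns (drug, non-drug).
    """

    cost: np.ndarray
    qaly: np.ndarray
    arms: tuple[str, str] = (Arm.DRUG.value, Arm.NON_DRUG.value)
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return self.cost.shape[0]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost[:, 0] - self.cost[:, 1]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly[:, 0] - self.qaly[:, 1]

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, arm in enumerate(self.arms):
            rows.append(
                {
                    "arm": arm,
                    "mean_cost": self.cost[:, k].mean(),
                    "sd_cost": self.cost[:, k].std(ddof=1),
                    "mean_qaly": self.qaly[:, k].mean(),
                    "sd_qaly": self.qaly[:, k].std(ddof=1),
                }
            )
        return pd.DataFrame(rows)

    def scatter(self) -> pd.DataFrame:
        """Per-draw incremental pairs - the data behind a CE-plane scatter plot."""
        return pd.DataFrame({"delta_qaly": self.delta_qaly, "delta_cost": self.delta_cost})


def build_psa_samplers(params: ParameterSet, *, include_stage2_rrs: bool = False,
                       ) -> list[tuple[str, DistributionSpec]]:
    """Fit one sampling distribution per uncertain input.

    Rates are fitted on the per-person-year proportion scale (rate/1000) and
    scaled back when applied; the stage-2 relative-risk column is sampled only
    when the model is configured to use it.
    """
    samplers: list[tuple[str, DistributionSpec]] = []
    for stage in STAGES:
        for event in RATE_EVENTS:
            est = params.rates[stage][event]
            spec = fit_beta_from_interval(
                est.mean / 1000.0, est.ci_low / 1000.0, est.ci_high / 1000.0
            )
            samplers.append((f"rate.{stage}.{event}", spec))
    p = params.progression
    samplers.append(("progression", fit_beta_from_interval(p.mean, p.ci_low, p.ci_high)))
    rr_stages = ("stage1", "stage2") if include_stage2_rrs else ("stage1",)
    for stage in rr_stages:
        for endpoint in RR_ENDPOINTS:
            est = params.relative_risks[stage][endpoint]
            if est is not None:
                samplers.append(
                    (f"rr.{stage}.{endpoint}",
                     fit_lognormal_from_ci(est.mean, est.ci_low, est.ci_high))
                )
    for item in COST_ITEMS:
        c = params.costs[item]
        samplers.append((f"cost.{item}", fit_gamma_from_mean_cv(c.mean, c.rel_range)))
    for state in UTILITY_STATES:
        u = params.utilities[state]
        samplers.append(
            (f"utility.{state}", fit_beta_from_interval(u.mean, u.ci_low, u.ci_high))
        )
    return samplers


def _apply_draw(base: ModelInputs, names: list[str], values: np.ndarray) -> ModelInputs:
    out = base.clone()
    for name, value in zip(names, values):
        parts = name.split(".")
        if parts[0] == "rate":
            out.rates[(parts[1], parts[2])] = float(value) * 1000.0
        elif parts[0] == "rr":
            out.rr[(parts[1], parts[2])] = float(value)
        elif parts[0] == "progression":
            out.progression_prob = float(value)
        elif parts[0] == "cost":
            out.costs[parts[1]] = float(value)
        elif parts[0] == "utility":
            out.utilities[parts[1]] = float(value)
        else:  # pragma: no cover - sampler names are built above
            raise KeyError(name)
    return out


def run_psa(
    params: ParameterSet,
    config: RunConfig,
    n_draws: int = 10_000,
    seed: int | None = None,
    inner: str = "cohort",
) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n_draws`` parameter samples.

    Each draw replaces every uncertain input by a sample from its fitted
    distribution and evaluates both arms.  ``inner`` selects the evaluator:
    ``"cohort"`` (deterministic, the default) or ``"microsim"`` (nests
    ``config.n_individuals`` simulated patients per draw and arm).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if inner not in ("cohort", "microsim"):
        raise ValueError("inner must be 'cohort' or 'microsim'")
    if seed is None:
        seed = config.seed
    base = params.to_inputs()
    samplers = build_psa_samplers(params, include_stage2_rrs=config.apply_stage2_rrs)
    names = [name for name, _ in samplers]
    rng = np.random.default_rng(seed)
    draws = np.column_stack([spec.sample(rng, n_draws) for _, spec in samplers])

    cost = np.empty((n_draws, 2))
    qaly = np.empty((n_draws, 2))
    for i in range(n_draws):
        inputs_i = _apply_draw(base, names, draws[i])
        for k, arm in enumerate((Arm.DRUG, Arm.NON_DRUG)):
            if inner == "cohort":
                res = solve_cohort(inputs_i, arm, config)
            else:
                inner_cfg = RunConfig(
                    horizon_years=config.horizon_years,
                    n_individuals=config.n_individuals,
                    seed=int(rng.integers(2**31)),
                    discount_rate=config.discount_rate,
                    half_cycle_correction=config.half_cycle_correction,
                    include_productivity=config.include_productivity,
                    apply_stage2_rrs=config.apply_stage2_rrs,
                )
                res = run_microsimulation(inputs_i, arm, inner_cfg)
            cost[i, k] = res.discounted_cost
            qaly[i, k] = res.discounted_qalys
    return PSAResult(cost=cost, qaly=qaly, seed=seed)


def default_wtp_grid(params: ParameterSet | ModelInputs, n: int = 25) -> np.ndarray:
    """Willingness-to-pay grid from 0 to 3x GDP per capita, including the
    exact 1x/2x/3x anchors."""
    gdp = as_inputs(params).wtp_per_gdp
    grid = np.union1d(np.linspace(0.0, 3 * gdp, n), [gdp, 2 * gdp, 3 * gdp])
    return grid


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    The probability at threshold lambda is the fraction of draws with positive
    incremental net monetary benefit lambda * dE - dC.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp grid must be nonempty")
    if (grid < 0).any():
        raise ValueError("wtp values must be nonnegative")
    de = psa.delta_qaly
    dc = psa.delta_cost
    prob = [(w * de - dc > 0).mean() for w in grid]
    return pd.DataFrame({"wtp": grid, "probability": prob})


def psa_t_tests(psa: PSAResult) -> dict[str, dict[str, float]]:
    """Welch two-sample t-tests of the per-draw cost and QALY vectors across arms."""
    if psa.n_draws < 2:
        raise ValueError("need at least 2 draws per arm")
    out = {}
    for label, data in (("cost", psa.cost), ("effectiveness", psa.qaly)):
        a, b = data[:, 0], data[:, 1]
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError(f"degenerate t-test: zero variance in both {label} samples")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out[label] = {"t": float(t), "p": float(p)}
    return out


# ---------------------------------------------------------------------------
# Scenario analyses
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    name: str
    horizon_years: int
    include_productivity: bool
    drug: ArmResult
    non_drug: ArmResult
    comparison: CEComparison


def run_scenarios(
    params: ParameterSet | ModelInputs,
    scenarios: list[dict] | None = None,
    base_config: RunConfig | None = None,
) -> list[ScenarioResult]:
    """Evaluate the base-case comparison under alternative run settings.

    The default scenario list covers the published set: 8- and 15-year
    horizons, the 55-year extended horizon, and the 15-year horizon with
    productivity losses excluded.
    """
    inputs = as_inputs(params)
    if base_config is None:
        base_config = RunConfig()
    if scenarios is None:
        scenarios = [
            {"name": "8-year horizon", "horizon_years": 8},
            {"name": "15-year horizon", "horizon_years": 15},
            {"name": "55-year horizon", "horizon_years": 55},
            {"name": "15-year, productivity excluded", "horizon_years": 15,
             "include_productivity": False},
        ]
    out = []
    for sc in scenarios:
        cfg = RunConfig(
            horizon_years=sc.get("horizon_years", base_config.horizon_years),
            n_individuals=base_config.n_individuals,
            seed=base_config.seed,
            discount_rate=base_config.discount_rate,
            half_cycle_correction=base_config.half_cycle_correction,
            include_productivity=sc.get(
                "include_productivity", base_config.include_productivity
            ),
            apply_stage2_rrs=base_config.apply_stage2_rrs,
        )
        drug = solve_cohort(inputs, Arm.DRUG, cfg)
        non_drug = solve_cohort(inputs, Arm.NON_DRUG, cfg)
        out.append(
            ScenarioResult(
                name=sc.get("name", f"{cfg.horizon_years}-year horizon"),
                horizon_years=cfg.horizon_years,
                include_productivity=cfg.include_productivity,
                drug=drug,
                non_drug=non_drug,
                comparison=compare(drug, non_drug, inputs.wtp_per_gdp),
            )
        )
    return out
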