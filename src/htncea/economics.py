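"""Cost and QALY accrual, discounting, and incremental cost-effectiveness.

Accrual convention
------------------
Values attach to state occupancy at cycle boundaries t = 0..H and are
discounted by (1 + r)^-t (boundary 0 undiscounted).  With the half-cycle
correction (base case) boundary weights are the trapezoid 1/2, 1, ..., 1, 1/2
over [0, H]; without it, full weight on boundaries 0..H-1 (state at cycle
start).  Productivity losses accrue to all living patients over the first
``productivity_window_years`` (10 in the base case, the cohort's mean
early-retirement horizon), using the same boundary weights masked to the
window.  In the zero-event, unit-utility, zero-discount limit both
conventions give exactly H QALYs over an H-year horizon.

Cost categories mirror the published breakdown: stage-1 hypertension
(screening/management plus, in the drug arm, one standard-dose drug), stage-2
hypertension (management plus drug in both arms, since stage 2 includes
receiving antihypertensive medication), stroke (acute first-year and chronic
subsequent-year), MI (likewise), and productivity loss (4.8% lower in the
drug arm).  The total discounted cost is exactly the sum of the five
categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import (
    ALIVE,
    MI_1,
    MI_2,
    N_STATES,
    POST_MI_1,
    POST_MI_2,
    POST_STROKE_1,
    POST_STROKE_2,
    S1,
    S2,
    STROKE_1,
    STROKE_2,
    Arm,
    RunConfig,
    State,
)
from .parameters import ModelInputs

__all__ = [
    "CATEGORIES",
    "ArmResult",
    "CEComparison",
    "discount",
    "boundary_weights",
    "productivity_weights",
    "accrue_cycle",
    "accrue_occupancy",
    "accrue_states",
    "compare",
]

CATEGORIES = ("stage1", "stage2", "stroke", "mi", "productivity")


@dataclass
class ArmResult:
    """Discounted outcomes of one strategy arm.

    Monte-Carlo standard errors are zero for the deterministic cohort solver.
    """

    arm: Arm
    horizon_years: int
    discounted_qalys: float
    discounted_cost: float
    cost_by_category: dict[str, float]
    se_qalys: float = 0.0
    se_cost: float = 0.0
    n_individuals: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.cost_by_category.values())
        if not math.isclose(total, self.discounted_cost, rel_tol=0, abs_tol=1e-6):
            raise ValueError("discounted_cost must equal the sum of categories")

    def to_dict(self) -> dict:
        return {
            "arm": self.arm.value,
            "horizon_years": self.horizon_years,
            "discounted_qalys": self.discounted_qalys,
            "discounted_cost": self.discounted_cost,
            "cost_by_category": dict(self.cost_by_category),
            "se_qalys": self.se_qalys,
            "se_cost": self.se_cost,
            "n_individuals": self.n_individuals,
        }


@dataclass
class CEComparison:
    """Incremental comparison of an intervention against a reference strategy."""

    delta_cost: float
    delta_qaly: float
    wtp: float
    icer: float | None
    verdict: str          # "dominant", "dominated", "icer", or "no_icer"
    cost_effective: bool
    nmb: float            # incremental net monetary benefit at wtp

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "wtp": self.wtp,
            "icer": self.icer,
            "verdict": self.verdict,
            "cost_effective": self.cost_effective,
            "nmb": self.nmb,
        }


def discount(amount: float, cycle_index: int, rate: float) -> float:
    """Present value of ``amount`` accrued at cycle boundary ``cycle_index``."""
    if rate < 0:
        raise ValueError("discount rate must be nonnegative")
    return amount / (1.0 + rate) ** cycle_index


def boundary_weights(horizon: int, half_cycle_correction: bool) -> np.ndarray:
    """Accrual weights over cycle boundaries 0..H (see module docstring)."""
    w = np.ones(horizon + 1)
    if half_cycle_correction:
        w[0] = 0.5
        w[-1] = 0.5
    else:
        w[-1] = 0.0
    return w


def productivity_weights(horizon: int, window: int, half_cycle_correction: bool) -> np.ndarray:
    """Weights for the productivity-loss window.

    The global boundary trapezoid masked to the window: with the half-cycle
    correction, boundaries t <= window keep their trapezoid weight (half at
    t = 0 and, when the horizon ends inside the window, at t = H); without
    it, full weight on boundaries t < window.
    """
    w = boundary_weights(horizon, half_cycle_correction)
    if half_cycle_correction:
        w[window + 1:] = 0.0
    else:
        w[window:] = 0.0
    return w


def _productivity_rate(inputs: ModelInputs, arm: Arm) -> float:
    rate = inputs.costs["productivity"]
    if arm is Arm.DRUG:
        rate *= 1.0 - inputs.productivity_reduction_drug
    return rate


def _state_tables(inputs: ModelInputs, arm: Arm) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-boundary utility vector (11,), cost matrix (11, 4 state categories),
    and productivity rate vector (11,)."""
    u = np.zeros(N_STATES)
    u[S1] = u[S2] = inputs.utilities["hypertension"]
    u[STROKE_1] = u[STROKE_2] = inputs.utilities["stroke"]
    u[POST_STROKE_1] = u[POST_STROKE_2] = inputs.utilities["post_stroke"]
    u[MI_1] = u[MI_2] = inputs.utilities["mi"]
    u[POST_MI_1] = u[POST_MI_2] = inputs.utilities["post_mi"]

    cost = np.zeros((N_STATES, 4))  # stage1, stage2, stroke, mi
    stage1_cost = inputs.costs["screening"]
    if arm is Arm.DRUG:
        stage1_cost += inputs.costs["drug"]
    cost[S1, 0] = stage1_cost
    cost[S2, 1] = inputs.costs["screening"] + inputs.costs["drug"]
    cost[STROKE_1, 2] = cost[STROKE_2, 2] = inputs.costs["stroke_first_year"]
    cost[POST_STROKE_1, 2] = cost[POST_STROKE_2, 2] = inputs.costs["stroke_subsequent"]
    cost[MI_1, 3] = cost[MI_2, 3] = inputs.costs["mi_first_year"]
    cost[POST_MI_1, 3] = cost[POST_MI_2, 3] = inputs.costs["mi_subsequent"]

    prod = np.where(ALIVE, _productivity_rate(inputs, arm), 0.0)
    return u, cost, prod


def _weight_vectors(inputs: ModelInputs, config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Discounted accrual weights (w*v, pw*v) over boundaries 0..H."""
    rate = config.discount_rate if config.discount_rate is not None else inputs.discount_rate
    if rate < 0:
        raise ValueError("discount rate must be nonnegative")
    H = config.horizon_years
    v = (1.0 + rate) ** -np.arange(H + 1)
    w = boundary_weights(H, config.half_cycle_correction) * v
    if config.include_productivity:
        pw = productivity_weights(H, inputs.productivity_window_years,
                                  config.half_cycle_correction) * v
    else:
        pw = np.zeros(H + 1)
    return w, pw


def accrue_cycle(
    state: State | int,
    stage_attr: int,
    arm: Arm | str,
    cycle_index: int,
    inputs: ModelInputs,
    config: RunConfig,
) -> tuple[dict[str, float], float]:
    """Undiscounted, unweighted accrual for occupying one state at one boundary.

    Returns a per-category cost dict and the utility weight.  Productivity is
    zero outside the accrual window (boundaries up to ``window`` with the
    half-cycle trapezoid, strictly below it otherwise); the boundary weights
    themselves are applied by the integrators.
    """
    arm = Arm(arm)
    state = State(state)
    if state is State.DEAD:
        return {c: 0.0 for c in CATEGORIES}, 0.0
    if stage_attr not in (1, 2):
        raise ValueError("stage_attr must be 1 or 2")

    costs = {c: 0.0 for c in CATEGORIES}
    if state is State.STAGE1_HTN:
        costs["stage1"] = inputs.costs["screening"]
        if arm is Arm.DRUG:
            costs["stage1"] += inputs.costs["drug"]
        utility = inputs.utilities["hypertension"]
    elif state is State.STAGE2_HTN:
        costs["stage2"] = inputs.costs["screening"] + inputs.costs["drug"]
        utility = inputs.utilities["hypertension"]
    elif state is State.STROKE:
        costs["stroke"] = inputs.costs["stroke_first_year"]
        utility = inputs.utilities["stroke"]
    elif state is State.POST_STROKE:
        costs["stroke"] = inputs.costs["stroke_subsequent"]
        utility = inputs.utilities["post_stroke"]
    elif state is State.MI:
        costs["mi"] = inputs.costs["mi_first_year"]
        utility = inputs.utilities["mi"]
    elif state is State.POST_MI:
        costs["mi"] = inputs.costs["mi_subsequent"]
        utility = inputs.utilities["post_mi"]
    else:  # pragma: no cover - exhaustive
        raise ValueError(f"unknown state {state!r}")

    window = inputs.productivity_window_years
    in_window = cycle_index <= window if config.half_cycle_correction else cycle_index < window
    if config.include_productivity and in_window:
        costs["productivity"] = _productivity_rate(inputs, arm)
    return costs, utility


def accrue_occupancy(
    occ: np.ndarray,
    inputs: ModelInputs,
    arm: Arm,
    config: RunConfig,
) -> ArmResult:
    """Discounted outcomes from a deterministic occupancy trace (H+1, 11)."""
    u, cost, prod = _state_tables(inputs, arm)
    w, pw = _weight_vectors(inputs, config)

    qalys = float(w @ (occ @ u))
    by_cat = {
        name: float(w @ (occ @ cost[:, k]))
        for k, name in enumerate(CATEGORIES[:4])
    }
    by_cat["productivity"] = float(pw @ (occ @ prod))
    return ArmResult(
        arm=arm,
        horizon_years=config.horizon_years,
        discounted_qalys=qalys,
        discounted_cost=sum(by_cat.values()),
        cost_by_category=by_cat,
    )


def accrue_states(
    states: np.ndarray,
    inputs: ModelInputs,
    arm: Arm,
    config: RunConfig,
) -> ArmResult:
    """Discounted outcomes from microsimulated state paths (n, H+1).

    Means carry Monte-Carlo standard errors of the per-individual totals.
    """
    n = states.shape[0]
    u, cost, prod = _state_tables(inputs, arm)
    w, pw = _weight_vectors(inputs, config)

    qaly_i = (u[states] * w).sum(axis=1)
    cat_totals: dict[str, float] = {}
    cost_i = np.zeros(n)
    for k, name in enumerate(CATEGORIES[:4]):
        c_i = (cost[:, k][states] * w).sum(axis=1)
        cat_totals[name] = float(c_i.mean())
        cost_i += c_i
    p_i = (prod[states] * pw).sum(axis=1)
    cat_totals["productivity"] = float(p_i.mean())
    cost_i += p_i

    se = lambda x: float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return ArmResult(
        arm=arm,
        horizon_years=config.horizon_years,
        discounted_qalys=float(qaly_i.mean()),
        discounted_cost=float(cost_i.mean()),
        cost_by_category=cat_totals,
        se_qalys=se(qaly_i),
        se_cost=se(cost_i),
        n_individuals=n,
    )


def compare(intervention: ArmResult, reference: ArmResult, wtp: float) -> CEComparison:
    """Incremental cost-effectiveness of ``intervention`` vs ``reference``.

    Quadrant rules: lower cost and higher effect is dominant; higher cost and
    lower effect is dominated; otherwise the ICER delta_cost / delta_qaly
    applies.  ``cost_effective`` uses the net-monetary-benefit sign at the
    willingness-to-pay threshold, which handles every quadrant without
    division.  A zero QALY difference yields no ICER and is flagged.
    """
    if wtp < 0:
        raise ValueError("willingness-to-pay must be nonnegative")
    dc = intervention.discounted_cost - reference.discounted_cost
    de = intervention.discounted_qalys - reference.discounted_qalys
    nmb = wtp * de - dc

    if dc < 0 and de > 0:
        verdict, icer = "dominant", None
    elif dc > 0 and de < 0:
        verdict, icer = "dominated", None
    elif de == 0:
        verdict, icer = "no_icer", None
    else:
        verdict, icer = "icer", dc / de

    if verdict == "dominant":
        ce = True
    elif verdict == "dominated":
        ce = False
    elif verdict == "no_icer":
        ce = dc < 0
    elif de > 0:
        ce = icer <= wtp
    else:  # de < 0, dc <= 0: acceptable only if savings per QALY lost >= wtp
        ce = dc < 0 and abs(dc) / abs(de) >= wtp
    return CEComparison(
        delta_cost=dc,
        delta_qaly=de,
        wtp=wtp,
        icer=icer,
        verdict=verdict,
        cost_effective=ce,
        nmb=nmb,
    )
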