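"""Markov state-transition engine for the hypertension treatment model.

Seven clinical health states: stage 1 hypertension, stage 2 hypertension,
acute stroke, post-stroke, acute MI, post-MI, and death (absorbing).  Acute
stroke/MI are one-cycle tunnel states that feed the matching chronic state
unless a recurrence, a cross event, or death intervenes.  Because second-event
rates are stratified by hypertension stage, each patient carries a persistent
stage attribute frozen at the time of the first event; internally the model
therefore runs on an 11-element expanded state space (clinical state x stage
attribute, with death unstratified).

Two evaluators share one transition model and one accrual convention:

* :func:`run_microsimulation` - individual-level simulation (first-order
  Monte Carlo), one multinomial draw per patient-cycle.
* :func:`solve_cohort` - deterministic occupancy propagation; the exact
  n -> infinity limit of the microsimulation, used as the internal oracle and
  as the fast inner evaluator for sensitivity analyses.

Cycle length is one year.  All patients start in stage 1 hypertension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum, IntEnum

import numpy as np

from .parameters import ModelInputs, ParameterSet, as_inputs

__all__ = [
    "Arm",
    "State",
    "EXPANDED_STATES",
    "RunConfig",
    "TransitionModel",
    "Trajectory",
    "PatientState",
    "build_transition_model",
    "simulate_individual",
    "simulate_states",
    "run_microsimulation",
    "solve_cohort",
    "cohort_trace",
]


class Arm(str, Enum):
    DRUG = "drug"
    NON_DRUG = "non_drug"


class State(IntEnum):
    """Clinical health state labels."""

    STAGE1_HTN = 0
    STAGE2_HTN = 1
    STROKE = 2
    POST_STROKE = 3
    MI = 4
    POST_MI = 5
    DEAD = 6


# Expanded (clinical state, stage attribute) space. The stage attribute
# selects the rate column for second events and is frozen at first-event time.
S1 = 0           # stage 1 hypertension (attribute 1 by definition)
S2 = 1           # stage 2 hypertension (attribute 2 by definition)
STROKE_1 = 2
STROKE_2 = 3
POST_STROKE_1 = 4
POST_STROKE_2 = 5
MI_1 = 6
MI_2 = 7
POST_MI_1 = 8
POST_MI_2 = 9
DEAD = 10
N_STATES = 11

EXPANDED_STATES: tuple[tuple[State, int], ...] = (
    (State.STAGE1_HTN, 1),
    (State.STAGE2_HTN, 2),
    (State.STROKE, 1),
    (State.STROKE, 2),
    (State.POST_STROKE, 1),
    (State.POST_STROKE, 2),
    (State.MI, 1),
    (State.MI, 2),
    (State.POST_MI, 1),
    (State.POST_MI, 2),
    (State.DEAD, 0),
)

ALIVE = np.array([s != State.DEAD for s, _ in EXPANDED_STATES])
ACUTE_STROKE = (STROKE_1, STROKE_2)
ACUTE_MI = (MI_1, MI_2)


@dataclass
class RunConfig:
    """Run-level settings of one model evaluation.

    ``discount_rate=None`` defers to the parameter file (5% base case).
    """

    horizon_years: int = 15
    n_individuals: int = 100_000
    seed: int = 0
    discount_rate: float | None = None
    half_cycle_correction: bool = True
    include_productivity: bool = True
    apply_stage2_rrs: bool = False  # treat progressed patients with stage-2-column RRs

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass
class TransitionModel:
    """Annual transition structure for one strategy arm.

    ``matrix[i, j]`` is the per-cycle probability of moving from expanded
    state i to j.  Each cause-specific hazard converts independently,
    p = 1 - exp(-h); the stage-1 -> stage-2 progression probability enters
    directly (it is published as an annual percentage); the residual
    1 - sum(p) goes to the row's residual destination (the state itself, or
    the chronic post state for the acute tunnel states).  At the published
    rate magnitudes every row's cause probabilities sum to well under 1;
    this is asserted at build time.  ``hazards[(i, j)]`` keeps the
    underlying cause-specific annual hazards.
    """

    arm: Arm
    matrix: np.ndarray
    hazards: dict[tuple[int, int], float]
    residual_dest: dict[int, int]
    progression_prob: float = 0.0  # annual stage-1 -> stage-2 probability

    def cause_specific_prob(self, i: int, j: int) -> float:
        """Annual probability 1 - exp(-h) of the (i -> j) cause-specific hazard."""
        return -math.expm1(-self.hazards.get((i, j), 0.0))

    def validate(self) -> None:
        if self.matrix.shape != (N_STATES, N_STATES):
            raise ValueError("transition matrix must be 11x11")
        if (self.matrix < 0).any() or (self.matrix > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        off_dead = self.matrix[DEAD].copy()
        off_dead[DEAD] = 0.0
        if off_dead.any():
            raise ValueError("death must be absorbing")


def _drug_multiplier(inputs: ModelInputs, arm: Arm, stage: str, endpoint: str,
                     apply_stage2_rrs: bool) -> float:
    """Hazard/probability multiplier of drug treatment for one (stage, endpoint).

    The published treatment-effect values are relative risk *reductions*
    (see :class:`~htncea.parameters.ParameterSet`), so the multiplier is
    ``1 - value``, clipped to [0, 1] for sampled values beyond the null.
    """
    if arm is not Arm.DRUG:
        return 1.0
    if stage == "stage2" and not apply_stage2_rrs:
        return 1.0
    reduction = inputs.rr.get((stage, endpoint))
    if reduction is None:
        return 1.0
    return min(max(1.0 - reduction, 0.0), 1.0)


def _progression_prob(inputs: ModelInputs, arm: Arm,
                      apply_stage2_rrs: bool) -> float:
    """Annual stage-1 -> stage-2 probability for one arm."""
    p = inputs.progression_prob * _drug_multiplier(
        inputs, arm, "stage1", "progression", apply_stage2_rrs
    )
    return min(max(p, 0.0), 1.0)


def build_transition_model(
    params: ParameterSet | ModelInputs,
    arm: Arm | str,
    *,
    apply_stage2_rrs: bool = False,
) -> TransitionModel:
    """Build the annual transition model for one strategy arm.

    Drug-arm treatment effects apply to patients with stage attribute 1
    (first events, mortality, progression, and recurrent events);
    progressed/stage-2 patients receive usual care in both arms unless
    ``apply_stage2_rrs`` is set.  Cross events (MI after stroke, stroke
    after MI) and post-event mortality carry no treatment effect.
    """
    inputs = as_inputs(params)
    arm = Arm(arm)

    def h(stage: str, event: str, endpoint: str | None = None) -> float:
        base = inputs.rates[(stage, event)] / 1000.0
        if endpoint is None:
            return base
        return base * _drug_multiplier(inputs, arm, stage, endpoint, apply_stage2_rrs)

    hazards: dict[tuple[int, int], float] = {}
    residual: dict[int, int] = {}

    # Stage 1 hypertension: first events, death, progression; competing.
    hazards[(S1, STROKE_1)] = h("stage1", "stroke", "stroke")
    hazards[(S1, MI_1)] = h("stage1", "mi", "mi")
    hazards[(S1, DEAD)] = h("stage1", "death", "death")
    progression = _progression_prob(inputs, arm, apply_stage2_rrs)
    residual[S1] = S1

    # Stage 2 hypertension: first events and death at the stage-2 column rates.
    hazards[(S2, STROKE_2)] = h("stage2", "stroke", "stroke")
    hazards[(S2, MI_2)] = h("stage2", "mi", "mi")
    hazards[(S2, DEAD)] = h("stage2", "death", "death")
    residual[S2] = S2

    # Stroke states, by stage attribute: recurrence (re-entering the acute
    # state), cross MI, post-event death. The acute tunnel exits to the
    # chronic post state; the post state is its own residual.
    for stage, acute, post, mi_dest in (
        ("stage1", STROKE_1, POST_STROKE_1, MI_1),
        ("stage2", STROKE_2, POST_STROKE_2, MI_2),
    ):
        for src in (acute, post):
            hazards[(src, acute)] = h(stage, "recurrent_stroke", "recurrent_stroke")
            hazards[(src, mi_dest)] = h(stage, "mi_after_stroke")
            hazards[(src, DEAD)] = h(stage, "death_after_stroke")
        residual[acute] = post
        residual[post] = post

    # MI states, symmetric.
    for stage, acute, post, stroke_dest in (
        ("stage1", MI_1, POST_MI_1, STROKE_1),
        ("stage2", MI_2, POST_MI_2, STROKE_2),
    ):
        for src in (acute, post):
            hazards[(src, acute)] = h(stage, "recurrent_mi", "recurrent_mi")
            hazards[(src, stroke_dest)] = h(stage, "stroke_after_mi")
            hazards[(src, DEAD)] = h(stage, "death_after_mi")
        residual[acute] = post
        residual[post] = post

    matrix = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        if i == DEAD:
            matrix[i, DEAD] = 1.0
            continue
        for (src, j), hz in hazards.items():
            if src == i:
                matrix[i, j] += -math.expm1(-hz)
        if i == S1:
            matrix[S1, S2] += progression
        out = matrix[i].sum()
        if out > 1.0 + 1e-12:
            raise ValueError(
                f"outgoing probabilities from state {i} sum to {out:.6f} > 1"
            )
        matrix[i, residual[i]] += max(0.0, 1.0 - out)

    model = TransitionModel(arm=arm, matrix=matrix, hazards=hazards,
                            residual_dest=residual, progression_prob=progression)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Trajectories (individual level)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientState:
    clinical: State
    stage_attr: int
    years_since_entry: int
    had_event: bool


@dataclass
class Trajectory:
    """States of one simulated patient at cycle boundaries 0..H.

    ``states[t]`` is the expanded-state index after t transitions;
    ``states[0]`` is always stage 1 hypertension.
    """

    states: np.ndarray  # (H+1,) int

    @property
    def horizon(self) -> int:
        return len(self.states) - 1

    def patient_states(self) -> list[PatientState]:
        out = []
        had_event = False
        for t, idx in enumerate(self.states):
            clinical, attr = EXPANDED_STATES[idx]
            if clinical in (State.STROKE, State.MI):
                had_event = True
            out.append(PatientState(clinical, attr, t, had_event))
        return out

    def new_strokes(self) -> np.ndarray:
        """Boolean per boundary 1..H: entered (or re-entered) the acute stroke state."""
        s = self.states
        return np.isin(s[1:], ACUTE_STROKE)

    def new_mis(self) -> np.ndarray:
        s = self.states
        return np.isin(s[1:], ACUTE_MI)

    def death_cycle(self) -> int | None:
        dead = np.nonzero(self.states == DEAD)[0]
        return int(dead[0]) if dead.size else None


def simulate_states(
    model: TransitionModel,
    horizon_years: int,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    """Simulate ``n`` independent patients; returns (n, H+1) expanded-state indices."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cum = np.cumsum(model.matrix, axis=1)
    cum[:, -1] = 1.0  # guard against float round-off in the final column
    states = np.empty((n, horizon_years + 1), dtype=np.int8)
    states[:, 0] = S1
    cur = np.full(n, S1, dtype=np.intp)
    for t in range(horizon_years):
        u = rng.random(n)
        cur = (cum[cur] < u[:, None]).sum(axis=1)
        states[:, t + 1] = cur
    return states


def simulate_individual(
    model: TransitionModel,
    config: RunConfig,
    rng: np.random.Generator,
) -> Trajectory:
    """Simulate a single patient trajectory over the configured horizon."""
    states = simulate_states(model, config.horizon_years, rng, 1)[0]
    return Trajectory(states=states.astype(np.intp))


# ---------------------------------------------------------------------------
# Arm-level evaluation
# ---------------------------------------------------------------------------

def cohort_trace(
    params: ParameterSet | ModelInputs,
    arm: Arm | str,
    config: RunConfig,
) -> np.ndarray:
    """Deterministic state occupancy at each cycle boundary, shape (H+1, 11)."""
    model = build_transition_model(params, arm, apply_stage2_rrs=config.apply_stage2_rrs)
    occ = np.zeros((config.horizon_years + 1, N_STATES))
    occ[0, S1] = 1.0
    for t in range(config.horizon_years):
        occ[t + 1] = occ[t] @ model.matrix
    return occ


def solve_cohort(
    params: ParameterSet | ModelInputs,
    arm: Arm | str,
    config: RunConfig,
):
    """Deterministic cohort evaluation (expected-value oracle of the microsimulation)."""
    from .economics import accrue_occupancy

    inputs = as_inputs(params)
    occ = cohort_trace(inputs, arm, config)
    total = occ.sum(axis=1)
    if not np.allclose(total, 1.0, atol=1e-12):
        raise RuntimeError("state occupancy is not conserved")
    return accrue_occupancy(occ, inputs, Arm(arm), config)


def run_microsimulation(
    params: ParameterSet | ModelInputs,
    arm: Arm | str,
    config: RunConfig,
):
    """Individual-level evaluation: mean discounted QALYs/costs over ``n_individuals``.

    The random stream is keyed on (seed, arm) so the two arms are simulated
    independently and any (seed, config, params) triple is bit-reproducible.
    """
    from .economics import accrue_states

    inputs = as_inputs(params)
    arm = Arm(arm)
    model = build_transition_model(inputs, arm, apply_stage2_rrs=config.apply_stage2_rrs)
    rng = np.random.default_rng([config.seed, list(Arm).index(arm)])
    states = simulate_states(model, config.horizon_years, rng, config.n_individuals)
    return accrue_states(states, inputs, arm, config)
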