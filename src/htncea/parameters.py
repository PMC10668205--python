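"""Model inputs for the hypertension treatment cost-effectiveness model.

Every input of the decision model lives here: cardiovascular event rates per
1000 person-years with 95% CIs (stratified by hypertension stage), the annual
probability of progression from stage 1 to stage 2 hypertension, relative
risks of drug treatment, annual costs in 2020 US dollars with +/-25%
uncertainty ranges, EQ-5D health-state utilities, the annual discount rate,
and the per-capita-GDP willingness-to-pay anchor.

The module also provides the standard actuarial rate-to-probability
conversion and fits the sampling distributions used by the probabilistic
sensitivity analysis: beta for rates/probabilities/utilities, gamma for
costs, lognormal for relative risks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy import optimize, stats

__all__ = [
    "STAGES",
    "FIRST_EVENTS",
    "SECOND_EVENTS",
    "RATE_EVENTS",
    "RR_ENDPOINTS",
    "COST_ITEMS",
    "UTILITY_STATES",
    "RateEstimate",
    "RelativeRisk",
    "AnnualCost",
    "Utility",
    "Probability",
    "ParameterSet",
    "ModelInputs",
    "DistributionSpec",
    "rate_to_prob",
    "fit_beta_from_interval",
    "fit_gamma_from_mean_cv",
    "fit_lognormal_from_ci",
    "load_parameters",
    "load_default_parameters",
    "default_parameter_path",
    "set_input",
]

STAGES = ("stage1", "stage2")
FIRST_EVENTS = ("stroke", "mi", "death")
SECOND_EVENTS = (
    "mi_after_stroke",
    "recurrent_stroke",
    "death_after_stroke",
    "stroke_after_mi",
    "recurrent_mi",
    "death_after_mi",
)
RATE_EVENTS = FIRST_EVENTS + SECOND_EVENTS
RR_ENDPOINTS = ("stroke", "recurrent_stroke", "mi", "recurrent_mi", "death", "progression")
COST_ITEMS = (
    "screening",
    "drug",
    "productivity",
    "stroke_first_year",
    "stroke_subsequent",
    "mi_first_year",
    "mi_subsequent",
)
UTILITY_STATES = ("hypertension", "stroke", "post_stroke", "mi", "post_mi")

_Z975 = float(stats.norm.ppf(0.975))


class RateEstimate(BaseModel):
    """Event rate per 1000 person-years with a 95% confidence interval."""

    mean: float = Field(ge=0)
    ci_low: float = Field(ge=0)
    ci_high: float

    @model_validator(mode="after")
    def _ordered(self) -> "RateEstimate":
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError(
                f"rate CI must satisfy ci_low <= mean <= ci_high, got "
                f"{self.ci_low} / {self.mean} / {self.ci_high}"
            )
        return self


class RelativeRisk(BaseModel):
    """Dimensionless treatment-effect value with a 95% confidence interval.

    The published effect rows are relative risk reductions; the drug arm
    applies the multiplier ``1 - mean`` (see :class:`ParameterSet`).
    """

    mean: float = Field(gt=0)
    ci_low: float = Field(gt=0)
    ci_high: float

    @model_validator(mode="after")
    def _ordered(self) -> "RelativeRisk":
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError(
                f"RR CI must satisfy ci_low <= mean <= ci_high, got "
                f"{self.ci_low} / {self.mean} / {self.ci_high}"
            )
        return self


class AnnualCost(BaseModel):
    """Annual cost in 2020 US dollars with a fractional uncertainty half-width."""

    mean: float = Field(ge=0)
    rel_range: float = Field(default=0.25, gt=0, lt=1)

    @property
    def low(self) -> float:
        return self.mean * (1 - self.rel_range)

    @property
    def high(self) -> float:
        return self.mean * (1 + self.rel_range)


class Utility(BaseModel):
    """Health-state utility weight on [0, 1] with its published range."""

    mean: float = Field(ge=0, le=1)
    ci_low: float = Field(ge=0)
    ci_high: float = Field(le=1)

    @model_validator(mode="after")
    def _ordered(self) -> "Utility":
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError(
                f"utility range must satisfy ci_low <= mean <= ci_high, got "
                f"{self.ci_low} / {self.mean} / {self.ci_high}"
            )
        return self


class Probability(BaseModel):
    """Annual transition probability on [0, 1] with its published range."""

    mean: float = Field(ge=0, le=1)
    ci_low: float = Field(ge=0)
    ci_high: float = Field(le=1)

    @model_validator(mode="after")
    def _ordered(self) -> "Probability":
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError(
                f"probability range must satisfy ci_low <= mean <= ci_high, got "
                f"{self.ci_low} / {self.mean} / {self.ci_high}"
            )
        return self


class StageRates(BaseModel):
    stroke: RateEstimate
    mi: RateEstimate
    death: RateEstimate
    mi_after_stroke: RateEstimate
    recurrent_stroke: RateEstimate
    death_after_stroke: RateEstimate
    stroke_after_mi: RateEstimate
    recurrent_mi: RateEstimate
    death_after_mi: RateEstimate

    def __getitem__(self, event: str) -> RateEstimate:
        if event not in RATE_EVENTS:
            raise KeyError(event)
        return getattr(self, event)


class StageRelativeRisks(BaseModel):
    stroke: RelativeRisk
    recurrent_stroke: RelativeRisk
    mi: RelativeRisk
    recurrent_mi: RelativeRisk
    death: RelativeRisk
    progression: Optional[RelativeRisk] = None

    def __getitem__(self, endpoint: str) -> Optional[RelativeRisk]:
        if endpoint not in RR_ENDPOINTS:
            raise KeyError(endpoint)
        return getattr(self, endpoint)


class ParameterSet(BaseModel):
    """The full input registry of the decision model (point estimates + uncertainty).

    Notes on conventions
    --------------------
    * ``progression`` is an annual transition probability, used directly
      (not a rate needing conversion).
    * ``relative_risks`` holds the published drug-treatment effect rows.
      These values are relative risk *reductions* derived from the treatment
      literature (e.g. 0.61 for hypertension progression): the engine
      multiplies the corresponding event hazard - or, for progression, the
      annual probability - by ``1 - value`` in the drug arm.  The stage-2
      column is carried for scenario use but is off in the base case
      (progressed patients receive usual care in both arms).
    """

    rates: dict[str, StageRates]
    progression: Probability
    relative_risks: dict[str, StageRelativeRisks]
    costs: dict[str, AnnualCost]
    productivity_reduction_drug: float = Field(default=0.048, ge=0, le=1)
    productivity_window_years: int = Field(default=10, ge=0)
    utilities: dict[str, Utility]
    discount_rate: Probability
    wtp_per_gdp: float = Field(default=10438.66, gt=0)

    @model_validator(mode="after")
    def _complete(self) -> "ParameterSet":
        for stage in STAGES:
            if stage not in self.rates:
                raise ValueError(f"rates missing stage {stage!r}")
            if stage not in self.relative_risks:
                raise ValueError(f"relative_risks missing stage {stage!r}")
        missing = [c for c in COST_ITEMS if c not in self.costs]
        if missing:
            raise ValueError(f"costs missing {missing}")
        missing = [u for u in UTILITY_STATES if u not in self.utilities]
        if missing:
            raise ValueError(f"utilities missing {missing}")
        if self.relative_risks["stage1"].progression is None:
            raise ValueError("relative_risks.stage1.progression is required")
        if not 0 <= self.discount_rate.mean <= 0.5:
            raise ValueError("discount_rate must be in [0, 0.5]")
        return self

    def to_inputs(self) -> "ModelInputs":
        return ModelInputs.from_parameters(self)


@dataclass
class ModelInputs:
    """Point-estimate view of a :class:`ParameterSet` consumed by the engine.

    A plain scalar container so that sensitivity analyses can perturb values
    freely (sampled draws legitimately fall outside the printed intervals, so
    no interval-consistency validation applies here).
    """

    rates: dict[tuple[str, str], float]          # (stage, event) -> per 1000 py
    progression_prob: float                      # annual probability, stage 1 -> 2
    rr: dict[tuple[str, str], float]             # (stage, endpoint) -> ratio
    costs: dict[str, float]                      # item -> $ per year
    productivity_reduction_drug: float
    productivity_window_years: int
    utilities: dict[str, float]                  # state -> weight
    discount_rate: float
    wtp_per_gdp: float

    @classmethod
    def from_parameters(cls, params: ParameterSet) -> "ModelInputs":
        rates = {
            (stage, event): params.rates[stage][event].mean
            for stage in STAGES
            for event in RATE_EVENTS
        }
        rr = {}
        for stage in STAGES:
            for endpoint in RR_ENDPOINTS:
                est = params.relative_risks[stage][endpoint]
                if est is not None:
                    rr[(stage, endpoint)] = est.mean
        return cls(
            rates=rates,
            progression_prob=params.progression.mean,
            rr=rr,
            costs={c: params.costs[c].mean for c in COST_ITEMS},
            productivity_reduction_drug=params.productivity_reduction_drug,
            productivity_window_years=params.productivity_window_years,
            utilities={u: params.utilities[u].mean for u in UTILITY_STATES},
            discount_rate=params.discount_rate.mean,
            wtp_per_gdp=params.wtp_per_gdp,
        )

    def clone(self) -> "ModelInputs":
        return ModelInputs(
            rates=dict(self.rates),
            progression_prob=self.progression_prob,
            rr=dict(self.rr),
            costs=dict(self.costs),
            productivity_reduction_drug=self.productivity_reduction_drug,
            productivity_window_years=self.productivity_window_years,
            utilities=dict(self.utilities),
            discount_rate=self.discount_rate,
            wtp_per_gdp=self.wtp_per_gdp,
        )


def as_inputs(params: "ParameterSet | ModelInputs") -> ModelInputs:
    if isinstance(params, ParameterSet):
        return params.to_inputs()
    return params


def set_input(inputs: ModelInputs, name: str, value: float) -> ModelInputs:
    """Return a copy of ``inputs`` with one named scalar replaced.

    Names use dotted paths: ``rate.stage1.stroke``, ``rr.stage1.progression``,
    ``progression``, ``cost.productivity``, ``utility.post_stroke``,
    ``discount_rate``, ``productivity_reduction_drug``, ``wtp_per_gdp``.
    """
    out = inputs.clone()
    parts = name.split(".")
    kind = parts[0]
    if kind == "rate" and len(parts) == 3 and (parts[1], parts[2]) in out.rates:
        out.rates[(parts[1], parts[2])] = float(value)
    elif kind == "rr" and len(parts) == 3 and (parts[1], parts[2]) in out.rr:
        out.rr[(parts[1], parts[2])] = float(value)
    elif kind == "progression" and len(parts) == 1:
        out.progression_prob = float(value)
    elif kind == "cost" and len(parts) == 2 and parts[1] in out.costs:
        out.costs[parts[1]] = float(value)
    elif kind == "utility" and len(parts) == 2 and parts[1] in out.utilities:
        out.utilities[parts[1]] = float(value)
    elif kind == "discount_rate" and len(parts) == 1:
        out.discount_rate = float(value)
    elif kind == "productivity_reduction_drug" and len(parts) == 1:
        out.productivity_reduction_drug = float(value)
    elif kind == "wtp_per_gdp" and len(parts) == 1:
        out.wtp_per_gdp = float(value)
    else:
        raise KeyError(f"unknown parameter name {name!r}")
    return out


# ---------------------------------------------------------------------------
# Rate/probability conversion
# ---------------------------------------------------------------------------

def rate_to_prob(rate: float, rr: float = 1.0, cycle_years: float = 1.0) -> float:
    """Convert an event rate per 1000 person-years into a cycle probability.

    Uses the constant-hazard exponential form ``p = 1 - exp(-(rate/1000) * rr
    * t)``; the relative risk multiplies the hazard, which keeps the result in
    [0, 1) for any positive ratio.
    """
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    if cycle_years <= 0:
        raise ValueError(f"cycle length must be positive, got {cycle_years}")
    return -math.expm1(-(rate / 1000.0) * rr * cycle_years)


def prob_to_hazard(p: float) -> float:
    """Inverse of the exponential conversion: annual hazard for probability ``p``."""
    if not 0 <= p < 1:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    return -math.log1p(-p)


# ---------------------------------------------------------------------------
# Sampling distributions for the probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution.

    family ``beta``: a, b are the shape parameters.
    family ``gamma``: a is the shape, b the scale.
    family ``lognormal``: a is the log-scale mean (mu), b the log-scale sd.
    family ``point``: a is the value (degenerate mass).
    """

    family: Literal["beta", "gamma", "lognormal", "point"]
    a: float
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.family == "beta" and not (self.a > 0 and self.b > 0):
            raise ValueError("beta parameters must be positive")
        if self.family == "gamma" and not (self.a > 0 and self.b > 0):
            raise ValueError("gamma shape and scale must be positive")
        if self.family == "lognormal" and self.b < 0:
            raise ValueError("lognormal sigma must be nonnegative")

    def mean(self) -> float:
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.a * self.b
        if self.family == "lognormal":
            return math.exp(self.a + self.b**2 / 2)
        return self.a

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size=size)
        if self.family == "lognormal":
            return rng.lognormal(self.a, self.b, size=size)
        if size is None:
            return self.a
        return np.full(size, self.a)


def fit_beta_from_interval(mean: float, lo: float, hi: float) -> DistributionSpec:
    """Fit a beta distribution with the given mean whose central 95% interval
    best matches ``(lo, hi)`` in the least-squares sense.

    The mean constraint fixes ``b = a * (1 - mean) / mean``, leaving a
    one-dimensional search over ``a`` (performed on the log scale).  A
    degenerate interval collapses to a point mass.
    """
    if not 0 < mean < 1:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    if hi - lo < 1e-12:
        return DistributionSpec("point", mean)
    if not (0 <= lo < mean < hi <= 1):
        raise ValueError(
            f"interval must satisfy 0 <= lo < mean < hi <= 1, got "
            f"lo={lo}, mean={mean}, hi={hi}"
        )

    def loss(log_a: float) -> float:
        a = math.exp(log_a)
        b = a * (1 - mean) / mean
        q_lo, q_hi = stats.beta.ppf([0.025, 0.975], a, b)
        return (q_lo - lo) ** 2 + (q_hi - hi) ** 2

    res = optimize.minimize_scalar(
        loss,
        bounds=(math.log(1e-3), math.log(1e9)),
        method="bounded",
        options={"xatol": 1e-9},
    )
    a = math.exp(res.x)
    return DistributionSpec("beta", a, a * (1 - mean) / mean)


def fit_gamma_from_mean_cv(mean: float, cv: float = 0.25) -> DistributionSpec:
    """Method-of-moments gamma: shape = 1/cv^2, scale = mean * cv^2 (exact mean/CV)."""
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if not 0 < cv < 1:
        raise ValueError(f"cv must be in (0, 1), got {cv}")
    return DistributionSpec("gamma", 1.0 / cv**2, mean * cv**2)


def fit_lognormal_from_ci(point: float, lo: float, hi: float) -> DistributionSpec:
    """Lognormal with median at ``point`` and 95% interval width from (lo, hi).

    Standard for ratio measures: sigma = (ln hi - ln lo) / (2 * 1.96).  The
    arithmetic mean of the fitted distribution exceeds the median by the
    factor exp(sigma^2/2), negligible at the interval widths involved here.
    """
    if not 0 < lo <= point <= hi:
        raise ValueError(f"need 0 < lo <= point <= hi, got {lo}, {point}, {hi}")
    if hi - lo < 1e-12:
        return DistributionSpec("point", point)
    sigma = (math.log(hi) - math.log(lo)) / (2 * _Z975)
    return DistributionSpec("lognormal", math.log(point), sigma)


# ---------------------------------------------------------------------------
# File loading
# ---------------------------------------------------------------------------

def default_parameter_path() -> Path:
    """Path of the packaged base-case parameter file."""
    return Path(__file__).resolve().parent / "data" / "table1_base_case.json"


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter file (JSON, or YAML by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)  # JSONDecodeError carries line/column context
    return ParameterSet.model_validate(raw)


def load_default_parameters() -> ParameterSet:
    """The shipped base-case registry (all printed point estimates and ranges)."""
    return load_parameters(default_parameter_path())
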