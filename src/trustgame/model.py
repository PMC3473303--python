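"""Trust-game decision model of clinical-trial participation.

A patient deciding whether to enroll in a randomized controlled trial (RCT)
and the researcher offering it play a trust version of the prisoner's
dilemma.  The patient moves first: *trust* (consent, accepting vulnerability)
or *do not trust* (insist on standard treatment).  A trusting patient's
researcher then either *honors* the trust (enrolls the patient in the RCT,
randomizing to the experimental arm with probability ``r``) or *abuses* it
(administers the unproven experimental treatment outside the trial).

Outcomes carry utilities on a common 0-100 scale, separately for the patient
(``u1``..``u4``) and the researcher (``v1``..``v4``), indexed in the order
experimental success, experimental failure, standard success, standard
failure.  Treatment success is probabilistic: ``e`` for the experimental arm,
``s`` for standard therapy.  Two psychological adjustments enter the payoffs:

* **regret** ``R`` — on a failure branch the patient loses a fraction ``R``
  of the utility gap to the retrospectively best outcome;
* **guilt** ``G`` — on the experimental-failure branch under abuse the
  researcher loses a fraction ``G`` of the researcher-patient utility gap
  ``v2 - u2``.

The module is organised in the order the method runs:

1. domain types and validation;
2. closed-form expected values of the four strategies and the symmetric
   equipoise randomization rule, plus a brute-force tree-enumeration oracle;
3. threshold solvers (critical ``r`` for the researcher, critical ``p`` for
   the patient) and two-way strategy-region sweeps;
4. a Monte Carlo probabilistic-sensitivity engine sampling every parameter
   from configurable distributions and tabulating the 2x2 strategy table;
5. scenario/config file IO and result serialization.

The game is single-shot: no state is carried between :func:`solve_game`
calls.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "PatientChoice",
    "ResearcherChoice",
    "ThresholdDirection",
    "GamePayoffs",
    "GameProbabilities",
    "PsychParams",
    "Scenario",
    "ExpectedValues",
    "StrategyProfile",
    "per_arm_expectations",
    "ev_honor",
    "ev_abuse",
    "ev_no_trust",
    "ev_trust",
    "trust_conditionals",
    "expected_values",
    "equipoise_randomization",
    "solve_game",
    "evaluate_tree_bruteforce",
    "ThresholdResult",
    "researcher_randomization_threshold",
    "patient_trust_threshold",
    "StrategyRegionGrid",
    "sweep_2d",
    "DistributionSpec",
    "MCConfig",
    "MCResult",
    "sample_parameter",
    "run_monte_carlo",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
    "dump_scenario_yaml",
    "mc_config_from_dict",
    "load_mc_config",
]

logger = logging.getLogger("trustgame")

#: Order in which the Monte Carlo engine draws parameters from one RNG
#: stream (parameter-major: the full vector of each parameter is drawn
#: before the next).  Fixed so that runs are reproducible for a given seed.
PARAM_ORDER: Tuple[str, ...] = (
    "u1", "u2", "u3", "u4", "v1", "v2", "v3", "v4",
    "e", "s", "r", "p", "regret", "guilt",
)

_PROBABILITY_PARAMS = ("e", "s", "r", "p", "regret", "guilt")

#: Parameters that may be swept in two-way sensitivity analyses.
SWEEPABLE: Tuple[str, ...] = ("e", "s", "r", "p", "regret", "guilt")


class ValidationError(ValueError):
    """Raised when a parameter violates the model's domain constraints.

    The message always names the offending field.
    """


class PatientChoice(str, enum.Enum):
    TRUST = "TRUST"
    NO_TRUST = "NO_TRUST"


class ResearcherChoice(str, enum.Enum):
    HONOR = "HONOR"
    ABUSE = "ABUSE"


class ThresholdDirection(str, enum.Enum):
    """How a threshold value bounds the favorable region."""

    AT_LEAST = "AT_LEAST"    # strategy favored for variable >= threshold
    LESS_THAN = "LESS_THAN"  # strategy favored for variable < threshold
    ALWAYS = "ALWAYS"        # favored over the whole [0, 1] range
    NEVER = "NEVER"          # never favored


# ---------------------------------------------------------------------------
# 1. Domain types
# ---------------------------------------------------------------------------

def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")


def _require_unit_interval(name: str, value: float) -> None:
    _require_finite(name, value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class GamePayoffs:
    """The eight outcome utilities, on a common (default 0-100) scale.

    ``u1``..``u4`` are the patient's utilities and ``v1``..``v4`` the
    researcher's, in the order: experimental success, experimental failure,
    standard success, standard failure.  The expected orderings are
    ``u1 >= u3 >= u2, u4`` (success beats failure, experimental success is
    the hoped-for best outcome), ``v1 >= v2, v3 >= v4`` and ``v2 >= u2``
    (society still gains knowledge from a failed experiment).  Ordering is
    checked by :meth:`validate`, not at construction, because sensitivity
    analyses deliberately sample payoff sets that may break it.
    """

    u1: float
    u2: float
    u3: float
    u4: float
    v1: float
    v2: float
    v3: float
    v4: float

    def __post_init__(self) -> None:
        for name in ("u1", "u2", "u3", "u4", "v1", "v2", "v3", "v4"):
            _require_finite(name, getattr(self, name))

    def ordering_violations(self) -> List[str]:
        """Return human-readable descriptions of violated payoff orderings."""
        checks = [
            (self.u1 >= self.u3, "u1 >= u3"),
            (self.u3 >= self.u2, "u3 >= u2"),
            (self.u3 >= self.u4, "u3 >= u4"),
            (self.v1 >= self.v2, "v1 >= v2"),
            (self.v1 >= self.v3, "v1 >= v3"),
            (self.v3 >= self.v4, "v3 >= v4"),
            (self.v2 >= self.u2, "v2 >= u2"),
        ]
        return [desc for ok, desc in checks if not ok]

    def validate(self, *, require_ordering: bool = True,
                 allow_negative: bool = False) -> "GamePayoffs":
        if not allow_negative:
            for name in ("u1", "u2", "u3", "u4", "v1", "v2", "v3", "v4"):
                if getattr(self, name) < 0:
                    raise ValidationError(
                        f"{name} must be non-negative on the default utility "
                        f"scale, got {getattr(self, name)!r} "
                        "(pass allow_negative=True to accept)")
        if require_ordering:
            violations = self.ordering_violations()
            if violations:
                raise ValidationError(
                    "payoff ordering violated: " + "; ".join(violations))
        return self


@dataclass(frozen=True)
class GameProbabilities:
    """The four chance/behavior probabilities of the game.

    e: experimental-treatment success probability.
    s: standard-treatment success probability.
    r: randomization probability (allocation to the experimental arm).
    p: probability that the researcher honors the patient's trust.
    """

    e: float
    s: float
    r: float
    p: float

    def __post_init__(self) -> None:
        for name in ("e", "s", "r", "p"):
            _require_unit_interval(name, getattr(self, name))


@dataclass(frozen=True)
class PsychParams:
    """Regret and guilt fractions in [0, 1].

    The baseline model shares one regret fraction between the no-trust and
    abused-trust scenarios; ``regret_no_trust`` / ``regret_abuse`` may be set
    separately when the two regrets should differ (they default to
    ``regret``).
    """

    regret: float
    guilt: float
    regret_no_trust: Optional[float] = None
    regret_abuse: Optional[float] = None

    def __post_init__(self) -> None:
        _require_unit_interval("regret", self.regret)
        _require_unit_interval("guilt", self.guilt)
        if self.regret_no_trust is not None:
            _require_unit_interval("regret_no_trust", self.regret_no_trust)
        if self.regret_abuse is not None:
            _require_unit_interval("regret_abuse", self.regret_abuse)

    @property
    def r_no_trust(self) -> float:
        return self.regret if self.regret_no_trust is None else self.regret_no_trust

    @property
    def r_abuse(self) -> float:
        return self.regret if self.regret_abuse is None else self.regret_abuse


@dataclass(frozen=True)
class Scenario:
    """A fully specified instance of the trust game."""

    payoffs: GamePayoffs
    probs: GameProbabilities
    psych: PsychParams
    label: str = ""

    def validate(self, *, require_ordering: bool = True,
                 allow_negative: bool = False) -> "Scenario":
        self.payoffs.validate(require_ordering=require_ordering,
                              allow_negative=allow_negative)
        return self

    @classmethod
    def table1_baseline(cls) -> "Scenario":
        """The published baseline parameter set of the model.

        Patient utilities (90, 16.3, 84, 16.9), researcher utilities
        (95, 54, 70, 44), e=0.41, s=0.59, r=0.5, p=0.5, regret=guilt=0.2.
        """
        return cls(
            payoffs=GamePayoffs(u1=90.0, u2=16.3, u3=84.0, u4=16.9,
                                v1=95.0, v2=54.0, v3=70.0, v4=44.0),
            probs=GameProbabilities(e=0.41, s=0.59, r=0.5, p=0.5),
            psych=PsychParams(regret=0.2, guilt=0.2),
            label="table1_baseline",
        )

    def replace(self, **params: float) -> "Scenario":
        """Return a copy with named probability/psych parameters replaced."""
        probs = {"e": self.probs.e, "s": self.probs.s,
                 "r": self.probs.r, "p": self.probs.p}
        psych = {"regret": self.psych.regret, "guilt": self.psych.guilt,
                 "regret_no_trust": self.psych.regret_no_trust,
                 "regret_abuse": self.psych.regret_abuse}
        for name, value in params.items():
            if name in probs:
                probs[name] = value
            elif name in psych:
                psych[name] = value
            else:
                raise ValidationError(
                    f"unknown parameter {name!r}; expected one of "
                    f"{sorted(probs) + ['regret', 'guilt']}")
        return dataclasses.replace(
            self, probs=GameProbabilities(**probs), psych=PsychParams(**psych))


@dataclass(frozen=True)
class ExpectedValues:
    """The strategy expected utilities and their per-arm building blocks.

    eu_exp/eu_std are the patient's per-arm expectations E_U[Exp], E_U[Std];
    ev_exp/ev_std the researcher's.  ev_trust_given_honor and
    ev_trust_given_abuse are the patient's conditional trust values.
    """

    eu_exp: float
    eu_std: float
    ev_exp: float
    ev_std: float
    ev_honor: float
    ev_abuse: float
    ev_no_trust: float
    ev_trust_given_honor: float
    ev_trust_given_abuse: float
    ev_trust: float

    def to_dict(self) -> Dict[str, float]:
        return {f.name: float(getattr(self, f.name))
                for f in dataclasses.fields(self)}


@dataclass(frozen=True)
class StrategyProfile:
    """Each player's best response plus the expected values behind it.

    Ties resolve toward cooperation: the patient trusts when
    ``ev_trust >= ev_no_trust`` and the researcher honors when
    ``ev_honor >= ev_abuse``.
    """

    patient_choice: PatientChoice
    researcher_choice: ResearcherChoice
    evs: ExpectedValues

    def to_dict(self) -> Dict[str, object]:
        return {
            "patient_choice": self.patient_choice.value,
            "researcher_choice": self.researcher_choice.value,
            "expected_values": self.evs.to_dict(),
        }


# ---------------------------------------------------------------------------
# 2. Closed-form expected values and the tree oracle
# ---------------------------------------------------------------------------

def _ev_fields(u1, u2, u3, u4, v1, v2, v3, v4, e, s, r, p,
               regret_no_trust, regret_abuse, guilt) -> Dict[str, object]:
    """Closed-form expected values; numpy-broadcasting friendly.

    All ten quantities are plain convex combinations and affine penalty
    terms, so scalars and arrays flow through identically.  This single code
    path backs both :func:`solve_game` and the vectorized Monte Carlo engine.
    """
    eu_exp = e * u1 + (1.0 - e) * u2
    eu_std = s * u3 + (1.0 - s) * u4
    ev_exp = e * v1 + (1.0 - e) * v2
    ev_std = s * v3 + (1.0 - s) * v4
    # Researcher: honor mixes the two arms by the randomization probability;
    # abuse gives the experimental treatment outright, paying a guilt penalty
    # G*(v2 - u2) on the experimental-failure branch only.
    ev_honor_ = r * ev_exp + (1.0 - r) * ev_std
    ev_abuse_ = ev_exp - (1.0 - e) * guilt * (v2 - u2)
    # Patient: refusing the trial yields standard therapy with regret
    # R*(u1 - u4) on the standard-failure branch only.
    ev_no_trust_ = eu_std - (1.0 - s) * regret_no_trust * (u1 - u4)
    tgh = r * eu_exp + (1.0 - r) * eu_std
    tga = eu_exp - (1.0 - e) * regret_abuse * (u3 - u2)
    ev_trust_ = p * tgh + (1.0 - p) * tga
    return {
        "eu_exp": eu_exp, "eu_std": eu_std, "ev_exp": ev_exp, "ev_std": ev_std,
        "ev_honor": ev_honor_, "ev_abuse": ev_abuse_,
        "ev_no_trust": ev_no_trust_,
        "ev_trust_given_honor": tgh, "ev_trust_given_abuse": tga,
        "ev_trust": ev_trust_,
    }


def _scenario_fields(scenario: Scenario) -> Dict[str, float]:
    pay, pr, ps = scenario.payoffs, scenario.probs, scenario.psych
    return _ev_fields(pay.u1, pay.u2, pay.u3, pay.u4,
                      pay.v1, pay.v2, pay.v3, pay.v4,
                      pr.e, pr.s, pr.r, pr.p,
                      ps.r_no_trust, ps.r_abuse, ps.guilt)


def per_arm_expectations(payoffs: GamePayoffs,
                         probs: GameProbabilities) -> Tuple[float, float, float, float]:
    """Per-arm expectations ``(eu_exp, eu_std, ev_exp, ev_std)``.

    ``eu_exp = e*u1 + (1-e)*u2`` and analogously for the other three.
    """
    f = _ev_fields(payoffs.u1, payoffs.u2, payoffs.u3, payoffs.u4,
                   payoffs.v1, payoffs.v2, payoffs.v3, payoffs.v4,
                   probs.e, probs.s, probs.r, probs.p, 0.0, 0.0, 0.0)
    return (float(f["eu_exp"]), float(f["eu_std"]),
            float(f["ev_exp"]), float(f["ev_std"]))


def expected_values(scenario: Scenario) -> ExpectedValues:
    """All closed-form expected values of a scenario."""
    return ExpectedValues(**{k: float(v)
                             for k, v in _scenario_fields(scenario).items()})


def ev_honor(scenario: Scenario) -> float:
    """Researcher's expected utility of honoring trust: ``r*EV[Exp] + (1-r)*EV[Std]``."""
    return float(_scenario_fields(scenario)["ev_honor"])


def ev_abuse(scenario: Scenario) -> float:
    """Researcher's expected utility of abusing trust.

    ``EV[Exp] - (1-e)*G*(v2 - u2)``: the guilt penalty is incurred only when
    the experimental treatment fails.
    """
    return float(_scenario_fields(scenario)["ev_abuse"])


def ev_no_trust(scenario: Scenario) -> float:
    """Patient's expected utility of refusing the trial.

    ``EU[Std] - (1-s)*R*(u1 - u4)``: regret relative to the best outcome
    (experimental success) is felt only when standard therapy fails.
    """
    return float(_scenario_fields(scenario)["ev_no_trust"])


def trust_conditionals(scenario: Scenario) -> Tuple[float, float]:
    """``(E[Trust|Honor], E[Trust|Abuse])`` for the patient."""
    f = _scenario_fields(scenario)
    return float(f["ev_trust_given_honor"]), float(f["ev_trust_given_abuse"])


def ev_trust(scenario: Scenario) -> float:
    """Patient's expected utility of trusting.

    ``p*E[Trust|Honor] + (1-p)*E[Trust|Abuse]`` with
    ``E[Trust|Honor] = r*EU[Exp] + (1-r)*EU[Std]`` and
    ``E[Trust|Abuse] = EU[Exp] - (1-e)*R*(u3 - u2)``.
    """
    return float(_scenario_fields(scenario)["ev_trust"])


def equipoise_randomization(e: float, s: float) -> float:
    """Indifference randomization probability in the symmetric equipoise model.

    When both players value success at 100 and failure at 0 and feel no
    regret or guilt, the patient is indifferent between arms at
    ``r = s / (s + e)``, which is exactly 0.5 under equipoise (``e == s``).
    """
    _require_unit_interval("e", e)
    _require_unit_interval("s", s)
    if e == 0.0 and s == 0.0:
        raise ValidationError(
            "e and s cannot both be 0: the equipoise randomization "
            "probability s/(s+e) is undefined")
    if e == s:
        return 0.5
    return s / (s + e)


def solve_game(scenario: Scenario) -> StrategyProfile:
    """Best response of each player by direct expected-value comparison.

    Deterministic for fixed inputs; ties resolve toward TRUST and HONOR.
    """
    evs = expected_values(scenario)
    patient = (PatientChoice.TRUST if evs.ev_trust >= evs.ev_no_trust
               else PatientChoice.NO_TRUST)
    researcher = (ResearcherChoice.HONOR if evs.ev_honor >= evs.ev_abuse
                  else ResearcherChoice.ABUSE)
    return StrategyProfile(patient, researcher, evs)


def evaluate_tree_bruteforce(scenario: Scenario) -> ExpectedValues:
    """Evaluate the game by explicit leaf enumeration of the decision tree.

    Independent oracle for the closed forms: every root-to-leaf path is
    listed with its chance probability and its regret/guilt-adjusted leaf
    payoff, and each strategy's expected value is the probability-weighted
    sum over its paths.  No algebraic simplification is shared with
    :func:`_ev_fields`.
    """
    pay, pr, ps = scenario.payoffs, scenario.probs, scenario.psych
    e, s, r, p = pr.e, pr.s, pr.r, pr.p

    def total(paths: Iterable[Tuple[float, float]]) -> float:
        return math.fsum(prob * payoff for prob, payoff in paths)

    # Patient, "do not trust": standard therapy chance node.  On failure the
    # patient regrets the gap to the best imaginable outcome (u1).
    no_trust_paths = [
        (s, pay.u3),
        (1.0 - s, pay.u4 - ps.r_no_trust * (pay.u1 - pay.u4)),
    ]

    # Patient, "trust", researcher honors: randomization then outcome.
    trust_honor_paths = [
        (r * e, pay.u1),
        (r * (1.0 - e), pay.u2),
        ((1.0 - r) * s, pay.u3),
        ((1.0 - r) * (1.0 - s), pay.u4),
    ]
    # Patient, "trust", researcher abuses: experimental treatment outside the
    # trial; on failure the patient regrets forgoing standard therapy (u3).
    trust_abuse_paths = [
        (e, pay.u1),
        (1.0 - e, pay.u2 - ps.r_abuse * (pay.u3 - pay.u2)),
    ]
    trust_paths = ([(p * prob, u) for prob, u in trust_honor_paths]
                   + [((1.0 - p) * prob, u) for prob, u in trust_abuse_paths])

    # Researcher, "honor": randomization then outcome, researcher utilities.
    honor_paths = [
        (r * e, pay.v1),
        (r * (1.0 - e), pay.v2),
        ((1.0 - r) * s, pay.v3),
        ((1.0 - r) * (1.0 - s), pay.v4),
    ]
    # Researcher, "abuse": guilt is felt on the experimental-failure branch.
    abuse_paths = [
        (e, pay.v1),
        (1.0 - e, pay.v2 - ps.guilt * (pay.v2 - pay.u2)),
    ]

    return ExpectedValues(
        eu_exp=total([(e, pay.u1), (1.0 - e, pay.u2)]),
        eu_std=total([(s, pay.u3), (1.0 - s, pay.u4)]),
        ev_exp=total([(e, pay.v1), (1.0 - e, pay.v2)]),
        ev_std=total([(s, pay.v3), (1.0 - s, pay.v4)]),
        ev_honor=total(honor_paths),
        ev_abuse=total(abuse_paths),
        ev_no_trust=total(no_trust_paths),
        ev_trust_given_honor=total(trust_honor_paths),
        ev_trust_given_abuse=total(trust_abuse_paths),
        ev_trust=total(trust_paths),
    )


# ---------------------------------------------------------------------------
# 3. Threshold solvers and two-way sensitivity sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdResult:
    """Critical value of a behavior probability (``r`` or ``p``).

    ``threshold`` is clamped to [0, 1]; ``raw_threshold`` keeps the
    pre-clamp solution of the affine inequality.  ``ALWAYS`` / ``NEVER``
    results carry no threshold.
    """

    variable: str
    direction: ThresholdDirection
    threshold: Optional[float]
    raw_threshold: Optional[float]
    scenario: Scenario

    @property
    def percent(self) -> Optional[int]:
        """Threshold rounded to a whole percent, for display."""
        if self.threshold is None:
            return None
        return int(round(self.threshold * 100.0))

    def to_dict(self) -> Dict[str, object]:
        return {
            "variable": self.variable,
            "direction": self.direction.value,
            "threshold": None if self.threshold is None else float(self.threshold),
            "raw_threshold": (None if self.raw_threshold is None
                              else float(self.raw_threshold)),
            "percent": self.percent,
        }


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def researcher_randomization_threshold(scenario: Scenario) -> ThresholdResult:
    """Critical randomization probability r* for honoring trust.

    Honoring beats abusing when ``r*(EV[Exp]-EV[Std]) >= (EV[Exp]-EV[Std])
    - (1-e)*G*(v2-u2)``.  With ``EV[Exp] > EV[Std]`` the researcher honors
    for ``r >= t`` with ``t = 1 - (1-e)*G*(v2-u2)/(EV[Exp]-EV[Std])``; with
    ``EV[Exp] < EV[Std]`` the inequality flips and honoring holds for
    ``r < t``.  When the two arm expectations coincide the comparison no
    longer involves r and honoring weakly dominates iff the guilt term is
    non-negative.
    """
    f = _scenario_fields(scenario)
    pay, pr, ps = scenario.payoffs, scenario.probs, scenario.psych
    gap = f["ev_exp"] - f["ev_std"]
    guilt_term = (1.0 - pr.e) * ps.guilt * (pay.v2 - pay.u2)
    if gap == 0.0:
        direction = (ThresholdDirection.ALWAYS if guilt_term >= 0.0
                     else ThresholdDirection.NEVER)
        return ThresholdResult("r", direction, None, None, scenario)
    raw = 1.0 - guilt_term / gap
    direction = (ThresholdDirection.AT_LEAST if gap > 0.0
                 else ThresholdDirection.LESS_THAN)
    return ThresholdResult("r", direction, _clamp01(raw), raw, scenario)


def patient_trust_threshold(scenario: Scenario) -> ThresholdResult:
    """Critical honor probability p* for the patient to trust.

    ``E[Trust]`` is affine in p: ``E[Trust] = E[Trust|Abuse] + p*slope`` with
    ``slope = (1-r)*(EU[Std]-EU[Exp]) + (1-e)*R*(u3-u2)``.  Trust beats
    no-trust when ``p*slope >= gap`` where
    ``gap = E[NoTrust] - E[Trust|Abuse]``.  A positive slope gives an
    AT_LEAST threshold ``gap/slope``, a negative slope a LESS_THAN one, and
    a zero slope makes the comparison independent of p (ALWAYS/NEVER).
    """
    f = _scenario_fields(scenario)
    slope = f["ev_trust_given_honor"] - f["ev_trust_given_abuse"]
    gap = f["ev_no_trust"] - f["ev_trust_given_abuse"]
    if slope == 0.0:
        direction = (ThresholdDirection.ALWAYS if gap <= 0.0
                     else ThresholdDirection.NEVER)
        return ThresholdResult("p", direction, None, None, scenario)
    raw = gap / slope
    direction = (ThresholdDirection.AT_LEAST if slope > 0.0
                 else ThresholdDirection.LESS_THAN)
    return ThresholdResult("p", direction, _clamp01(raw), raw, scenario)


@dataclass(frozen=True)
class StrategyRegionGrid:
    """Best-response pair of both players over a 2-D parameter grid.

    ``patient`` and ``researcher`` are ``(len(y_values), len(x_values))``
    arrays of choice codes; the four ``ev_*`` arrays carry the strategy
    expected values cell by cell.  Cell (i, j) is the game solved at
    ``x = x_values[j]``, ``y = y_values[i]`` with all other parameters taken
    from ``base``.
    """

    base: Scenario
    x_variable: str
    y_variable: str
    x_values: np.ndarray
    y_values: np.ndarray
    patient: np.ndarray
    researcher: np.ndarray
    ev_trust: np.ndarray
    ev_no_trust: np.ndarray
    ev_honor: np.ndarray
    ev_abuse: np.ndarray

    def profile_at(self, ix: int, iy: int) -> Tuple[PatientChoice, ResearcherChoice]:
        return (PatientChoice(self.patient[iy, ix]),
                ResearcherChoice(self.researcher[iy, ix]))

    def cell_nearest(self, x: float, y: float) -> Tuple[PatientChoice, ResearcherChoice]:
        ix = int(np.argmin(np.abs(self.x_values - x)))
        iy = int(np.argmin(np.abs(self.y_values - y)))
        return self.profile_at(ix, iy)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per grid cell."""
        xs, ys = np.meshgrid(self.x_values, self.y_values)
        return pd.DataFrame({
            "x_variable": self.x_variable,
            "y_variable": self.y_variable,
            "x": xs.ravel(),
            "y": ys.ravel(),
            "patient_choice": self.patient.ravel(),
            "researcher_choice": self.researcher.ravel(),
            "ev_trust": self.ev_trust.ravel(),
            "ev_no_trust": self.ev_no_trust.ravel(),
            "ev_honor": self.ev_honor.ravel(),
            "ev_abuse": self.ev_abuse.ravel(),
        })

    def plot(self, ax=None):
        """Render the four strategy regions as a categorical heatmap."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        code = ((self.patient == PatientChoice.TRUST.value).astype(int) * 2
                + (self.researcher == ResearcherChoice.HONOR.value).astype(int))
        extent = (float(self.x_values[0]), float(self.x_values[-1]),
                  float(self.y_values[0]), float(self.y_values[-1]))
        im = ax.imshow(code, origin="lower", extent=extent, aspect="auto",
                       vmin=0, vmax=3, cmap="viridis")
        ax.set_xlabel(self.x_variable)
        ax.set_ylabel(self.y_variable)
        cbar = ax.figure.colorbar(im, ax=ax, ticks=[0, 1, 2, 3])
        cbar.ax.set_yticklabels([
            "no-trust / abuse", "no-trust / honor",
            "trust / abuse", "trust / honor"])
        return ax


def sweep_2d(base: Scenario, x_variable: str, y_variable: str,
             x_range: Tuple[float, float] = (0.0, 1.0),
             y_range: Tuple[float, float] = (0.0, 1.0),
             n_steps: int = 101) -> StrategyRegionGrid:
    """Solve the game over an ``n_steps`` x ``n_steps`` grid of two parameters.

    ``x_variable`` and ``y_variable`` must be distinct members of
    ``SWEEPABLE`` (e, s, r, p, regret, guilt); both ranges must lie in
    [0, 1].  The default 101-point grid resolves one-percentage-point
    features of the strategy regions.
    """
    for name in (x_variable, y_variable):
        if name not in SWEEPABLE:
            raise ValidationError(
                f"unknown sweep variable {name!r}; valid names: "
                f"{', '.join(SWEEPABLE)}")
    if x_variable == y_variable:
        raise ValidationError(
            f"x_variable and y_variable must differ, both are {x_variable!r}")
    if n_steps < 2:
        raise ValidationError(f"n_steps must be >= 2, got {n_steps}")
    for rng_name, (lo, hi) in (("x_range", x_range), ("y_range", y_range)):
        if not (0.0 <= lo < hi <= 1.0):
            raise ValidationError(
                f"{rng_name} must satisfy 0 <= low < high <= 1, got {(lo, hi)}")

    x_values = np.linspace(x_range[0], x_range[1], n_steps)
    y_values = np.linspace(y_range[0], y_range[1], n_steps)
    shape = (n_steps, n_steps)
    patient = np.empty(shape, dtype=object)
    researcher = np.empty(shape, dtype=object)
    evt = np.empty(shape)
    evnt = np.empty(shape)
    evh = np.empty(shape)
    eva = np.empty(shape)
    for iy, yv in enumerate(y_values):
        for ix, xv in enumerate(x_values):
            prof = solve_game(base.replace(**{x_variable: float(xv),
                                              y_variable: float(yv)}))
            patient[iy, ix] = prof.patient_choice.value
            researcher[iy, ix] = prof.researcher_choice.value
            evt[iy, ix] = prof.evs.ev_trust
            evnt[iy, ix] = prof.evs.ev_no_trust
            evh[iy, ix] = prof.evs.ev_honor
            eva[iy, ix] = prof.evs.ev_abuse
    return StrategyRegionGrid(base, x_variable, y_variable, x_values, y_values,
                              patient.astype(str), researcher.astype(str),
                              evt, evnt, evh, eva)


# ---------------------------------------------------------------------------
# 4. Monte Carlo probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution for one model parameter.

    Kinds: ``fixed(value)``, ``triangular(mode, low, high)``,
    ``uniform(low, high)`` and ``binomial_proportion(p0, n)`` — the last
    draws k ~ Binomial(n, p0) and returns k/n, the sampling distribution of
    an observed success proportion from n trials.
    """

    kind: str
    value: Optional[float] = None
    mode: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    p0: Optional[float] = None
    n: Optional[int] = None

    _KINDS = ("fixed", "triangular", "uniform", "binomial_proportion")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValidationError(
                f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.kind == "fixed":
            if self.value is None:
                raise ValidationError("fixed distribution requires 'value'")
            _require_finite("value", self.value)
        elif self.kind == "triangular":
            for name in ("mode", "low", "high"):
                if getattr(self, name) is None:
                    raise ValidationError(
                        f"triangular distribution requires {name!r}")
                _require_finite(name, getattr(self, name))
            if not self.low <= self.mode <= self.high:
                raise ValidationError(
                    f"triangular requires low <= mode <= high, got "
                    f"({self.low}, {self.mode}, {self.high})")
            if self.low == self.high:
                raise ValidationError(
                    "triangular requires low < high (use 'fixed' for a "
                    "degenerate distribution)")
        elif self.kind == "uniform":
            for name in ("low", "high"):
                if getattr(self, name) is None:
                    raise ValidationError(
                        f"uniform distribution requires {name!r}")
                _require_finite(name, getattr(self, name))
            if not self.low < self.high:
                raise ValidationError(
                    f"uniform requires low < high, got ({self.low}, {self.high})")
        else:  # binomial_proportion
            if self.p0 is None or self.n is None:
                raise ValidationError(
                    "binomial_proportion distribution requires 'p0' and 'n'")
            _require_unit_interval("p0", self.p0)
            if int(self.n) != self.n or self.n < 1:
                raise ValidationError(f"n must be an integer >= 1, got {self.n!r}")

    # -- constructors -------------------------------------------------------
    @classmethod
    def fixed(cls, value: float) -> "DistributionSpec":
        return cls("fixed", value=value)

    @classmethod
    def triangular(cls, mode: float, low: float, high: float) -> "DistributionSpec":
        return cls("triangular", mode=mode, low=low, high=high)

    @classmethod
    def uniform(cls, low: float, high: float) -> "DistributionSpec":
        return cls("uniform", low=low, high=high)

    @classmethod
    def binomial_proportion(cls, p0: float, n: int) -> "DistributionSpec":
        return cls("binomial_proportion", p0=p0, n=int(n))

    # -- sampling -----------------------------------------------------------
    def sample(self, rng: np.random.Generator,
               size: Optional[int] = None) -> Union[float, np.ndarray]:
        if self.kind == "fixed":
            return (self.value if size is None
                    else np.full(size, self.value, dtype=float))
        if self.kind == "triangular":
            return rng.triangular(self.low, self.mode, self.high, size)
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size)
        return rng.binomial(int(self.n), self.p0, size) / float(self.n)

    def support(self) -> Tuple[float, float]:
        if self.kind == "fixed":
            return (self.value, self.value)
        if self.kind == "binomial_proportion":
            return (0.0, 1.0)
        return (self.low, self.high)

    def to_dict(self) -> Dict[str, object]:
        out: Dict[str, object] = {"kind": self.kind}
        for name in ("value", "mode", "low", "high", "p0", "n"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "DistributionSpec":
        if "kind" not in d:
            raise ValidationError("distribution spec missing 'kind'")
        known = {"kind", "value", "mode", "low", "high", "p0", "n"}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(
                f"unknown distribution spec keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items()})


@dataclass(frozen=True)
class MCConfig:
    """Configuration of one probabilistic-sensitivity run.

    ``specs`` maps every parameter in ``PARAM_ORDER`` to a distribution.
    When ``enforce_payoff_invariants`` is set, utility draws violating the
    payoff orderings are rejected and resampled; by default draws are
    accepted as-is so that each parameter keeps exactly its declared
    marginal distribution.
    """

    specs: Mapping[str, DistributionSpec]
    n_trials: int = 100_000
    seed: Optional[int] = None
    enforce_payoff_invariants: bool = False

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValidationError(f"n_trials must be >= 1, got {self.n_trials}")
        missing = [k for k in PARAM_ORDER if k not in self.specs]
        if missing:
            raise ValidationError(f"missing distribution specs for: {missing}")
        extra = [k for k in self.specs if k not in PARAM_ORDER]
        if extra:
            raise ValidationError(f"unknown parameters in specs: {extra}")

    @classmethod
    def table1_default(cls, n_trials: int = 100_000, seed: Optional[int] = None,
                       p_dist: str = "uniform",
                       enforce_payoff_invariants: bool = False) -> "MCConfig":
        """The published distribution set for all fourteen parameters.

        Triangular distributions on every utility (mode = baseline value,
        range as elicited), success probabilities as observed proportions of
        meta-analytic trial counts (e: n=450, s: n=316), triangular
        randomization probability, and regret/guilt triangular over [0, 1].
        The honor probability p defaults to Uniform(0, 1), the only
        parameter published without a distribution annotation;
        ``p_dist="triangular"`` selects triangular(0.5; 0-1) instead.
        """
        tri = DistributionSpec.triangular
        if p_dist == "uniform":
            p_spec = DistributionSpec.uniform(0.0, 1.0)
        elif p_dist == "triangular":
            p_spec = tri(0.5, 0.0, 1.0)
        else:
            raise ValidationError(
                f"p_dist must be 'uniform' or 'triangular', got {p_dist!r}")
        specs = {
            "u1": tri(90.0, 50.0, 100.0),
            "u2": tri(16.3, 0.0, 50.0),
            "u3": tri(84.0, 50.0, 100.0),
            "u4": tri(16.9, 0.0, 50.0),
            "v1": tri(95.0, 80.0, 100.0),
            "v2": tri(54.0, 10.0, 100.0),
            "v3": tri(70.0, 40.0, 80.0),
            "v4": tri(44.0, 0.0, 80.0),
            "e": DistributionSpec.binomial_proportion(0.41, 450),
            "s": DistributionSpec.binomial_proportion(0.59, 316),
            "r": tri(0.5, 0.2, 0.8),
            "p": p_spec,
            "regret": tri(0.2, 0.0, 1.0),
            "guilt": tri(0.2, 0.0, 1.0),
        }
        return cls(specs=specs, n_trials=n_trials, seed=seed,
                   enforce_payoff_invariants=enforce_payoff_invariants)

    @classmethod
    def all_fixed(cls, scenario: Scenario, n_trials: int = 1,
                  seed: Optional[int] = None) -> "MCConfig":
        """Degenerate config putting all mass on one scenario."""
        pay, pr, ps = scenario.payoffs, scenario.probs, scenario.psych
        values = {"u1": pay.u1, "u2": pay.u2, "u3": pay.u3, "u4": pay.u4,
                  "v1": pay.v1, "v2": pay.v2, "v3": pay.v3, "v4": pay.v4,
                  "e": pr.e, "s": pr.s, "r": pr.r, "p": pr.p,
                  "regret": ps.regret, "guilt": ps.guilt}
        return cls(specs={k: DistributionSpec.fixed(v) for k, v in values.items()},
                   n_trials=n_trials, seed=seed)

    def to_dict(self) -> Dict[str, object]:
        return {
            "distributions": {k: self.specs[k].to_dict() for k in PARAM_ORDER},
            "n_trials": self.n_trials,
            "seed": self.seed,
            "enforce_payoff_invariants": self.enforce_payoff_invariants,
        }


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator,
                     size: Optional[int] = None) -> Union[float, np.ndarray]:
    """Draw from a distribution spec (thin wrapper over ``spec.sample``)."""
    return spec.sample(rng, size)


_ORDER_CHECKS = (("u1", "u3"), ("u3", "u2"), ("u3", "u4"),
                 ("v1", "v2"), ("v1", "v3"), ("v3", "v4"), ("v2", "u2"))
_UTILITY_PARAMS = ("u1", "u2", "u3", "u4", "v1", "v2", "v3", "v4")


@dataclass(frozen=True)
class MCResult:
    """2x2 contingency table of best strategies over Monte Carlo trials.

    ``counts`` rows index the researcher's choice (HONOR, ABUSE) and columns
    the patient's (TRUST, NO_TRUST); the four cells sum to ``n_trials``.
    """

    counts: np.ndarray
    n_trials: int
    seed: Optional[int]
    config: MCConfig
    draws: Optional[pd.DataFrame] = None

    ROWS = (ResearcherChoice.HONOR, ResearcherChoice.ABUSE)
    COLS = (PatientChoice.TRUST, PatientChoice.NO_TRUST)

    def count(self, researcher: ResearcherChoice, patient: PatientChoice) -> int:
        return int(self.counts[self.ROWS.index(researcher),
                               self.COLS.index(patient)])

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / float(self.n_trials)

    @property
    def honor_rate(self) -> float:
        """Marginal proportion of trials where honoring is the researcher's best strategy."""
        return float(self.counts[0].sum()) / self.n_trials

    @property
    def trust_rate(self) -> float:
        """Marginal proportion of trials where trusting is the patient's best strategy."""
        return float(self.counts[:, 0].sum()) / self.n_trials

    @property
    def cooperation_rate(self) -> float:
        """Joint proportion of full cooperation (HONOR and TRUST)."""
        return float(self.counts[0, 0]) / self.n_trials

    def to_dict(self) -> Dict[str, object]:
        props = self.proportions
        return {
            "n_trials": self.n_trials,
            "seed": self.seed,
            "counts": {
                row.value: {col.value: int(self.counts[i, j])
                            for j, col in enumerate(self.COLS)}
                for i, row in enumerate(self.ROWS)
            },
            "proportions": {
                row.value: {col.value: float(props[i, j])
                            for j, col in enumerate(self.COLS)}
                for i, row in enumerate(self.ROWS)
            },
            "marginals": {
                "HONOR": self.honor_rate,
                "ABUSE": 1.0 - self.honor_rate,
                "TRUST": self.trust_rate,
                "NO_TRUST": 1.0 - self.trust_rate,
            },
            "cooperation_rate": self.cooperation_rate,
            "config": self.config.to_dict(),
        }

    def to_frame(self) -> pd.DataFrame:
        """One row per cell plus marginal rows."""
        rows = []
        for i, row in enumerate(self.ROWS):
            for j, col in enumerate(self.COLS):
                rows.append({"researcher": row.value, "patient": col.value,
                             "count": int(self.counts[i, j]),
                             "proportion": float(self.proportions[i, j])})
        rows.append({"researcher": "HONOR", "patient": "(any)",
                     "count": int(self.counts[0].sum()),
                     "proportion": self.honor_rate})
        rows.append({"researcher": "(any)", "patient": "TRUST",
                     "count": int(self.counts[:, 0].sum()),
                     "proportion": self.trust_rate})
        return pd.DataFrame(rows)


def _resample_ordering_violations(draws: Dict[str, np.ndarray],
                                  config: MCConfig,
                                  rng: np.random.Generator,
                                  max_rounds: int = 1000) -> None:
    """Redraw all eight utilities for rows violating the payoff orderings."""
    for _ in range(max_rounds):
        bad = np.zeros(config.n_trials, dtype=bool)
        for hi, lo in _ORDER_CHECKS:
            bad |= draws[hi] < draws[lo]
        n_bad = int(bad.sum())
        if n_bad == 0:
            return
        for name in _UTILITY_PARAMS:
            draws[name][bad] = np.asarray(
                config.specs[name].sample(rng, n_bad), dtype=float)
    raise ValidationError(
        "enforce_payoff_invariants: could not satisfy payoff orderings "
        f"after {max_rounds} resampling rounds; the configured utility "
        "distributions are incompatible with the ordering constraints")


def run_monte_carlo(config: MCConfig, *, keep_draws: bool = False) -> MCResult:
    """Sample all parameters, solve the game per trial, tabulate strategies.

    One seeded generator stream drives the whole run; parameters are drawn
    parameter-major in ``PARAM_ORDER`` so results are reproducible for a
    given seed.  Sampled probabilities are clamped to [0, 1].  Per-trial
    strategies come from the same closed forms as :func:`solve_game`
    (ties toward TRUST/HONOR), evaluated vectorized.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    draws: Dict[str, np.ndarray] = {}
    for name in PARAM_ORDER:
        draws[name] = np.asarray(config.specs[name].sample(rng, n), dtype=float)
    for name in _PROBABILITY_PARAMS:
        np.clip(draws[name], 0.0, 1.0, out=draws[name])
    if config.enforce_payoff_invariants:
        _resample_ordering_violations(draws, config, rng)

    f = _ev_fields(draws["u1"], draws["u2"], draws["u3"], draws["u4"],
                   draws["v1"], draws["v2"], draws["v3"], draws["v4"],
                   draws["e"], draws["s"], draws["r"], draws["p"],
                   draws["regret"], draws["regret"], draws["guilt"])
    honor = f["ev_honor"] >= f["ev_abuse"]
    trust = f["ev_trust"] >= f["ev_no_trust"]
    counts = np.array([
        [int(np.sum(honor & trust)), int(np.sum(honor & ~trust))],
        [int(np.sum(~honor & trust)), int(np.sum(~honor & ~trust))],
    ], dtype=np.int64)

    frame = None
    if keep_draws:
        frame = pd.DataFrame({k: draws[k] for k in PARAM_ORDER})
        frame["researcher_choice"] = np.where(
            honor, ResearcherChoice.HONOR.value, ResearcherChoice.ABUSE.value)
        frame["patient_choice"] = np.where(
            trust, PatientChoice.TRUST.value, PatientChoice.NO_TRUST.value)

    logger.info("monte carlo: n_trials=%d seed=%s honor=%.4f trust=%.4f "
                "cooperation=%.4f", n, config.seed,
                counts[0].sum() / n, counts[:, 0].sum() / n, counts[0, 0] / n)
    return MCResult(counts=counts, n_trials=n, seed=config.seed,
                    config=config, draws=frame)


# ---------------------------------------------------------------------------
# 5. Scenario / config IO
# ---------------------------------------------------------------------------

_SCENARIO_SECTIONS = {
    "payoffs": ("u1", "u2", "u3", "u4", "v1", "v2", "v3", "v4"),
    "probabilities": ("e", "s", "r", "p"),
    "psych": ("regret", "guilt"),
}
_PSYCH_OPTIONAL = ("regret_no_trust", "regret_abuse")


def scenario_to_dict(scenario: Scenario) -> Dict[str, object]:
    pay, pr, ps = scenario.payoffs, scenario.probs, scenario.psych
    psych: Dict[str, float] = {"regret": ps.regret, "guilt": ps.guilt}
    if ps.regret_no_trust is not None:
        psych["regret_no_trust"] = ps.regret_no_trust
    if ps.regret_abuse is not None:
        psych["regret_abuse"] = ps.regret_abuse
    return {
        "payoffs": {k: getattr(pay, k) for k in _SCENARIO_SECTIONS["payoffs"]},
        "probabilities": {k: getattr(pr, k)
                          for k in _SCENARIO_SECTIONS["probabilities"]},
        "psych": psych,
        "label": scenario.label,
    }


def scenario_from_dict(data: Mapping[str, object]) -> Scenario:
    """Build a scenario from a parsed config mapping; strict about keys."""
    if not isinstance(data, Mapping):
        raise ValidationError("scenario config must be a mapping")
    unknown = set(data) - set(_SCENARIO_SECTIONS) - {"label"}
    if unknown:
        raise ValidationError(f"unknown config sections: {sorted(unknown)}")
    parsed: Dict[str, Dict[str, float]] = {}
    for section, keys in _SCENARIO_SECTIONS.items():
        if section not in data:
            raise ValidationError(f"missing config section {section!r}")
        block = data[section]
        if not isinstance(block, Mapping):
            raise ValidationError(f"section {section!r} must be a mapping")
        allowed = set(keys) | (set(_PSYCH_OPTIONAL) if section == "psych" else set())
        unknown = set(block) - allowed
        if unknown:
            raise ValidationError(
                f"unknown keys in section {section!r}: {sorted(unknown)}")
        for key in keys:
            if key not in block:
                raise ValidationError(
                    f"missing field {key!r} in section {section!r}")
        parsed[section] = {k: float(v) for k, v in block.items()}
    return Scenario(
        payoffs=GamePayoffs(**parsed["payoffs"]),
        probs=GameProbabilities(**parsed["probabilities"]),
        psych=PsychParams(**parsed["psych"]),
        label=str(data.get("label", "")),
    )


BUILTIN_PREFIX = "builtin:"
_BUILTIN_SCENARIOS = {"table1_baseline": Scenario.table1_baseline}


def load_scenario(source: str) -> Scenario:
    """Load a scenario from a YAML file path or a ``builtin:`` name."""
    if source.startswith(BUILTIN_PREFIX):
        name = source[len(BUILTIN_PREFIX):]
        if name not in _BUILTIN_SCENARIOS:
            raise ValidationError(
                f"unknown builtin scenario {name!r}; available: "
                f"{sorted(_BUILTIN_SCENARIOS)}")
        return _BUILTIN_SCENARIOS[name]()
    try:
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ValidationError(f"scenario config not found: {source}") from None
    except yaml.YAMLError as exc:
        raise ValidationError(f"could not parse {source}: {exc}") from None
    return scenario_from_dict(data or {})


def dump_scenario_yaml(scenario: Scenario) -> str:
    return yaml.safe_dump(scenario_to_dict(scenario), sort_keys=True)


def baseline_scenario_path() -> str:
    """Filesystem path of the bundled baseline scenario config."""
    return str(resources.files("trustgame").joinpath("data/table1_baseline.yaml"))


def mc_config_from_dict(data: Mapping[str, object]) -> MCConfig:
    """Build an MC config from a parsed mapping.

    Only the ``distributions`` entries present are overridden; absent
    parameters keep the default distribution set.
    """
    if not isinstance(data, Mapping):
        raise ValidationError("mc config must be a mapping")
    known = {"distributions", "n_trials", "seed", "enforce_payoff_invariants",
             "p_dist"}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown mc config keys: {sorted(unknown)}")
    default = MCConfig.table1_default(
        n_trials=int(data.get("n_trials", 100_000)),
        seed=data.get("seed"),
        p_dist=str(data.get("p_dist", "uniform")),
        enforce_payoff_invariants=bool(data.get("enforce_payoff_invariants",
                                                False)))
    overrides = data.get("distributions", {}) or {}
    if not isinstance(overrides, Mapping):
        raise ValidationError("'distributions' must be a mapping")
    specs = dict(default.specs)
    for name, spec in overrides.items():
        if name not in PARAM_ORDER:
            raise ValidationError(
                f"unknown parameter {name!r} in distributions; valid: "
                f"{', '.join(PARAM_ORDER)}")
        specs[name] = DistributionSpec.from_dict(spec)
    return dataclasses.replace(default, specs=specs)


def load_mc_config(path: str) -> MCConfig:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ValidationError(f"mc config not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ValidationError(f"could not parse {path}: {exc}") from None
    return mc_config_from_dict(data or {})


def to_json(obj: Mapping[str, object], **kwargs: object) -> str:
    """Serialize a result mapping to JSON with stable key order."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, enum.Enum):
            return o.value
        raise TypeError(f"not JSON serializable: {type(o)!r}")

    kwargs.setdefault("sort_keys", True)
    kwargs.setdefault("indent", 2)
    return json.dumps(obj, default=_default, **kwargs)
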