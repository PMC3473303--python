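"""Closed-form expected values, the tree oracle, and their invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trustgame as tg
from conftest import make_random_scenario

unit = st.floats(0.0, 1.0, allow_nan=False)
utility = st.floats(0.0, 100.0, allow_nan=False)

EV_FIELDS = [f.name for f in dataclasses.fields(tg.ExpectedValues)]


# -- per-arm expectations ----------------------------------------------------

def test_per_arm_expectations_baseline(baseline):
    """Hand-computed convex combinations of the baseline utilities."""
    eu_exp, eu_std, ev_exp, ev_std = tg.per_arm_expectations(
        baseline.payoffs, baseline.probs)
    assert eu_exp == pytest.approx(46.517, abs=1e-9)
    assert eu_std == pytest.approx(56.489, abs=1e-9)
    assert ev_exp == pytest.approx(70.81, abs=1e-9)
    assert ev_std == pytest.approx(59.34, abs=1e-9)


@pytest.mark.parametrize("e, expected", [(1.0, 90.0), (0.0, 16.3)])
def test_per_arm_degenerate_probability(baseline, e, expected):
    probs = dataclasses.replace(baseline.probs, e=e)
    eu_exp, *_ = tg.per_arm_expectations(baseline.payoffs, probs)
    assert eu_exp == expected


def test_per_arm_constant_payoff(baseline):
    payoffs = dataclasses.replace(baseline.payoffs, u1=42.0, u2=42.0)
    for e in (0.0, 0.3, 0.77, 1.0):
        probs = dataclasses.replace(baseline.probs, e=e)
        assert tg.per_arm_expectations(payoffs, probs)[0] == pytest.approx(42.0)


# -- strategy expected values at the baseline --------------------------------

@pytest.mark.parametrize("func, expected", [
    (tg.ev_honor, 65.075),
    (tg.ev_abuse, 66.3614),
    (tg.ev_no_trust, 50.4948),
    (tg.ev_trust, 45.0157),
])
def test_strategy_evs_baseline(baseline, func, expected):
    """Frozen hand-computed values; round to the published 65/66/50/45."""
    value = func(baseline)
    assert value == pytest.approx(expected, abs=1e-9)
    assert abs(value - round(expected)) < 0.5


@pytest.mark.parametrize("params, func, attr", [
    ({"guilt": 0.0}, tg.ev_abuse, "ev_exp"),       # no guilt -> pure EV[Exp]
    ({"regret": 0.0}, tg.ev_no_trust, "eu_std"),   # no regret -> pure EU[Std]
    ({"p": 1.0}, tg.ev_trust, "ev_trust_given_honor"),
])
def test_strategy_ev_degenerate_reductions(baseline, params, func, attr):
    scenario = baseline.replace(**params)
    assert func(scenario) == pytest.approx(
        getattr(tg.expected_values(scenario), attr), abs=1e-12)


def test_ev_abuse_zero_utility_gap(baseline):
    payoffs = dataclasses.replace(baseline.payoffs, v2=baseline.payoffs.u2)
    scenario = dataclasses.replace(baseline, payoffs=payoffs)
    for guilt in (0.0, 0.5, 1.0):
        sc = scenario.replace(guilt=guilt)
        assert tg.ev_abuse(sc) == pytest.approx(
            tg.expected_values(sc).ev_exp, abs=1e-12)


def test_ev_no_trust_certain_standard_success(baseline):
    assert tg.ev_no_trust(baseline.replace(s=1.0)) == baseline.payoffs.u3


def test_ev_trust_always_abused_no_regret(baseline):
    sc = baseline.replace(p=0.0, regret=0.0)
    assert tg.ev_trust(sc) == pytest.approx(
        tg.expected_values(sc).eu_exp, abs=1e-12)


def test_ev_trust_matches_expanded_form():
    """Direct mixture form equals the fully expanded affine-in-p form."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        sc = make_random_scenario(rng)
        pay, pr, ps = sc.payoffs, sc.probs, sc.psych
        eu_exp = pr.e * pay.u1 + (1 - pr.e) * pay.u2
        eu_std = pr.s * pay.u3 + (1 - pr.s) * pay.u4
        expanded = (pr.p * ((1 - pr.r) * (eu_std - eu_exp)
                            + (1 - pr.e) * ps.regret * (pay.u3 - pay.u2))
                    + eu_exp - (1 - pr.e) * ps.regret * (pay.u3 - pay.u2))
        assert tg.ev_trust(sc) == pytest.approx(expanded, abs=1e-9)


# -- equipoise randomization -------------------------------------------------

@pytest.mark.parametrize("e", [0.1, 0.41, 0.5, 0.99, 1.0])
def test_equipoise_randomization_is_half_under_equipoise(e):
    assert tg.equipoise_randomization(e, e) == 0.5


def test_equipoise_randomization_general():
    """r = s/(s+e) equalizes the chance of success via either arm."""
    assert tg.equipoise_randomization(0.8, 0.2) == pytest.approx(0.2)
    for e, s in [(0.8, 0.2), (0.3, 0.6), (1.0, 0.5)]:
        r = tg.equipoise_randomization(e, s)
        assert r * e == pytest.approx((1 - r) * s, abs=1e-12)


def test_equipoise_randomization_undefined_at_zero():
    with pytest.raises(tg.ValidationError):
        tg.equipoise_randomization(0.0, 0.0)
    with pytest.raises(tg.ValidationError, match="e"):
        tg.equipoise_randomization(1.5, 0.5)


# -- validation --------------------------------------------------------------

@pytest.mark.parametrize("field, value", [
    ("e", 1.5), ("s", -0.1), ("r", 2.0), ("p", -1e-9),
])
def test_probability_validation_names_field(field, value):
    kwargs = {"e": 0.5, "s": 0.5, "r": 0.5, "p": 0.5, field: value}
    with pytest.raises(tg.ValidationError, match=field):
        tg.GameProbabilities(**kwargs)


def test_psych_validation_names_field():
    with pytest.raises(tg.ValidationError, match="regret"):
        tg.PsychParams(regret=1.2, guilt=0.0)
    with pytest.raises(tg.ValidationError, match="guilt"):
        tg.PsychParams(regret=0.0, guilt=-0.5)


def test_payoff_ordering_validation(baseline):
    bad = dataclasses.replace(baseline.payoffs, u3=10.0)  # breaks u3 >= u2
    assert "u3 >= u2" in " ".join(bad.ordering_violations())
    with pytest.raises(tg.ValidationError, match="ordering"):
        bad.validate()
    bad.validate(require_ordering=False)


def test_negative_utilities_rejected_unless_allowed(baseline):
    shifted = tg.GamePayoffs(u1=40, u2=-33.7, u3=34, u4=-33.1,
                             v1=45, v2=4, v3=20, v4=-6)
    with pytest.raises(tg.ValidationError, match="u2"):
        shifted.validate()
    shifted.validate(allow_negative=True)


def test_distinct_regret_fields(baseline):
    psych = tg.PsychParams(regret=0.2, guilt=0.2,
                           regret_no_trust=0.0, regret_abuse=0.4)
    sc = dataclasses.replace(baseline, psych=psych)
    evs = tg.expected_values(sc)
    assert evs.ev_no_trust == pytest.approx(56.489, abs=1e-9)  # no regret
    assert evs.ev_trust_given_abuse == pytest.approx(
        46.517 - 0.59 * 0.4 * 67.7, abs=1e-9)


# -- solve_game and the brute-force oracle -----------------------------------

def test_solve_game_baseline_defects(baseline):
    profile = tg.solve_game(baseline)
    assert profile.patient_choice is tg.PatientChoice.NO_TRUST
    assert profile.researcher_choice is tg.ResearcherChoice.ABUSE


def test_solve_game_trusting_when_success_certain(baseline):
    sc = baseline.replace(p=1.0, r=1.0, e=1.0)
    assert tg.solve_game(sc).patient_choice is tg.PatientChoice.TRUST


def test_solve_game_tie_breaks_toward_cooperation(baseline):
    flat = tg.Scenario(
        payoffs=tg.GamePayoffs(*([50.0] * 8)),
        probs=baseline.probs,
        psych=tg.PsychParams(regret=0.0, guilt=0.0))
    profile = tg.solve_game(flat)
    assert profile.evs.ev_trust == profile.evs.ev_no_trust
    assert profile.patient_choice is tg.PatientChoice.TRUST
    assert profile.researcher_choice is tg.ResearcherChoice.HONOR


def test_solve_game_is_deterministic(baseline):
    assert tg.solve_game(baseline) == tg.solve_game(baseline)


def test_closed_form_matches_tree_oracle_on_random_scenarios():
    """Leaf enumeration and the closed forms agree to 1e-9 on 1000 draws."""
    rng = np.random.default_rng(7)
    worst = 0.0
    for _ in range(1000):
        sc = make_random_scenario(rng)
        closed = tg.expected_values(sc)
        brute = tg.evaluate_tree_bruteforce(sc)
        for name in EV_FIELDS:
            worst = max(worst, abs(getattr(closed, name) - getattr(brute, name)))
        # the strategy choices implied by the oracle match solve_game
        profile = tg.solve_game(sc)
        assert (profile.patient_choice is tg.PatientChoice.TRUST) == (
            brute.ev_trust >= brute.ev_no_trust)
        assert (profile.researcher_choice is tg.ResearcherChoice.HONOR) == (
            brute.ev_honor >= brute.ev_abuse)
    assert worst < 1e-9


def test_tree_oracle_constant_tree(baseline):
    const = tg.Scenario(
        payoffs=tg.GamePayoffs(*([73.0] * 8)),
        probs=baseline.probs,
        psych=tg.PsychParams(regret=0.0, guilt=0.0))
    brute = tg.evaluate_tree_bruteforce(const)
    for name in ("ev_trust", "ev_no_trust", "ev_honor", "ev_abuse"):
        assert getattr(brute, name) == pytest.approx(73.0, abs=1e-12)


def test_per_arm_expectation_bounds():
    """Each per-arm expectation lies between its two leaf payoffs."""
    rng = np.random.default_rng(3)
    for _ in range(200):
        sc = make_random_scenario(rng)
        evs = tg.expected_values(sc)
        pay = sc.payoffs
        assert min(pay.u1, pay.u2) - 1e-12 <= evs.eu_exp <= max(pay.u1, pay.u2) + 1e-12
        assert min(pay.u3, pay.u4) - 1e-12 <= evs.eu_std <= max(pay.u3, pay.u4) + 1e-12
        assert min(pay.v1, pay.v2) - 1e-12 <= evs.ev_exp <= max(pay.v1, pay.v2) + 1e-12
        assert min(pay.v3, pay.v4) - 1e-12 <= evs.ev_std <= max(pay.v3, pay.v4) + 1e-12


# -- hypothesis properties ---------------------------------------------------

@settings(max_examples=100, derandomize=True)
@given(p1=unit, p2=unit, lam=unit)
def test_ev_trust_affine_in_p(p1, p2, lam):
    base = tg.Scenario.table1_baseline()
    tgh, tga = tg.trust_conditionals(base)
    assert tg.ev_trust(base.replace(p=0.0)) == pytest.approx(tga, abs=1e-9)
    assert tg.ev_trust(base.replace(p=1.0)) == pytest.approx(tgh, abs=1e-9)
    pm = lam * p1 + (1 - lam) * p2
    mixed = lam * tg.ev_trust(base.replace(p=p1)) \
        + (1 - lam) * tg.ev_trust(base.replace(p=p2))
    assert tg.ev_trust(base.replace(p=pm)) == pytest.approx(mixed, abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(g1=unit, g2=unit)
def test_ev_abuse_monotone_decreasing_in_guilt(g1, g2):
    base = tg.Scenario.table1_baseline()  # v2 > u2 and e < 1
    lo, hi = sorted((g1, g2))
    if hi - lo < 1e-12:  # below float resolution of the penalty term
        return
    assert tg.ev_abuse(base.replace(guilt=hi)) < tg.ev_abuse(base.replace(guilt=lo))
    assert tg.ev_honor(base.replace(guilt=hi)) == tg.ev_honor(base.replace(guilt=lo))


@settings(max_examples=100, derandomize=True)
@given(r1=unit, r2=unit)
def test_regret_monotone_decreases_patient_evs(r1, r2):
    base = tg.Scenario.table1_baseline()  # u1 > u4, s < 1, u3 > u2, e < 1
    lo, hi = sorted((r1, r2))
    if hi - lo < 1e-12:  # below float resolution of the penalty term
        return
    assert tg.ev_no_trust(base.replace(regret=hi)) < tg.ev_no_trust(base.replace(regret=lo))
    assert (tg.trust_conditionals(base.replace(regret=hi))[1]
            < tg.trust_conditionals(base.replace(regret=lo))[1])


@settings(max_examples=50, derandomize=True)
@given(c=st.floats(0.0, 500.0, allow_nan=False))
def test_shifting_all_utilities_shifts_all_evs(c):
    """Regret/guilt depend only on utility gaps, so EVs are shift-covariant."""
    base = tg.Scenario.table1_baseline()
    shifted = dataclasses.replace(
        base, payoffs=tg.GamePayoffs(**{
            k: getattr(base.payoffs, k) + c
            for k in ("u1", "u2", "u3", "u4", "v1", "v2", "v3", "v4")}))
    evs0, evs1 = tg.expected_values(base), tg.expected_values(shifted)
    for name in ("ev_trust", "ev_no_trust", "ev_honor", "ev_abuse"):
        assert getattr(evs1, name) - getattr(evs0, name) == pytest.approx(c, abs=1e-7)


@settings(max_examples=100, derandomize=True)
@given(e=st.floats(0.01, 1.0, allow_nan=False), r=unit)
def test_equipoise_reduction_symmetric_tree(e, r):
    """With symmetric 100/0 utilities, no regret/guilt and e = s, the
    within-trial chance of success via either arm balances exactly at r=0.5."""
    assert tg.equipoise_randomization(e, e) == 0.5
    sc = tg.Scenario(
        payoffs=tg.GamePayoffs(u1=100, u2=0, u3=100, u4=0,
                               v1=100, v2=0, v3=100, v4=0),
        probs=tg.GameProbabilities(e=e, s=e, r=r, p=1.0),
        psych=tg.PsychParams(regret=0.0, guilt=0.0))
    evs = tg.expected_values(sc)
    # both arms are worth the same, so the honor value is flat in r
    assert evs.ev_honor == pytest.approx(100 * e, abs=1e-9)
    assert evs.ev_trust_given_honor == pytest.approx(evs.eu_std, abs=1e-9)


def test_single_shot_game_no_state(baseline):
    """Solving one scenario does not perturb the next (no hidden state)."""
    before = tg.solve_game(baseline)
    tg.solve_game(baseline.replace(p=1.0, e=0.9))
    assert tg.solve_game(baseline) == before
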