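# Methods

## The model

Enrollment in a randomized controlled trial (RCT) is modelled as a
single-shot trust variant of the prisoner's dilemma between a patient and a
researcher. The patient moves first and either **trusts** (consents,
accepting vulnerability) or **does not trust** (insists on standard
therapy). Facing a trusting patient, the researcher either **honors** the
trust — enrolls the patient in the RCT, which allocates the experimental arm
with randomization probability `r` — or **abuses** it by administering the
unproven experimental treatment outside the trial.

Chance resolves treatment outcomes: the experimental treatment succeeds with
probability `e`, standard therapy with probability `s`. Outcomes carry
utilities on a common 0–100 scale, `u1..u4` for the patient and `v1..v4` for
the researcher, ordered (experimental success, experimental failure,
standard success, standard failure). The assumed orderings are
`u1 ≥ u3 ≥ u2, u4`, `v1 ≥ v2`, `v1 ≥ v3 ≥ v4` and `v2 ≥ u2` (society gains
knowledge even from a failed experiment). `p` is the patient's subjective
probability that trust will be honored.

Two psychological adjustments modify leaf payoffs:

* **Regret** `R ∈ [0,1]`: on a failure branch the patient loses the fraction
  `R` of the gap to the retrospectively best outcome — `R·(u1−u4)` when
  standard therapy fails after refusing the trial, `R·(u3−u2)` when the
  experimental treatment fails after abused trust. One shared `R` is the
  default; the two scenarios can be given distinct regret fractions through
  `PsychParams(regret_no_trust=…, regret_abuse=…)` since they plausibly
  differ.
* **Guilt** `G ∈ [0,1]`: a researcher who abused trust and saw the
  experimental treatment fail loses `G·(v2−u2)`, the fraction of the
  researcher–patient utility gap on that branch.

The strategy expected values are closed-form:

```
EU[Exp] = e·u1 + (1−e)·u2            EU[Std] = s·u3 + (1−s)·u4
EV[Exp] = e·v1 + (1−e)·v2            EV[Std] = s·v3 + (1−s)·v4

E[Honor]    = r·EV[Exp] + (1−r)·EV[Std]
E[Abuse]    = EV[Exp] − (1−e)·G·(v2−u2)
E[NoTrust]  = EU[Std] − (1−s)·R·(u1−u4)
E[Trust|H]  = r·EU[Exp] + (1−r)·EU[Std]
E[Trust|A]  = EU[Exp] − (1−e)·R·(u3−u2)
E[Trust]    = p·E[Trust|H] + (1−p)·E[Trust|A]
```

Each player's best response is the larger expected value; ties resolve
toward cooperation (TRUST / HONOR), matching the weak-inequality direction
of the dominance conditions. Strategy comparison uses exact IEEE double
comparison with no epsilon band — the model is algebraic, not iterative.
The game is single-shot: `solve_game` keeps no state between calls.

In the **equipoise** special case (both players value any success at 100 and
any failure at 0, no regret or guilt) the randomization probability that
balances the chance of obtaining a success through either arm is
`r = s/(s+e)`, which is exactly 0.5 under equipoise (`e = s`).

### Oracle

`evaluate_tree_bruteforce` re-derives every expected value by explicit
root-to-leaf path enumeration of the decision tree — chance probabilities
multiplied into regret/guilt-adjusted leaf payoffs, summed per strategy with
compensated (`math.fsum`) summation — sharing no algebra with the closed
forms. The test suite requires agreement to 1e−9 on 1000 random scenarios.

## Thresholds and sensitivity analysis

Both dominance conditions are affine in one behavior probability, so the
critical values are closed-form:

* **Researcher, critical randomization `r*`**: honoring dominates when
  `r·(EV[Exp]−EV[Std]) ≥ (EV[Exp]−EV[Std]) − (1−e)·G·(v2−u2)`. With
  `EV[Exp] > EV[Std]` this gives honor for
  `r ≥ 1 − (1−e)·G·(v2−u2)/(EV[Exp]−EV[Std])` (baseline: 61.2%, reported
  rounded to 61%); with `EV[Exp] < EV[Std]` the inequality flips
  (LESS_THAN). When the arm expectations coincide the division is undefined
  and the solver falls back to the direct comparison: honoring weakly
  dominates iff the guilt term is non-negative (ALWAYS/NEVER).
* **Patient, critical honor probability `p*`**: `E[Trust]` is affine in `p`
  with slope `E[Trust|H] − E[Trust|A]`; trust dominates when
  `p·slope ≥ E[NoTrust] − E[Trust|A]`. Positive slope gives an AT_LEAST
  threshold `gap/slope` (baseline: 92.2%); negative slope a LESS_THAN
  threshold; zero slope makes the decision independent of `p`
  (ALWAYS/NEVER). Thresholds are reported un-rounded, clamped to [0,1] with
  the pre-clamp value retained; a `percent` accessor provides whole-percent
  display rounding.

A widely quoted alternative figure for the baseline patient threshold is
67%. Direct evaluation of the dominance condition at the baseline gives
92.2%; 67% is what the same condition yields at `r = 0` — i.e. the
*necessary* honor probability for trusting anywhere along the randomization
axis of the p×r sensitivity plane (the left edge of the trust region, whose
boundary rises with `r`). This implementation reports the condition at the
scenario's own `r` and exposes the `r = 0` reading simply by evaluating the
threshold at `r = 0`.

`sweep_2d` solves the game over an `n_steps × n_steps` grid (default
101×101, resolving one-percentage-point features) of any two of
`e, s, r, p, regret, guilt`, returning per-cell best responses and strategy
EVs, exportable as a long-format table or a categorical heatmap.

## Monte Carlo probabilistic sensitivity analysis

`run_monte_carlo` samples all fourteen parameters per trial, determines both
players' best strategies with exactly the same closed forms as
`solve_game` (evaluated vectorized), and tabulates the 2×2
honor/abuse × trust/no-trust contingency table with marginals.

The default distribution set (the published one):

| parameter | distribution | rationale |
|---|---|---|
| u1, u3 | triangular(mode 90/84, 50–100) | elicited mode and range |
| u2, u4 | triangular(16.3/16.9, 0–50) | " |
| v1 | triangular(95, 80–100) | " |
| v2 | triangular(54, 10–100) | " |
| v3 | triangular(70, 40–80) | " |
| v4 | triangular(44, 0–80) | " |
| e | Binomial(450, 0.41)/450 | success proportion of n=450 trials |
| s | Binomial(316, 0.59)/316 | success proportion of n=316 trials |
| r | triangular(0.5, 0.2–0.8) | typical randomization ratios |
| p | Uniform(0, 1) | see below |
| regret, guilt | triangular(0.2, 0–1) | elicited mode, full range |

Numerical and design choices:

* **`p` distribution.** The honor probability is the one parameter published
  without a distribution annotation (only "0.5 (0–1)"). The default is
  Uniform(0,1) — maximal ignorance over the printed range;
  `MCConfig.table1_default(p_dist="triangular")` selects triangular(0.5,
  0–1) instead. The tabulated strategy proportions differ by under two
  percentage points between the two.
* **Payoff-ordering violations.** Sampled utility vectors can violate the
  orderings (e.g. a drawn `u3` above `u1`). The default accepts draws as-is
  so every parameter keeps exactly its declared marginal distribution;
  `enforce_payoff_invariants=True` rejects-and-resamples the whole utility
  vector of violating trials.
* **The (0.2–0.8) ranges beside `e` and `s`** describe the deterministic
  sensitivity range, not truncation bounds for the binomial draws (whose
  sd ≈ 0.023 makes truncation irrelevant); sampled probabilities are always
  clamped to [0,1].
* **Reproducibility.** One `numpy.random.Generator` stream seeds the whole
  run; parameters are drawn parameter-major in a fixed documented order
  (`PARAM_ORDER`), so identical config + seed gives identical counts on any
  platform with the same generator algorithm.
* Plain Monte Carlo only — no variance reduction or quasi-random sequences.

### Known divergence from the published 2×2 table

At 100,000 trials under the default distribution set this engine finds
honoring best for the researcher in ≈ 49.5% of trials, trusting best for
the patient in ≈ 38.3%, and full cooperation in ≈ 16.0%. The published
table reports 40.8% / 68.9% / 18.9%. The joint cooperation proportion
agrees to within three percentage points; the two marginals do not, and the
trust marginal differs by ≈ 30 points.

This divergence was investigated systematically: re-running the engine with
every defensible alternative reading of the inputs (triangular or uniform
`e`/`s` over 0.2–0.8; triangular `p`; uniform utilities over their ranges;
uniform regret/guilt; ordering-enforced resampling) and of the decision
rules (threshold inequalities applied without the sign flip for negative
denominators; trust decided by `E[Trust|Honor]` alone; regret/guilt terms
without their branch-probability factors) moves the three proportions but
no combination reproduces all three published marginals, and none
reproduces the published table's strong conditional asymmetry
(trust best in ≈ 84% of abuse-best trials vs ≈ 46% of honor-best trials).
The engine therefore implements the model's own equations exactly as
defined above and reports what they produce; the published table is treated
as not reproducible from the stated model. Notably, a patient deciding by
`E[Trust|Honor]` alone would trust in ≈ 69% of trials — matching the
published trust marginal — but that rule contradicts the model's trust
expectation, so it is not adopted.

## What the synthetic conditions do and do not show

All analyses here run on parameter distributions, not patient data. The
triangular utilities emulate expert-elicited central estimates with wide
ranges; the binomial `e` and `s` emulate sampling noise of meta-analytic
success proportions. Real trial decisions involve correlated utilities
(a patient who values experimental success highly usually also fears
failure differently), non-stationary beliefs, and process-based regret
(regret about how the decision was made, not just its outcome), none of
which the model represents. Passing tests therefore validate the algebra,
thresholds and sampling machinery of this model — not the empirical claim
that patients and researchers behave this way.

## Problem sizes

Default analysis sizes: 100,000 Monte Carlo trials (well under a second,
vectorized), 101×101 sensitivity grids, 1000-scenario oracle comparisons in
the test suite. These match the published analysis scale; nothing is scaled
down.

## Limitations

* Single clinical scenario (RCT vs off-trial experimental treatment); other
  enrollment dilemmas need different trees.
* Outcome-based regret only; process regret is out of scope.
* Trust is reduced to a risk assessment; virtue, goodwill and moral
  integrity are not modelled.
* Utilities come from a small convenience elicitation; the wide sensitivity
  ranges are the mitigation, not a substitute for data.
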