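# trustgame

Decision analysis of clinical-trial participation as a trust game.

Enrollment in a randomized controlled trial (RCT) puts a patient and a
researcher in a trust variant of the prisoner's dilemma: the patient decides
whether to **trust** (consent and accept vulnerability) or **not trust**
(insist on standard therapy), and the researcher facing a trusting patient
decides whether to **honor** the trust (enroll in the RCT, randomizing to
the experimental arm with probability *r*) or to **abuse** it (give the
unproven experimental treatment outside the trial). `trustgame` computes
the closed-form expected utilities of all four strategies — with **regret**
(a patient penalty on failure branches, a fraction *R* of the utility gap to
the retrospectively best outcome) and **guilt** (a researcher penalty
*G*·(v₂−u₂) on the experimental-failure branch under abuse) — and answers
when cooperation is rational.

With per-arm expectations `E_U[Exp] = e·u1 + (1−e)·u2` etc., the strategy
values are

```
E[Honor]   = r·E_V[Exp] + (1−r)·E_V[Std]
E[Abuse]   = E_V[Exp] − (1−e)·G·(v2−u2)
E[NoTrust] = E_U[Std] − (1−s)·R·(u1−u4)
E[Trust]   = p·(r·E_U[Exp] + (1−r)·E_U[Std]) + (1−p)·(E_U[Exp] − (1−e)·R·(u3−u2))
```

where *e* and *s* are the experimental and standard success probabilities
and *p* is the probability that trust is honored. On top of the core model
the package provides:

* threshold solvers — the critical randomization probability *r\** above
  which honoring dominates, and the critical honor probability *p\** above
  which trusting dominates;
* two-way sensitivity sweeps producing strategy-region maps over any two of
  *e, s, r, p, R, G*;
* a seeded, vectorized Monte Carlo probabilistic-sensitivity engine that
  samples all fourteen parameters (triangular utilities, binomial success
  proportions, uniform/triangular behavior probabilities) and tabulates the
  2×2 table of best strategies;
* a brute-force decision-tree oracle used by the test suite to verify every
  closed form by leaf enumeration.

It is aimed at decision scientists, trial methodologists and ethicists who
want to reproduce, probe or extend the model. See `docs/methods.md` for the
full model description and design choices.

## Worked example

The bundled baseline scenario uses patient utilities (90, 16.3, 84, 16.9),
researcher utilities (95, 54, 70, 44), e = 0.41, s = 0.59, r = p = 0.5 and
R = G = 0.2:

```python
>>> import trustgame as tg
>>> sc = tg.Scenario.table1_baseline()
>>> evs = tg.expected_values(sc)
>>> round(evs.ev_trust, 2), round(evs.ev_no_trust, 2)
(45.02, 50.49)
>>> round(evs.ev_honor, 2), round(evs.ev_abuse, 2)
(65.07, 66.36)
>>> prof = tg.solve_game(sc)
>>> prof.patient_choice.value, prof.researcher_choice.value
('NO_TRUST', 'ABUSE')
```

Trusting is worth 45 to the patient against 50 for refusing, and honoring
is worth 65 to the researcher against 66 for abusing — at the baseline the
rational outcome is mutual defection, even though both margins are slim.
The thresholds show what would change that:

```python
>>> tg.researcher_randomization_threshold(sc).percent   # honor iff r >= ...
61
>>> tg.patient_trust_threshold(sc).percent              # trust iff p >= ...
92
```

The same numbers from the command line, plus the Monte Carlo engine
(`trustgame solve`, `trustgame thresholds`, `trustgame sweep`,
`trustgame mc`):

```sh
$ trustgame mc --trials 100000 --seed 1 --out mc.json
```

yields (abridged)

```json
{
  "counts": {
    "HONOR": {"TRUST": 15972, "NO_TRUST": 33692},
    "ABUSE": {"TRUST": 22413, "NO_TRUST": 27923}
  },
  "marginals": {"HONOR": 0.4966, "TRUST": 0.3839},
  "cooperation_rate": 0.1597
}
```

i.e. sampling every parameter from its published distribution, honoring is
the researcher's best strategy in ≈ 50% of trials, trusting is the
patient's best strategy in ≈ 38%, and full cooperation is rational for both
at once in ≈ 16%. (The originally published table reports different
marginals for this simulation; `docs/methods.md` documents why they are not
reproducible from the model's own equations.) Scenario files are plain YAML
(see `src/trustgame/data/table1_baseline.yaml`); every CLI run writes a
manifest sidecar and re-runs are byte-identical.

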