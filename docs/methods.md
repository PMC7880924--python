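# Methods

`stentcea` evaluates the cost-effectiveness of three diagnostic imaging
strategies — coronary CT angiography (CTA), stress myocardial CT perfusion
(CTP), and both combined (CTA+CTP) — in patients with previous coronary
stenting who present with suspected obstructive coronary artery disease or
in-stent restenosis. This note documents the model, its conventions, the
numerical choices, and what the synthetic components do and do not show.

## Model structure

**Decision tree (time 0).** A cohort with pre-test probability
*p* = 0.6267 of a stenosis requiring percutaneous transluminal coronary
angioplasty (PTCA) is tested once. The strategy's sensitivity *Se* and
specificity *Sp* partition the cohort into

- TP = *p·Se* → timely PTCA ($4,678),
- FN = *p·(1−Se)* → delayed PTCA ($6,081.40 = 1.3 × timely, extended stay),
- FP = *(1−p)·(1−Sp)* → unnecessary invasive coronary angiography ($2,810),
- TN = *(1−p)·Sp* → no acute cost,

plus the strategy's imaging cost (CTA $397.87, CTP $470.31, combined = sum
of both, overridable). Acute costs are charged undiscounted at entry.

**Markov cohort (annual cycles).** Three states: alive without symptomatic
stenosis (utility 0.75, $5,837.27/year), alive with symptomatic stenosis
(utility 0.70, $7,588.45/year = 1.3×), dead (absorbing, utility 0). Annual
probabilities: new relevant stenosis 0.0264, death with stenosis 0.0230,
death without stenosis 0.0232, other-cause death 0.0126. Costs and QALYs
are discounted at 3%/year; willingness to pay is $100,000/QALY. The default
horizon is 10 annual cycles from age 65 (a `--lifetime` mode runs to age
100). Incremental net monetary benefit (INMB) of CTP vs CTA is
`WTP·ΔQALYs − ΔCost`.

## Conventions (where the problem is genuinely open)

Several accounting details are not implied by the inputs; each is a named,
configurable flag on `ModelOptions`, and every report records the flags in
force.

- **Entry convention** (branch → initial state). Three readings are
  implemented: `all-treated` (everyone enters the well state),
  `fn-diseased` (only false negatives spend their first year symptomatic),
  and `positives-decrement` (every test-positive patient — treated or
  invasively worked up — carries a first-year cost/utility decrement).
  **Default: `positives-decrement`.** Rationale: CTA has sensitivity 1.0,
  so it produces no false negatives; under the other two readings CTA's
  QALYs can never fall below CTP's, yet the strategies plainly differ in
  how many patients they send through procedures and convalescence. Tying
  the decrement to test positivity is the only reading under which the low
  specificity of CTA carries a health (not just monetary) penalty, and the
  only one that yields strict dominance of CTP. The flag makes the choice
  auditable and reversible.
- **Competing risks.** Disease and other-cause death combine
  multiplicatively, `1−(1−p_dis)(1−p_other)`, guaranteeing valid rows;
  new stenoses arise among that cycle's survivors. An `additive` rule is
  available for spreadsheet-style replication and raises an error directing
  the user to the multiplicative rule if a row overflows.
- **Stenosis resolution.** Default `tunnel`: one symptomatic year (higher
  cost, lower utility, a PTCA event charge for new in-model stenoses), then
  back to the well state — consistent with the new-stenosis rate being a
  yearly revascularization rate. `persistent` keeps the state for life.
  Entry-time stenosis occupancy is never charged the PTCA event (the acute
  treatment is already in the decision tree).
- **Reward accrual.** Rewards belong to the state occupied *during* a
  cycle (occupancy at cycle start) — the standard cohort-Markov convention,
  and the only one under which the entry-state decrement is lived through
  at all. The `accrual` flag sets discount timing: `end` (default,
  exponent = cycle index 1…N, so a reward-only model reproduces the
  geometric series `u·Σ(1+r)^−t` exactly), `start` (exponent t−1), or
  `half` (half-cycle correction: mean of start/end occupancy at mid-cycle
  discount).
- **Other-cause mortality.** Default: the constant 0.0126. An
  `age-specific` option uses a synthetic Gompertz schedule anchored at
  q(65)=0.0126 with an 8.5-year doubling time (see `stentcea.mortality`);
  it mimics the shape of a national life table, not any published row.

## Probabilistic sensitivity analysis

Every input with a beta (probabilities, utilities) or gamma (costs) family
is sampled independently per iteration; WTP, discount rate, horizon and
start age are never sampled. The sources state families but no dispersion,
so hyperparameters are method-of-moments fits from assumed precision:
effective sample size 150 (the diagnostic-accuracy cohort) for accuracies
and prevalence, 100 for utilities and transition probabilities, and a
standard error of 20% of the mean for costs — all configurable.
Degenerate means (sensitivity 1.0) become fixed specs. While the 1.3× cost
link is on, the delayed-PTCA and with-stenosis costs follow their sampled
partners rather than being drawn independently. Each iteration owns an RNG
substream spawned from the master seed, so results are bit-reproducible
and independent of evaluation order.

A consequence of these assumptions worth stating plainly: the two
state-specific death rates (0.0230 / 0.0232) are drawn independently with
sd ≈ 0.015 each (CV ≈ 65% at n_eff = 100). Because the strategies differ
in first-year state composition under the default entry convention, these
draws create strategy-differential mortality whose survival effect
compounds over the horizon (∂ΔQALY/∂p_death ≈ ±0.96). This channel
dominates the incremental-QALY variance and pulls the fraction of
cost-effective iterations at $100,000/QALY down to ≈ 0.77 under the
default hyperparameters — materially below what an analysis with precise
(or correlated) mortality inputs would report. Raising the effective
sample sizes or correlating the two death rates raises the fraction; the
defaults deliberately encode weak prior precision rather than a favorable
one.

## Deterministic sensitivity analysis

`one_way_dsa` re-runs the full pipeline on an 11-point grid (1.3×-linked
partners move with their source while the link is on) and reports INMB of
CTP vs CTA per point; `tornado` sorts parameters by the span between the
endpoint INMBs, ties broken by name. The packaged default ranges are the
published ones: CTP cost $370–570, invasive angiography ±$500, PTCA
±$1,000, pre-test probability 40–80%, and each accuracy ±5 percentage
points clipped to [0, 1] (CTA sensitivity, at 1.0, varies only downward).
Because the imaging cost enters exactly once and undiscounted,
dINMB/d(cost_ctp) = −1 identically — a useful analytic anchor test.

## Microsimulation oracle and synthetic studies

`simulate_patients` realizes the identical process patient by patient
(truth → test result → acute cost → yearly state walk) and accounts
rewards through the cohort engine's own `cycle_rewards` with one-hot
occupancy indicators, so any cohort/microsimulation discrepancy isolates
the transition logic. Patient *i* consumes row *i* of a fixed-shape
uniform matrix under the master seed (fixed column slots: disease status,
test result, one per cycle). The equivalence check — cohort totals within
3 Monte Carlo SE of the microsimulation mean at n = 10⁵, for all
strategies under every entry/resolution convention — is the oracle's
purpose. `generate_study` simulates finite diagnostic-accuracy studies
(binomial prevalence, then binomial TP/TN) whose re-fitted beta
distributions converge to the generating accuracies as n grows.

What these synthetic components do **not** show: the generator reproduces
the statistical structure of the source study (size, prevalence, test
accuracy), not its patient mix, verification bias, or correlated test
errors; passing tests certify internal consistency of the model, not the
external validity of its inputs.

## Known limitations and fidelity

- At the 10-year horizon the discounted QALY total is bounded by
  0.75·Σ_{t=1..10}(1.03)^−t ≈ 6.40 per patient; published figures for
  comparable analyses that report ≈ 6.8–6.9 QALYs imply a longer effective
  accrual (≈ 15 years). The package keeps the 10-year default and reports
  what it computes; the `--lifetime` flag explores the longer horizon.
- Absolute totals shift by a few percent across accrual and entry
  conventions (that is what the flags are for); incremental orderings —
  CTP dominant, CTA+CTP dominated — are stable across every convention
  combination except as noted for QALY ties under `all-treated`.
- Radiation-dose QALY effects, alternative modalities, and cost inflation
  machinery are out of scope; costs are 2019 USD as given.
- The combined strategy's empirical specificity (0.429) is used as an
  input; the independence-based discordant-positive rule
  (`combine_tests_or_rule`) predicts 0.305 and is exposed only as a
  cross-check of how correlated the two tests' errors are.
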