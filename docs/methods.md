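# Methods

`feedlot_econ` implements a deterministic, per-animal break-even model of
beef feedlot profitability on the carcass basis, together with the solvers
and stochastic machinery needed to use it for procurement and precision-
feeding decisions. This note records the model, its assumptions, the
numerical choices, and what the synthetic data can and cannot show.

## The model

The unit of analysis is a cohort: one production-profile (PP) class of
feeder calves finished on one diet for a fixed feeding period. PP classes
are phenotype-based growth-potential categories assigned at feedlot intake
(PP 1 above-average, PP 2 average — the pooled union of PP 2+ and PP 2− —
and PP 3 below-average). Only calf purchase and feed are modelled; yard,
veterinary, and fixed costs are assumed equal across cohorts and cancel in
comparisons.

Per animal over `DOF` days on feed, with live price `p_l` (ZAR/kg), carcass
price `p_c` (ZAR/kg), diet cost `c_f` (ZAR/kg feed), annual interest rate
`r`, and day-count basis `basis`:

    A = W_entry · p_l · (1 + r · DOF/basis)                purchase cost
    feed principal  P = I · c_f · DOF                      (I = kg feed/d)
    B = P · (1 + ½ · r_B · DOF/basis)                      feeding cost (displayed)
    C = A + P · (1 + ½ · r · DOF/basis)                    total carcass cost
    D = W_carcass · p_c                                    carcass income
    E = B / G_carcass                                      carcass feed cost of gain
    F = D − C                                              profit
    G = 100 · F / C                                        profit margin (%)

Financing is simple (non-compounded) pro-rata interest, ACT/365: this is
the convention that reproduces the published purchase-cost row to the cent
(199.2 kg × 33.25 × (1 + 0.1175·142/365) = 6 926.17); no compounding scheme
does. The full purchase price and half the feed principal are financed —
feedlots buy calves on credit and purchase feed continuously through the
period, so on average half the feed bill is outstanding.

Two feed interest rates coexist deliberately. The published feeding-cost
row is reproducible only with `r_B = 10 %/yr`, while the published total
cost, profit, and margin are internally consistent only when the feed
principal inside `C` is financed at the headline `r = 11.75 %/yr`. The
model's canonical rate is therefore 11.75 % everywhere, and
`feed_interest_rate_override = 0.10` exists solely to reproduce the
displayed `B` row (and `E`, which is defined from `B`). Setting the
override to `None` makes the whole ledger single-rate.

The study's narrative also describes purchasing at R57.12/kg on the carcass
basis with 10 % interest; that description is inconsistent with the ledger
footnote convention (R33.25/kg live at 11.75 %), which is the one that
reproduces the published numbers. The narrative variant is documented here
and not implemented.

A calf's entry carcass weight is predicted from shrunk body weight by the
linear conversion `CW = 0.694·SBW − 38.43` kg, valid above the positive
root (≈55.4 kg). Cohort-level carcass gain is taken as measured input data
by default (`gain_source="data"`): the published cohort gains derive from
per-animal records and are *not* equal to
`W_carcass − CW(W_entry)` applied to the cohort means (PP3/LPD:
231.1 − 99.81 = 131.3 vs the measured 119.5). `gain_source="conversion"`
applies the conversion instead, for inputs that lack measured gains.

### Break-even solvers

Profit is linear in either price with everything else fixed, so the
break-even prices are closed-form:

    live:    p_l* = (D − financed feed) / (W_entry · (1 + r·DOF/basis))
    carcass: p_c* = C / W_carcass

Both are verified in tests against an independent bisection (Brent) on the
profit function, and by the round-trip property |F(p*)| < 0.01 ZAR for
every built-in cohort.

### Comparative statements

Relative margin change between a candidate and a baseline diet is computed
on **absolute** margins, `100·(|G_b| − |G_a|)/|G_b|`, so that a shrinking
loss reads as a positive improvement symmetrically with a growing gain.
This is the reading under which the published "14 %" improvement of PP3 on
the cheap diet over the feedlot norm is recoverable from the published
margins (−1.45 vs −1.68). Diet rankings (`best_diet_per_pp`) maximize
profit or margin, or minimize cost of gain, with ties broken toward the
cheaper diet.

## Reproduction accuracy and its limits

The built-in dataset carries the production inputs at their published
precision: intake to 0.01 kg/d, weights to 0.1 kg. Re-evaluating the
ledger from those inputs reproduces rows A–E within ~0.1 % (A to the
cent). Rows F and G cannot be reproduced to comparable *relative*
precision from the published inputs: F is a small difference (tens to
hundreds of ZAR) of ~15 000-ZAR quantities, so the ±1–9 ZAR that input
rounding propagates into C becomes 0.7–5 % of F. The published rows are
not mutually consistent at sub-rounding precision either (the published
feeding cost for PP2/MPD implies an intake of 10.268 kg/d, which does not
round to the printed 10.28). The package therefore exposes both the
re-evaluated grid and a `reference_scenario_table()` holding the published
cells, and computes headline comparisons on whichever the caller asks for.

Two corrections are applied to the published tables, both forced by the
tables' own internal identities: the garbled PP1/HPD carcass-weight cell is
read as 319.1 (305.1–333.1), and the PP1/HPD income cell is stored as
17 550.50 (= 319.1 × 55.00 = published profit + published cost; the
published 17 550.00 contradicts the table's own profit row by 0.50).

Two published percentages are documented as irreproducible from any pair
of published cells and are deliberately not computed: the "13.74 % higher
feed cost" of PP1 on the high diet, and the "49.6 % loss reduction" for
PP3 (the published profits give 21.3 %).

## Uncertainty propagation

The study reports trait means with 95 % CIs and group sizes, never SDs.
Assuming t-based intervals, the animal-level SD is recovered as
`sd = √n · halfwidth / t₀.₉₇₅,ₙ₋₁` (scipy quantiles). If the intervals
were z-based instead, this overestimates SDs by t/1.96 — conservative for
spread estimates. The same conversion, inverted, rebuilds CIs after
pooling: PP 2± pooling uses n-weighted means and the exact two-sample
sum-of-squares combination (within + between), conserving n and n-weighted
trait sums; the raw per-animal data behind the published pooled rows are
not available, so independence of the two sub-samples is assumed.

One-at-a-time sensitivity re-evaluates profit at (1±δ) times one input and
reports the central elasticity `(ΔF/F)/(Δx/x)`. Note that carcass *gain*
has zero profit elasticity by construction — income is priced off the exit
carcass weight directly; gain moves the cost of gain `E`, not `F`.

Monte-Carlo propagation draws the four priced traits (entry weight, exit
carcass weight, daily intake, carcass gain) independently from normal (or
moment-matched lognormal) distributions with CI-derived SDs, evaluates the
full-precision ledger per draw, and summarizes mean, SD, 2.5/97.5 %
quantiles, and loss probability. Choices that matter:

* **Independence.** No covariances are published. Intake and gain are
  positively correlated in real cattle and enter profit with opposite
  signs, so independence makes the simulated profit variance an
  overestimate (conservative).
* **Antithetic pairing (default).** Each standard-normal draw is mirrored
  with its negation. Profit is exactly linear in the four traits, so the
  simulated mean equals the deterministic profit to machine precision at
  any number of draws, while spread estimates remain unbiased. Plain
  sampling (`antithetic=False`) carries a ±2–7 ZAR standard error on the
  mean at 10⁵ draws — larger than the profit of near-break-even cohorts.
* **Rejection.** Draws with non-positive gain, intake, or weights are
  redrawn and counted; a rejection fraction above 10 % raises a warning
  flag in the summary (the built-in cohorts sit 6–11 SDs away from zero
  gain, so rejections are nil there).
* **Reproducibility.** All randomness flows through numpy's seeded PCG64
  generator, whose identifier is recorded in the summary; identical seeds
  give bit-identical summaries. Degenerate zero-variance inputs return
  the deterministic profit exactly (no summation rounding).

## Synthetic trials

The generator emulates the design behind the data: four PP classes of 27
calves each; per class, three solitary pens and six pens of four; pens
assigned to the three diets at random, three per diet, *after* animals are
ranked and blocked by entry weight; 142 days on feed. Entry weight is
drawn per class (the n-weighted pool of the class's diet cells — weight
ranking precedes diet assignment, so entry weight cannot depend on diet);
intake and gain are drawn per (class, diet) cell, optionally with a
Gaussian correlation (default 0 in the study-reproduction design). PP 2+
and PP 2− reuse the pooled PP 2 generators with a ±3 % offset on mean
gain. Records are internally consistent with the entry-carcass conversion:
exit carcass weight = CW(entry) + gain. A dropout fraction is exposed
(default 0): the study reports cell sizes below the allocated counts
without describing exclusions.

Summarization back to cohorts computes animal-level means with t-based
CIs; the ratio traits (carcass ADG, FCR) are computed per pen and averaged
(`mean_of_ratios`, the default — consistent with the published FCRs, which
exceed the ratio of the published cohort means, e.g. 10.62 vs 10.33 for
PP3/LPD) or from cell totals (`ratio_of_means`). The two differ by a
Jensen gap whenever pens vary, since the pen-level ratio is convex in the
denominator.

One design effect is worth knowing when interpreting simulations: because
pens are weight-ranked blocks, a diet cell is a *cluster sample* of
rank-adjacent animals, and replicate cell means of entry weight are
materially more variable than under per-animal randomization (simulated
coverage of the published 95 % CI drops from ~93 % with solitary pens to
~86 % with the 3×1 + 6×4 layout). The per-pen CIs produced by the
summarizer absorb this at the ratio-trait level, but cell means of entry
weight inherit it.

What passing tests on synthetic data do **not** show: the generator is
normal/lognormal with independent cells parameterized from a single
printed table; real feedlot data carry intake–gain correlation, seasonal
and market structure, morbidity, and non-Gaussian tails that it does not
emulate. Parameter-recovery results certify the pipeline's arithmetic, not
field validity.

## Problem sizes and tolerances

Default problem sizes are desk-scale by construction: 9 (or 12) cohorts,
10⁵ Monte-Carlo draws per cohort for convergence checks, 10⁴ animals per
cell for generator recovery, 500 replicate trials for coverage checks.
Currency comparisons in tests use 0.01 ZAR absolute unless the reference
value itself derives from coarser-printed inputs, in which case the
tolerance matches that printing (stated per test). The model never rounds
internally; rendering rounds to 2 decimals (ASCII minus, period decimal
separator).
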