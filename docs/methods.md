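# Methods

## Model structure

`crcscreen` implements a deterministic state-transition (Markov cohort)
model of colorectal neoplasia following the adenoma–carcinoma sequence. A
closed cohort, reported per 100,000 members, is tracked as a probability
mass over 21 health states:

| class | undiagnosed | treated (surveillance/follow-up) | diagnosed, declined treatment |
|---|---|---|---|
| normal epithelium | `NORMAL` | — | — |
| non-advanced adenoma | `NAA_U` | `NAA_T` | `NAA_DU` |
| advanced adenoma | `AA_U` | `AA_T` | `AA_DU` |
| CRC stage I–IV | `CRC1_U`…`CRC4_U` | `CRC1_T`…`CRC4_T` | `CRC1_DU`…`CRC4_DU` |

plus two absorbing states, `DEATH_CRC` and `DEATH_OTHER`. Progression
NORMAL → NAA → AA → CRC I → II → III → IV is irreversible. The model runs
in annual cycles from the cohort's entry age until mean age 82 (the
assumed life expectancy), with a half-cycle correction: state-occupancy
accruals (utilities and the annual follow-up cost) use the mean of the
start- and end-of-cycle distributions, while event accruals (screens,
colonoscopies, diagnoses, treatments) count at the cycle in which they
occur. Cycle-*t* accruals are discounted by (1 + r)^−t, r = 3 %/year
(0–5 % in sensitivity analysis).

### Within-cycle event order

1. **Screening round** (if scheduled this cycle; see below).
2. **Background mortality** is applied first to every alive state; all
   remaining transitions are conditioned on surviving it.
3. **CRC mortality**: every CRC state — preclinical, treated or
   diagnosed-untreated — faces the stage-specific annual probability
   1 − s^(1/5) derived from 5-year survival *s*. This is a deliberate
   design choice: applying CRC mortality only after diagnosis would make
   detection *start* the death clock, so screening a low-prevalence cohort
   would increase CRC deaths — an artifact, not a property of cancer. With
   mortality attached to the disease state itself, the entire benefit of
   detection flows through intercepted stage progression, which is the
   mechanism screening actually exploits in a model without
   stage-specific-survival-at-detection inputs.
4. **Symptom detection** of undiagnosed lesions (class-specific rates),
   split by treatment compliance into treated vs diagnosed-untreated;
   diagnosis incurs a one-time cost. Diagnosed-untreated lesions may also
   become symptomatic and accept the re-offered treatment at the same
   rate × compliance (no second diagnosis cost). Without this
   re-presentation route, a screening round would permanently lock
   treatment-decliners out of later symptom-triggered care and one-off
   screening could look harmful.
5. **Progression** of undetected and diagnosed-untreated lesions;
   **recurrence** of treated lesions back to the corresponding
   *undiagnosed* state (a recurrent lesion must be re-detected, and then
   naturally re-incurs detection and treatment costs).

Row-stochasticity of every transition matrix is asserted to 1e-12 and
cohort mass conservation to 1e-10 every cycle.

### Screening overlay

A strategy is (entry age ∈ {42, 47, 52, 57, 62, 67, 72}, frequency ∈
{once, every 10/5/3/2 years, annual}, stop age 74, optional per-round
adherence decay). Rounds occur at cycle starts while the cohort's mean age
is at most the stop age. In a round, a participation fraction (58.29 %) of
every screening-eligible state — the undiagnosed population, treated
adenomas under surveillance, and diagnosed-untreated adenomas; diagnosed
CRC is never re-screened — takes the initial screen (risk questionnaire +
FIT, 3.26 USD). Lesion states screen positive with the initial-screen
sensitivity (0.5476 adenomas / 0.7778 CRC), lesion-free states with
1 − specificity (0.2830). Positives undergo colonoscopy (95.80 USD) with
compliance 38.92 %; colonoscopy confirms lesions with sensitivity
0.85/0.95/1.00 (NAA/AA/CRC) and confirmed cases split by treatment
compliance (0.60/0.80/0.95) into treated (treatment cost by class/stage)
vs diagnosed-untreated. Lesion-free colonoscopies are counted as false
positives, cost-only; a fraction 1 − 0.95 (colonoscopy specificity) incurs
one follow-up cost. All screened masses are read from the pre-round
distribution, so mass moved by the round is not screened twice. A one-time
program preparation cost (13,572 USD) is charged at entry for any strategy
that screens; the model charges it once per cohort run because its
denominator is not further specified in the source material.

### Entry cohorts

`run_cohort` defaults to an entirely lesion-free cohort (useful for
bookkeeping oracles and natural-history runs). The study-condition
analyses — `run_strategy_grid`, PSA, one-way sweeps — default to an *aged*
entry cohort: the no-screening process is run from age 40 to the entry age
and renormalized over survivors, so the cohort enters with the
age-appropriate mix of prevalent adenomas and preclinical cancer. This
matters: a 100 %-NORMAL cohort makes one-off screening at entry detect
nothing and dominates the comparison with pure cost. Both modes are
exposed (`init_mode="aged" | "normal"`, or an explicit distribution).

### Utilities and costs

Age-dependent general-population utility (0.957 / 0.955 / 0.957 / 0.943
for 40–54 / 55–59 / 60–64 / 65–82) applies to NORMAL, all NAA states,
treated AA (treatment restores quality of life) and — because quality-of-
life decrements follow diagnosis — undiagnosed preclinical CRC. Untreated
AA carries 0.83; diagnosed CRC carries the stage utilities
0.74/0.74/0.67/0.25 whether treated or not. Death accrues nothing.
Treatment costs (706 / 1,185 / 6,038 / 8,821 / 9,468 / 10,265 USD for
NAA / AA / CRC I–IV) are charged once on entry to a treated state (again on
re-treatment after recurrence); every treated state accrues an annual
86.43 USD follow-up cost; symptom detection charges an 86.43 USD diagnosis
cost (screen-detected diagnosis is covered by the colonoscopy fee). All
values are 2023 USD (converted upstream at 7.0467 CNY/USD); no currency or
inflation machinery is included.

## Parameters and uncertainty

Every parameter is a (base, 95 % UI, distribution family, optional age
band) record; the packaged CSV carries the full base case. Triangular
distributions use (min = UI low, mode = base, max = UI high); uniform uses
the UI endpoints; gamma and beta are parameterized by method of moments
with mean = base and sd = UI width / 3.92 (reading the UI as ±1.96 sd).
Background mortality is fixed (no published uncertainty). PSA draws all
parameters jointly and independently — no correlation structure is
published — with per-draw random substreams spawned deterministically from
one master seed, so results are independent of draw count and evaluation
order. Age-banded families are drawn independently per band.

## Calibration

`calibrate_transitions` fits the three calibration-sourced age-banded
families (normal→NAA onset, NAA→AA, AA→CRC I) to an age-banded prevalence
table by bounded least squares (`scipy.optimize.least_squares`, trust
region reflective) started from the packaged base case, with bounds
defaulting to each band's UI; literature-sourced parameters stay fixed.
Model prevalence is the proportion of the alive no-screening cohort
(started lesion-free at 40) carrying each lesion class, averaged over the
band's ages: current carriers (undiagnosed + diagnosed-untreated) for
adenomas, all alive CRC states for cancer. Only bands overlapping the
target age range are freed. The procedure is deterministic; on synthetic
targets generated by the model itself it recovers the generating
probabilities to well under 1 % (the recovery test asserts 10 %).

A property of the published base case worth knowing: with NAA→AA
progression of 0.17–0.24/yr beyond age 65 against AA outflow of ~0.19/yr,
the AA stock overtakes NAA around the late 60s and the NAA stock peaks in
the mid-60s as the normal-epithelium pool depletes. Severity ordering
(NAA ≥ AA ≥ CRC) therefore holds as *lifetime cumulative incidence* and as
point prevalence through the 50s, but not as point prevalence at older
ages. The synthetic entry-prevalence generator imposes the
severity-and-age ordering a real entry-screening table exhibits on its
noise-perturbed output; at zero noise it returns the raw model prevalence
so calibration self-consistency is exact.

## Program-yield metrics

The cascade formulas follow the published footnotes exactly: yields per
10,000 participants/colonoscopies are 10,000 × the product of the relevant
rates; colonoscopies-to-detect-one-lesion is a ceiling quotient (the only
convention reproducing the published 6/11/108/10); cost-per-lesion, rates
and NNS round half-up. The formulas are evaluated on the report's own
two-decimal-percent rates (e.g. compliance 38.92 %), because the published
yields are only reproducible at that printed precision. Published cells
that disagree with their own formulas — the detection rates vs the raw
count ratios, the per-10,000-participants row, and both NNS values — are
listed in a discrepancy report rather than silently matched.

## Economic comparison

`rank_and_compare` orders strategies by ascending QALYs (ties by cost) and
reports increments and ICERs versus the baseline and versus each row's
QALY-predecessor ("next most effective"), without dominance pruning — the
published comparison keeps dominated strategies in the ladder. A separate
`efficiency_frontier` utility applies strict and extended dominance for
general use. ICERs are rounded half-up to the dollar; a strategy losing
QALYs at non-negative cost is flagged "dominated" (never a sign-flipped
ratio), one gaining QALYs at non-positive cost "dominant". CEACs count a
strategy cost-effective versus baseline when λ·ΔQALY − ΔCost ≥ 0 and
optimal when it maximizes net monetary benefit among all strategies (ties
to the cheaper strategy), with the default willingness-to-pay grid 0 to
106,470 USD in 500-USD steps.

## Synthetic data

Three pure-function generators (seed + configuration) stand in for data
such programs rarely deposit, and each ships its generating parameters so
recovery tests can close the loop. They emulate: the age-banded
entry-prevalence table (model prevalence, optional multiplicative
log-normal noise, structural reshaping as above); registry-style
age-specific clinically diagnosed CRC incidence and CRC mortality per
100,000 (model curves + Gaussian noise, default sd 15 per 100,000,
clipped at zero and with mortality capped at incidence); and binomial
cascade counts (participation → positivity derived from the unscreened
50–74 lesion mix × test characteristics → compliance → per-lesion
detection). What passing tests on these fixtures shows is that the
pipeline is self-consistent and statistically calibrated — not that the
model reproduces any particular real population.

## Problem sizes and numerical choices

The default analyses use the full 7 × 6 strategy grid (49 cohort runs of
10–40 annual cycles; fractions of a second) and a 500-draw PSA for the
two-strategy entry-42 comparison (~20 s on one CPU); the test suite keeps
PSA draws at 1–500 and calibration to five age bands. Tolerances: matrix
row sums 1e-12, mass conservation 1e-10, calibration recovery 10 %
relative, Monte-Carlo moment checks 1–3 %. Ties in CEAC optimality break
toward the cheaper strategy; zero-denominator ratios (deaths averted ≤ 0,
zero detections) are flagged or raised, never coerced.

## Known limitations

- No serrated-pathway lesions, no stage shift at detection, no
  individual-level microsimulation, no secular trends in incidence.
- 5-year-survival-based CRC mortality is applied to preclinical cancer as
  well as diagnosed cancer (see the design rationale above); absolute CRC
  death counts are therefore not comparable to diagnosis-based survival
  cohorts, though differences between strategies are.
- Parameters are sampled independently in PSA; any real correlation
  between, say, participation and compliance is ignored.
- The preparation cost's denominator is unknown; charging it once per
  cohort run makes "once" strategies carry the same fixed cost as annual
  ones.
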