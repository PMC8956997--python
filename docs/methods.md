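# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the places where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Analysis population and data model

The analysis set is the complete-case sample of a three-arm randomized
trial (web-based psychoeducation n=64, home-based n=63, routine care n=66;
193 of 204 randomized mothers had complete month-6 outcomes). Participants
with any missing month-6 score are excluded at load time with a logged
count; the four instruments are maternal parental self-efficacy (PMPSE,
17–68, higher better), perinatal infant-care social support (PICSS, 22–88,
higher better), postnatal depression (EPDS, 0–30, lower better) and
anxiety (HADS-A, 0–21, lower better). Costs are six-month health-service
bills (full bill before subsidy, SGD 2016–2017; SGD 1 = USD 0.75), stored
as an itemized long table whose per-participant sums must equal the wide
table's totals to the cent. Multi-period costs within the six-month
horizon are summed nominally; no within-trial discounting is applied.

## Effectiveness and cost models

Effectiveness: one gaussian-identity regression per outcome on arm
indicators plus baseline score, age, days since baseline, ethnicity,
employment, income band (ordered, threshold SGD 5,000 — the only
resolution reported), prenatal-course attendance and skin-to-skin contact.
Identity link on the score scale was chosen so adjusted means live on the
instrument scale; the published analysis names the adjustment set but not
the family. Categorical covariates are one-hot encoded with the largest
category as reference; the control arm is the reference arm when present.
No univariable pre-screening is applied: the full stated covariate list is
kept (pruning would add a data-dependent selection step that cannot be
replicated without the original data).

Cost: a two-part (hurdle) model. Part 1 is a probit on the indicator of
any cost, fitted to all participants; part 2 a gamma GLM with log link
fitted to positive costs only; covariates are employment and income band
plus arm. Expected cost per participant is P(positive) × E[cost|positive].
Gamma dispersion uses the Pearson estimator; IRLS runs to tolerance 1e-8,
maximum 100 iterations. Quasi-separation in the probit (|coef| > 50 or a
separation exception) raises an explicit error suggesting covariate
reduction. An arm with no positive costs at all is dropped from both parts
with a warning and assigned expected cost 0.

Adjusted per-arm means use marginal standardization (recycled
predictions): each participant's arm is set to every arm in turn and
predictions are averaged over the pooled sample. This is the standard
health-economics standardization; the source analysis states adjustment
but not the standardization method. With an intercept-per-arm model this
reproduces raw arm means exactly (identity for the gaussian part; exact
MLE invariance for probit/gamma), which the tests exploit as an oracle.

## Program costing

Per-participant program cost over the 6-month horizon:

    m * [ (EAC(upfront; r, L) + maintenance) * 0.5 / n_served + delivery ]

with EAC the equivalent annual cost `upfront * r / (1 - (1+r)^-L)`
(straight-line `upfront/L` at r=0), r = 3 %/year, L = 5 years, and m a
scenario multiplier acting on the whole program component. The published
per-participant components (web ≈ 50.9, home ≈ 77.8 SGD) are not exactly
derivable from the printed inputs under any single convention we could
construct (the annuity formula gives web ≈ 52.0; the base-case and
multiplier panels of the published scenario table imply slightly different
home components, 77.38 vs 77.80, and the printed per-visit fee is 77.42).
Both conventions are therefore implemented behind a switch: the annuity
formula for de-novo costing, and calibrated components (taken from the
200 %/300 % scenario rows, which pin them down to three decimals) for
reproducing the published panels. The residual between the two is ≤ 1 SGD
per participant and is reported, not hidden. The "valid for 3 years"
scenario is L=3 with all else fixed.

## CEA and dominance

Depression and anxiety scores are inverted (s → scale_max − s) before any
incremental comparison; the additive constant cancels in every ΔE, so
ICERs are invariant to it. ICERs are reported to 1 decimal (internal
arithmetic unrounded); |ΔE| < 1e-9 is treated as no effect difference
(status "undefined", no division). In the three-arm comparison an arm is
*dominant* when least-cost and best-effect among all arms and *dominated*
when most-cost and worst-effect; the remaining arms are walked in
ascending cost and each compared with the previous non-dominated arm,
with strong dominance (extra cost, no effect gain) flagged along the way
and pairwise-domination relations recorded as diagnostics. Cost ties are
broken by the better oriented effect and flagged. Scenario panels move
only the program component of cost; adjusted effects and adjusted
health-care costs are scenario-invariant.

## Bootstrap PSA

Nonparametric bootstrap, resampling participants with replacement within
arm (fixed per-arm n — stratification preserves the randomized design),
with a full refit of all effectiveness models and the two-part cost model
on every replicate. Replicate seeds are spawned from one seed sequence, so
runs are deterministic and enlarging the replicate count preserves the
earlier replicates. Replicates whose models cannot be fitted (rank
deficiency or probit separation in an unlucky resample) are dropped and
counted; a failure rate above 1 % aborts with diagnostics. Replicates with
an all-zero-cost arm are kept (expected cost 0) and flagged. The CE-plane
quadrant convention is closed on the right/upper edges (ΔE = 0 counts as
"more effective", ΔC = 0 as "more costly"), so the four fractions always
partition the draws. CEACs use NMB = λ·(oriented effect) − cost with ties
split equally; the willingness-to-pay grid defaults to 0–500 SGD/score in
steps of 5. The shipped default is 10,000 replicates; the test suite and
the analysis driver run 500, which is enough to exercise every structural
property (reproducibility, partition, consistency with the base case)
without multi-minute runtimes.

## Budget-impact projection

Cumulative, undiscounted, per arm × coverage (10/50/100 %) × year (1–5)
for a 20,000 mothers/year cohort: program(t) = upfront + t·maintenance +
t·coverage·cohort·delivery; health-care(t) = t·coverage·cohort·(unadjusted
arm mean cost); total = program + health care. Upfront amounts enter
undepreciated here — the published table's arithmetic (17,210 + 2,900·t)
confirms that convention — and the home upfront is carried at its rounded
value 233 (source value 233.40 retained in config), so reproduction is to
±1 SGD. Covered mothers incur their own arm's health-care cost and
uncovered mothers are outside the table entirely (no mixing of untreated
mothers at partial coverage); that is the published convention, and the
alternative is deliberately not modelled.

## Synthetic-data generator

The generator emulates the study conditions: arm sizes 64/63/66;
zero-cost probabilities 28/64, 20/63, 30/66; positive costs gamma with
parameters solved in closed form so the zero-inflated mixture reproduces
the published overall mean and SD per arm (mean 339.9/375.4/411.2, SD
493/699.9/601 — SD > mean implies heavy right skew, consistent with the
gamma family of the analysis model), with an explicit feasibility error
when a requested SD is unattainable given p0 and the mean. Month-6 means
are set to the published adjusted-effectiveness values — raw means are
calibrated to adjusted ones because those are the only per-arm levels
reported (a documented conflation). Values unstated anywhere were fixed
once as plausible: month-6 SDs 6/8/3.5/2.8 score points (PMPSE/PICSS/
EPDS/HADS-A), baseline means 48/74/7/6 with the same SDs, baseline–month-6
correlation 0.5 (exposed as a knob), age N(30, 4), ethnicity
.50/.25/.15/.10 (Chinese/Malay/Indian/other), employment 0.85, income >
SGD 5,000 0.75, prenatal courses 0.5, skin-to-skin 0.8, follow-up 168–196
days. Covariate effects on outcome and cost default to zero (arm effects
only); they are configurable — including per-arm covariate distributions —
so the confounding-adjustment path can be exercised against known truth.

Scores are clipped to the instrument range after the Gaussian draw, the
simplest bounded-score mechanism. Clipping shifts means (≈0.2 points for
PMPSE at the chosen SD), so the generator exposes the censored-normal mean
in closed form as its own ground truth for recovery tests. Positive totals
are split into 1–3 itemized bills (Dirichlet weights, categories drawn
from service-use-table-like frequencies) preserving the total to the cent.

What the generator does *not* emulate: attrition dynamics (the 204→193
drop is represented only by the analysis-set arm sizes), integer-valued
instrument scores, within-person cost correlation across periods, and any
real covariate–outcome association. Passing tests therefore demonstrate
that the machinery is correct under the stated data-generating process,
not that the published regression or PSA outputs on the real data are
recoverable — they are not, since the participant-level data were never
deposited. The published CEAC plateau probabilities, in particular, are
verified only structurally.

## Problem sizes

Deterministic checks (projection, ICER arithmetic) run at the published
inputs' own scale. Statistical checks use ~5,000 per arm for
"no-confounding ⇒ adjusted = raw" (2 SE tolerance), ~50,000 per arm for
parameter recovery and generator calibration (2–3 % tolerances), and 500
bootstrap replicates for PSA reproducibility and consistency — sizes at
which the tested tolerances are several standard errors wide while the
whole suite stays around a minute.
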