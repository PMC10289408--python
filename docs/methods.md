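# Methods

This note records the modelling assumptions, parameter defaults and
numerical conventions behind `cdsseval`, and what the synthetic-data tests
do and do not demonstrate about real panel-review data.

## Study representation

A study is a `StudyBundle`: a case table (seven categorical covariates, all
required — the design enrols only cases with complete information), two
tiered reference maps (CDSS and guideline) over every (case, treatment
stage), a decision-record table with one row per (case, stage, reviewer)
holding the initial and final decisions, and the panel rosters.  Regimen
labels are opaque tokens compared by exact string equality after
canonicalisation (case-fold, whitespace collapse); the package deliberately
models no drug content, dosing or regimen equivalence classes.  Each record
holds exactly one decision per pass; multi-regimen answers are out of
scope.  Tier sets within a reference must be pairwise disjoint and a
recommending reference must have a non-empty Level-I set; CDSS references
carry no Level-III tier.

## Classification schemes

The five-way scheme (physician vs tiered reference) and the four-way
high-level scheme are total functions over their structural input space; a
brute-force truth-table oracle in the test suite checks exhaustiveness and
mutual exclusivity.  Three conventions deserve note:

* **Level-I matching is set membership**, because references may list
  several Level-I options.
* **A guideline Level-III match is classified "not available"**: the
  five-way scheme recognises only Levels I-II, and a Level-III option is
  exploratory by definition.  The tier sets are kept disjoint so the choice
  never shadows a Level-I/II match.
* **A CDSS subject is its whole Level-I set.**  Conformity requires a
  non-empty intersection with the guideline Level-I tier, Level I taking
  precedence over Level II.  For the high-level comparison, a match means
  the high-level physician's regimen lies in the CDSS Level-I set.

Concordance, conformity and high-level concordance all use initial
decisions by default (the unaided judgment); this is configurable
(`AssessmentOptions.decision_pass`, `hl_pass`).  Whether the high-level
standard itself should be the initial or final decision is not fixed by the
design; initial is the default for symmetry.

## Stability, consensus, calibration

Stability is defined only on the subgroup of decisions whose initial
version is discordant with the CDSS — the operations enforce this contract
rather than silently filtering.  It is evaluated per decision point
(case × stage), the granularity at which the 6372/2124 accounting works.
The pipeline computes stability both on the raw discordance subgroup and on
a propensity-matched subset: each physician stratum's discordant records
are matched 1:1 (caliper 0.01 on the probability scale) against the pooled
remainder on the seven covariates (age group, menstrual status, breast and
axillary surgery, TNM stage, molecular subtype, treatment stage), which
removes case-mix differences before strata are compared.  The matched
arm definition (stratum vs pooled rest) is one of several defensible
readings of the design and is kept configurable at the library level.

Consensus is unanimity of the three panel decisions on a point, computed on
initial decisions by default.

Calibration multiplies a raw rate by the subgroup's relative stability
index.  Two benchmark policies exist because the stated rule and the
worked numbers in the source material disagree: under the stated
`max_stability` policy the benchmark is the most stable subgroup, indices
are ≤ 100, and calibration can only shrink a rate (the benchmark is a
fixed point — both properties are property-tested); the published
seniority-level calibrations, however, are arithmetically consistent only
with the *senior* subgroup as a fixed reference, since the middle subgroup
is more stable yet its calibrated value exceeds its raw one.  The default
is `max_stability`; `fixed_reference` reproduces the published triples.
Reconstruction of published calibrated values from one-decimal inputs is
asserted within ±0.1 percentage points (input-rounding tolerance).

## Variation and inference

Internal variation uses the antisymmetric pairwise difference matrix,
the SD of subgroup rates (sample SD, ddof = 1, by default; the convention
is not fixed by the design, so it is a parameter) and the mean absolute
off-diagonal difference.  Both dispersion measures are
translation-invariant, which the suite checks.

Chi-square is uncorrected Pearson — the published 3×3 reason-table
statistics (13.888, 12.831) are reproduced exactly by that convention.
McNemar uses (b−c)²/(b+c) on 1 df for b+c ≥ 25 and the exact two-sided
binomial test below; the exact branch is verified against full enumeration
for b+c ≤ 12 and the large-sample branch against `statsmodels`.  Logistic
risk-factor models are ML fits with first-level reference dummy coding;
rank deficiency and perfect separation raise diagnostic errors instead of
returning silently broken fits.  Propensity scores come from a pooled
logistic model of side membership; greedy matching traverses side A in
descending score order, ties broken by lower index, making the procedure
deterministic for a fixed input order (and invariant, up to relabelling,
to permutations of the candidate pool).

All percentages print at one decimal, rounded half-up (`decimal`-based, to
avoid binary-float round-to-even artefacts); χ² and p values print at three
decimals.  Unrounded rates are used whenever a rate feeds further
arithmetic (calibration, variation).

## The synthetic study generator

The generator reproduces the trial's *design* exactly: nine case groups of
59, panels of three (one physician per hospital grade with distinct
seniorities — the published rosters for G1, G7, G8, G9 are used verbatim
and the remaining five panels complete the same Latin-square pattern),
four stages, hence 531 cases, 2124 decision points and 6372 opinions per
pass.  Covariates are drawn iid from the trial's overall case-mix
frequencies.

Its stochastic decision model is deliberately simple and fully
parameterised:

* **References.**  Per (case, stage) the guideline recommends exemption
  with a per-stage probability (not reported for the real trial; the
  defaults 0.30/0.10/0.35/0.20 for targeted/chemo/radio/endocrine are the
  package's own choices reflecting that targeted and radiotherapy are the
  stages most often omitted), otherwise draws 1-2 Level-I options and one
  Level-II option from an abstract per-stage vocabulary.  The CDSS copies
  the guideline tiers with probability `p_ai` (default 0.975) and otherwise
  draws a Level-II promotion, an off-tier option, or a dispute.
* **Physicians.**  An initial decision conforms to the guideline Level-I
  set with a per-stratum probability `p_conf`.  Only two stratum values are
  published (provincial-senior 0.836, county-junior 0.856); the remaining
  seven defaults were solved once so that the equal-weight seniority and
  grade marginals match the published marginal rates (seniority
  80.6/79.5/79.9, grade 82.0/79.8/78.2), with the one remaining free
  parameter fixed a priori.  Nonconforming draws mix Level-II match /
  off-tier / dispute (0.35/0.35/0.30).
* **Switching.**  If the initial decision is CDSS-discordant, a discordance
  reason is drawn from the stratum's published reason mixture and the final
  decision keeps the initial one with the stratum's stability probability
  `p_stable` (three published values — 0.527/0.545/0.527 for 301/302/102 —
  and the rest solved from the published marginals the same way), otherwise
  switches to a CDSS Level-I option.  CDSS-concordant decisions never
  switch.

Every branch of this model keeps the configured probabilities identifiable:
conformity, stability and CDSS conformity are exact Bernoulli draws, so the
pipeline's estimates recover them within three binomial standard errors at
study scale — the parameter-recovery tests assert precisely that.

**What the generator does not emulate.**  Reviewer decisions are
conditionally independent given the references: there is no shared
case-difficulty effect, no within-physician consistency, and no covariate
dependence of conformity.  Consequently the synthetic consensus rate
(≈ 42% under the defaults) is an emergent quantity, lower than the real
trial's 64.2%, because real panels agree through the case itself and not
only through the guideline; equally, synthetic covariate subgroup rates are
flat by construction.  Passing tests therefore demonstrate that the
*indicator machinery* is correct and the generator's dials are recovered —
not that the stochastic model captures real inter-physician correlation
structure.  Reason labels are planted, not inferred, since in the real
study they were human-adjudicated.

## Problem sizes and determinism

The default test suite runs one full-size synthetic study (531 cases)
through the complete pipeline and uses n = 2000-10800 for simulation-based
checks and n = 5000 for logistic recovery — sizes at which three-standard-
error bands are meaningfully tight while the whole suite stays fast.  All
randomness flows through `numpy.random.default_rng` seeded from the config
or CLI `--seed`; identical config and seed give byte-identical serialized
bundles, and the assessment itself is deterministic given its inputs.

## Known limitations

* The matched-arm definition for post-matching stability is one reading of
  an underdetermined design; totals such as the published 495-record
  denominator depend on the unpublished raw data and are not reproduced,
  only the machinery to compute them.
* Calibrations of patient-level subgroups (e.g. by age group) require
  subgroup stabilities that the published material does not print; the
  pipeline computes them from data but they cannot be cross-checked.
* Greedy caliper matching is order-dependent by construction; optimal or
  full matching is intentionally out of scope.
* Regimen equality is string-level; clinically equivalent regimens with
  different labels count as different.
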