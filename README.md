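# cdsseval

Multi-level, multi-indicator assessment of treatment-decision quality for
physician raters and tiered clinical decision support systems (CDSS).

## The problem

In panel-review trials of oncology CDSS, every enrolled case is judged
independently by several physicians and by the CDSS, against a tiered
guideline standard ("Level I" = strong evidence and good accessibility,
"Level II" = weaker or less accessible options, or an explicit "not
recommended").  Plain agreement statistics answer the wrong question: a
junior physician who simply follows whatever the machine says will score a
high concordance without having made a good decision.  `cdsseval`
implements an indicator system that separates three layers:

* **empirical level** — decision concordance with the CDSS, concordance
  with designated high-level physicians, and the consensus rate of each
  three-physician panel;
* **pure standardisation level** — guideline conformity of physicians and
  of the CDSS;
* **comprehensive level** — the same indicators *calibrated* by decision
  stability, the fraction of initially CDSS-discordant decisions a reviewer
  keeps after seeing the CDSS report.

The trial design it targets: cases split into nine groups, each reviewed by
a panel of three physicians (one per hospital grade — county, municipal,
provincial — with distinct seniorities), four adjuvant treatment stages per
case (targeted, chemotherapy, radiotherapy, endocrine), two decision passes
(initial, then final after viewing the CDSS report).  Physicians are coded
by four digits: grade, two seniority digits, index — `3034` is provincial
junior physician 4.

## The indicators

For a physician decision d and a tiered reference R, the five-way match is

* Level I match: d ∈ R₁ — **concordant/conforming**
* Level II match: d ∈ R₂
* not available: both recommend, d in no tier
* not recommended match: both decline — **concordant/conforming**
* recommend dispute: exactly one recommends.

Rates are `n/N × 100%`, reported at one decimal (half-up).  With a CDSS as
subject, its whole Level-I set is compared and conformity requires a
non-empty intersection with the guideline Level-I set.  The strict rule —
Level II counts as discordant — is used throughout.

Stability calibration: with sᵍ the decision stability of subgroup g and s*
the benchmark stability (the maximum over subgroups, or a designated
reference subgroup),

    relative index RIᵍ = sᵍ / s* × 100,   calibrated rate = RIᵍ/100 × raw rate.

Internal variation is summarised by the antisymmetric pairwise
rate-difference matrix, the SD of subgroup rates, and the mean absolute
pairwise difference.  Supporting inference: uncorrected Pearson chi-square,
McNemar (closed form for b+c ≥ 25, exact binomial below), logistic
risk-factor regression, and 1:1 greedy nearest-neighbour propensity-score
matching within a caliper of 0.01 to balance the discordance subgroups
before stability comparisons.

Because the underlying trial data are not publicly deposited, the package
ships a synthetic study generator (`cdsseval.simulate`) that reproduces the
design — 531 cases × 4 stages × 3 reviewers = 6372 decision opinions per
pass — with a parameterised stochastic model of references, conformity,
discordance reasons and final-decision switching, so the entire pipeline is
testable end to end.

## Worked example

```python
from cdsseval import (AssessmentOptions, GeneratorConfig,
                      assemble_study, run_assessment)

bundle = assemble_study(GeneratorConfig(seed=1))      # 531 cases, 6372 records
report = run_assessment(bundle, AssessmentOptions(seed=1))

print(report.concordance["overall"]["Overall"])           # 78.4% (4997/6372)
print(report.conformity_physician["overall"]["Overall"])  # 80.3% (5117/6372)
print(report.conformity_ai["overall"]["Overall"])         # 97.4% (2068/2124)
print(report.consensus["Overall"])                        # 42.1% (895/2124)
print(report.stability_post["overall"]["Overall"])        # 41.6% (570/1370)
```

Reading: physicians agreed with the CDSS on 78.4% of their 6372 opinions
and with the guideline on 80.3%, while the CDSS itself conformed to the
guideline on 97.4% of the 2124 decision points — a 17.1-point gap.  Among
the 1370 propensity-matched initially-discordant decisions, 41.6% were kept
unchanged after the physicians saw the CDSS report; per-stratum stability
feeds the calibrated tables in `report.calibration`.

The same pipeline is scriptable from the shell:

```sh
cdsseval simulate --seed 1 --out study/         # write the four study tables
cdsseval assess study/ --out report/            # full report directory
cdsseval calibrate rates.csv --policy fixed_reference --reference senior
```

## Layout

| module | contents |
| --- | --- |
| `cdsseval.model` | domain types, reviewer-code codec, CSV/JSON study IO |
| `cdsseval.indicators` | five-/four-way classifiers, `indicator_rate` |
| `cdsseval.stability` | decision stability, panel consensus |
| `cdsseval.calibration` | relative stability index, calibrated rates, variation |
| `cdsseval.stats` | chi-square, McNemar, logistic regression, PS matching |
| `cdsseval.simulate` | synthetic study generator |
| `cdsseval.pipeline` | `run_assessment`, report writer |
| `cdsseval.cli` | `cdsseval` command |

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical conventions.
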