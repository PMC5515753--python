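# Methods

## Scores and definitions

All four scores are unweighted sums of binary indicators (except the
CHADS₂ prior-stroke component, which carries 2 points), compared against
an inclusive cutoff (`total >= cutoff`). The defaults are the published
values; every threshold lives in `ScoreConfig` so sensitivity analyses can
move any of them.

| score | components (1 point each unless noted) | range | cutoff |
|---|---|---|---|
| CHADS₂ | CHF, hypertension, age ≥ 75, diabetes, prior stroke/TIA (2 pts) | 0–6 | 4 (as a component) |
| CMCA score | >1/3 early hypodensity, HMCAS, brain edema, admission NIHSS ≥ 17, stroke in progression | 0–5 | 2 |
| Mortality score 1 | CMCA infarction, CHADS₂ ≥ 4 | 0–2 | 1 |
| Mortality score 2 | CMCA infarction, CHADS₂ ≥ 4, NIHSS ≥ 26 in the first 5 days | 0–3 | 2 |

**Infarct classification.** CMCA is defined purely by territory
involvement — all three of the deep, superior and posterior MCA
subdivisions — independent of the numeric fraction. Otherwise an
involvement fraction ≥ 0.5 is IMCA; below that the patient is outside the
LHI domain and the mortality scores are deliberately undefined
(`ScoreDomainError` / NA in tables).

**Stroke in progression** is an NIHSS rise of ≥ 2 points between admission
and day 5, or stroke-related death. A surviving patient with no day-5
assessment evaluates False with a data-completeness warning; no
imputation is attempted, because none is defined for these scores.

**NIHSS window for mortality score 2.** The source definitions waver
between "on day 5" and "during the first 5 days". The default is the peak
of admission and day-5 NIHSS (the clinically conservative reading: a
patient who is severe at any point in the window counts); a
`nihss_window="day5"` configuration restores the day-5-only reading.

**Known circularity.** The CMCA score contains a day-5 component (stroke
in progression) yet predicts a classification made on second imaging
within those same 5 days. The pipeline computes it as defined; its ROC
against CMCA membership is therefore an in-sample association, not a
prospective validation, and the report should be read accordingly.

## Evaluation statistics

* **ROC / AUC** — one operating point per distinct score value under the
  inclusive rule "positive iff score ≥ threshold", plus a sentinel above
  the maximum (sensitivity 0, specificity 1). AUC is the trapezoid over
  (1 − specificity, sensitivity), which for this step curve equals the
  Mann–Whitney concordance probability with ties counted ½ — both routes
  are implemented and cross-checked.
* **Cutoff selection** — maximize Youden's J = sensitivity +
  specificity − 1. "Best combination of sensitivity and specificity" names
  no criterion; J is the standard choice. Ties break toward higher
  sensitivity (missing a death is the costlier error here), then toward
  the lower threshold.
* **2×2 tests** — Pearson χ² without continuity correction by default
  (`correction=True` gives Yates); the uncorrected form is what reproduces
  the published group-comparison p-values from reconstructed counts. A
  zero margin raises rather than returning a meaningless statistic. The
  Fisher exact companion sums hypergeometric probabilities of all tables
  (fixed margins) no more probable than the observed one, with a 1e−9
  relative tolerance for probability ties.
* **t tests** — pooled-variance Student form by default (the two-sample
  t test without qualification), Welch behind a flag. Zero pooled variance
  returns (0, 1) for equal means and a signed infinite statistic for
  unequal ones.
* **Percentages** are rounded half-up (`pct`), matching the one-decimal
  reporting convention of clinical tables; raw numerators and denominators
  are always carried alongside in reports.

Tail probabilities (χ², t, hypergeometric pmf) come from scipy; every
statistic and decision rule above is implemented in this package and
tested against brute-force oracles (pairwise concordance, exhaustive
threshold scans, exact integer hypergeometric enumeration) and against
scipy/sklearn as independent implementations.

## Synthetic cohort generator

`generate_cohort` emulates the structure of a 77-patient prospective LHI
cohort; it is a pure function of (params, seed).

* **Group** ~ Bernoulli(0.429) for complete infarction. CMCA patients get
  all three territories (fraction 1.0); IMCA patients get a random pair of
  territories and a fraction uniform on [0.5, 0.95].
* **CT signs**, (CMCA, IMCA) prevalences: >1/3 hypodensity 0.488/0.159,
  HMCAS 0.5455/0.25, brain edema 0.5455/0.2955 — the published marginals.
  The hypodensity CMCA value 48.8% is not an integer fraction of 33
  (16/33 = 48.5%); the printed value is used as the generative probability
  since the true denominator is unknowable from the tables.
* **Risk factors**: hypertension 0.688 in both groups (the published
  overall rate; no group difference was reported). The remaining
  prevalences are not published per group and were fixed once at values
  realistic for an elderly East-Asian LHI cohort: CHF 0.10, diabetes 0.40,
  prior stroke/TIA 0.25, atrial fibrillation 0.40, smoking 0.35,
  hypercholesterolemia 0.35, coronary artery disease 0.15.
* **Age** ~ Normal(70.7, 12.6²) rounded and clipped to the study range
  40–94, which yields the age ≥ 75 rate organically (~37%).
* **NIHSS**: admission ~ Normal(20.3, 5²) / Normal(15.6, 5²) by group,
  rounded and clipped to [0, 42]; day 5 = admission + a group increment
  whose mean hits the day-5 targets (20.8 / 14.6) with sd 3, so stroke in
  progression arises organically instead of being drawn. The standard
  deviations are not published; sd 5 (cross-section) and sd 3 (5-day
  change) are plausible clinical spreads and are configurable. Because
  the day-5 value is rounded, the effective threshold for a ≥ 2-point rise
  is an increment ≥ 1.5, which (with stroke-related deaths) puts the
  emergent progression rate somewhat above the published 33%/14% — only
  the means are calibration targets.
* **Mortality** ~ Bernoulli with log-odds −3.542 + 1.5 · (mortality-score-2
  total). The slope is a design choice (a strong per-point effect, the
  minimal generative link for a score asserted to separate deaths); the
  intercept was solved once by root-finding on a 4·10⁵-draw simulation so
  overall mortality is 0.117 at the defaults. 90% of deaths are marked
  stroke-related. Group-wise mortality comes out ≈ 21.5% / 4.4% (published
  24.2% / 2.3%) — with binary features conditionally independent given
  group, the exact group split of deaths is not reproducible and only the
  overall rate is calibrated.
* **Correlation** — binary features are conditionally independent given
  group (only marginals are published). `ct_sign_correlation` switches on
  a shared-Gaussian-factor copula across the three CT signs for robustness
  experiments; default off.

What passing tests show about real data: the generator reproduces the
published *marginal* structure, so it validates the scoring arithmetic,
the ROC machinery and the pipeline plumbing end to end. It does not carry
the real cohort's joint dependence between signs, severity and outcome, so
synthetic AUCs and sensitivities are not estimates of the published ones
and are never asserted against them.

## Numerical and degenerate-input choices

* ROC requires both label classes; one-class input raises
  `DegenerateInputError` and the pipeline omits that ROC with an explicit
  notice instead of failing the whole report.
* Specificity inside `roc_curve` is computed with the same TN/(TN+FP)
  arithmetic as `sens_spec`, so operating points agree bit-for-bit.
* `fisher_exact` returns exactly 1.0 when every table is included in the
  two-sided sum (guarding float accumulation below 1).
* CSV round-trips use `float_precision="round_trip"`; a written cohort
  reads back equal to the records that produced it.
* Report provenance carries the config hash, seed and package version.
  A wall-clock timestamp would break bit-identical reproduction, so it is
  None unless explicitly requested (`lhirisk analyze --timestamp`).

## Problem sizes

Calibration checks use n = 10 000 draws, parameter recovery n = 20 000,
the study-size determinism and mortality-bracketing checks n = 77 (the
latter over 1000 seeds), and the exhaustive Fisher validation covers every
2×2 table with positive margins and total ≤ 40 (> 10⁵ tables). These
sizes put Monte-Carlo noise well inside the asserted tolerances
(±0.02 on prevalences ≈ 3·√(p(1−p)/n) at n = 20 000, ±0.5 on NIHSS means).

## Limitations

* Image interpretation is out of scope: the CT signs enter as booleans.
* No survival-time modelling, treatment-effect estimation, or external
  validation harness; laboratory variables are not modelled.
* The published per-patient table of the nine decedents is not printed in
  full and is not reproduced.
* The published P = .03 for the group mortality comparison (8/33 vs 1/44)
  is not reproducible by either the uncorrected χ² (.003) or Fisher
  (.004); the test used for that cell is unknown, and the pipeline simply
  reports its own χ² there.
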