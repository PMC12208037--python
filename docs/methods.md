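# Methods

## The validation problem

An EHR alert (BPA) decides, from structured fields only, whether an ED
patient with a routine lab order is eligible for HbA1c diabetes screening:
age ≥ 45, or age ≥ 18 with BMI ≥ 25 kg/m²; no diabetes history; no HbA1c
result within 3 years. Manual chart review — which also sees free text,
scanned documents and out-of-network records, and which disqualifies
patients in whom HbA1c is diagnostically unreliable (pregnancy, sickle-cell
anemia, HIV) — provides the reference label *should the alert have fired*.
Crossing decision with label per visit gives a 2×2 from which the usual
diagnostic test characteristics follow.

## Generative model for synthetic cohorts

Each visit draws independently (single `numpy` Generator, fixed per-field
stream order: lab order → age → chart BMI → visit-BMI-missing mask →
no-BMI-on-file mask → structured diabetes → chart-only diabetes → structured
HbA1c → chart-only HbA1c → exclusion condition → stratum → sex → insurance;
identical parameters + seed reproduce a byte-identical cohort):

- **age** ~ truncated normal (default mean 48 y, SD 17.9 y, floor 18 y),
  floored to whole years. The truncated normal is the minimal assumption
  given only a mean/SD; the floor encodes the adults-only cohort.
- **BMI** ~ truncated normal (default mean 30.1, SD 8.8, floor 12 kg/m² — a
  physiologic lower bound). One value per visit, recorded as `chart_bmi`
  (what a reviewer verifies from the visit vitals). The algorithm's inputs
  `visit_bmi` and `most_recent_bmi` equal that value but are independently
  *missing* with probabilities `p_visit_bmi_missing` and `p_no_bmi_on_file`
  (reporting-extract failure and no historical BMI on file, respectively).
  When both are missing, the engine cannot evaluate the BMI arm — the
  model's only false-negative mechanism.
- **history flags**: structured flags are Bernoulli; chart flags are the
  union of the structured flag and an independent chart-only Bernoulli
  (`p_chart_only_*`). The chart view is therefore a superset of the
  structured view by construction (a structured diagnosis code or lab result
  is always discoverable by the chart search), which the property tests
  assert on every generated record.
- **exclusion condition**: one categorical draw (`none`/pregnancy/
  sickle-cell/HIV), independent of the eligibility fields since no joint
  structure is reported; default total prevalence 3%, split 50/30/20 —
  a choice reflecting the predominance of pregnancy among these conditions
  in an ED population. Pregnancy forces female sex.
- **stratum, sex, insurance** use the validation cohort's exact count
  fractions (e.g. 763/2963 Hispanic). The published percentage roundings sum
  to 100.1%; the count fractions sum to 1 exactly.

Default `p_lab_ordered` = 2963/3850 ≈ 0.77: analyses condition on the
lab-ordered subpopulation, which is the study population.

### Expected confusion cells (closed form)

Writing e₄₅ = P(age ≥ 45), e_b = P(BMI ≥ 25), m = `p_visit_bmi_missing` ·
`p_no_bmi_on_file`, q_s = (1−a)(1−c) for the structured history rates a, c,
and q_x = (1−b)(1−d)(1−x) for the chart-only rates b, d and exclusion
prevalence x, the per-lab-ordered-visit cell probabilities under the default
missing-BMI reading are

    TP = [e₄₅ + (1−e₄₅)(1−m)·e_b] · q_s · q_x
    FP = [e₄₅ + (1−e₄₅)(1−m)·e_b] · q_s · (1−q_x)
    FN = (1−e₄₅)·m·e_b · q_s · q_x
    TN = 1 − TP − FP − FN

(the engine fires on clean structured records whose visible demographics
qualify; the chart search and the exclusions turn a fraction 1−q_x of those
into false positives; misses occur exactly when only the chart knows the
qualifying BMI). A test enumerates the full joint outcome tree of all
boolean fields through the *scalar* engine and reviewer and confirms these
formulas to 1e-12, and a 50,000-visit simulation reproduces them within
Monte-Carlo error.

### Calibration to a target 2×2

`calibrate_to_cells` inverts the formulas. With A = (1−e₄₅)e_b and
B = e₄₅ + A fixed by the age/BMI distributions, the normalized target cells
give

    q_x = TP/(TP+FP),   q_s = (TP+FP)(TP+FN)/(TP·B),   m = FN·B/(A·(TP+FN)).

Targets needing q_s > 1 or m > 1 are infeasible and raise. The 2×2
identifies only these three products, so the splits are conventions: the two
structured rates are set equal (a = c = 1−√q_s), the exclusion prevalence is
kept from the base parameters (capped at 1−q_x) and the two chart-only rates
absorb the rest symmetrically; the BMI-missingness factors keep the base
`p_no_bmi_on_file` when possible, otherwise both become √m. Calibrating to
the validation study's cells forces m ≈ 0.92 — implausibly high as a
literal missingness rate, because BMI invisibility is the model's *only*
miss mechanism, whereas the real algorithm also missed through input errors
the model does not represent. The calibrated cohort nonetheless reproduces
the study's operating point exactly in expectation, which is what the
downstream statistics consume.

## Engine and reference-standard conventions

- All threshold comparisons are inclusive (≥), and under-18 patients can
  never trigger regardless of BMI.
- Missing visit BMI falls back to the most recent BMI on file. When no BMI
  is available at all, the default reading (`missing_bmi_policy="age-alone"`)
  still lets the age-≥ 45 arm fire; the alternative strict reading
  (`"suppress"`), under which any missing BMI suppresses the alert, is a
  config switch because the deployed behaviour is ambiguous. Missing age
  always suppresses.
- The 3-year HbA1c lookback is consumed as a precomputed boolean;
  `hba1c_within_lookback` documents the preparation rule (half-open window
  of 3 × 365.25 days ending at the visit date).
- The reference standard substitutes the chart history flags and the
  chart-verified visit BMI, applies the *same* demographic rule and
  missing-data reading, and additionally rules out visits with an
  HbA1c-unreliability condition. Alerts for such visits count against the
  algorithm (false positives); silent visits with such conditions count as
  true negatives — the consistent completion of "counted against".
- The lab-order requirement applies to both views; every statistic is
  computed on the lab-ordered subpopulation.
- The chart history flag is a single boolean covering diabetes *and*
  prediabetes documentation; the generator does not distinguish them.

## Verification sampling and weighting

All alert-positive visits are verified (weight 1). Within each
race/ethnicity stratum of the negatives, round(fraction · n_stratum) visits
(half away from zero) are drawn without replacement and weighted
n_stratum / n_sampled, so weights sum exactly to each stratum's population —
making every weighted cell an unbiased (Horvitz–Thompson) estimate of its
census count; a 200-replicate test confirms this. A fraction that rounds a
nonempty stratum to zero raises a design error. With the study's per-stratum
negative counts, a fraction of 0.1019 yields exactly the 221 verified
negatives of the original design.

Weighted cells are treated as frequency counts downstream: unit weights
reduce every estimator exactly to its unweighted form, and rescaling all
weights changes no proportion. SEs computed from weighted cells therefore
read the extrapolated counts as real observations; for the synthetic
census-mode checks this is exact, for verification-sample mode it
understates the sampling noise of the weighted cells (a known property of
the simple binomial SE, retained because it is what the validated formulas
use).

## Statistical conventions

- Proportions: estimate p = k/n on the relevant margin, SE = √(p(1−p)/n),
  Wald CI truncated to [0,1]; Wilson intervals available
  (`method="wilson"`).
- Likelihood ratios: LR⁺ = se/(1−sp), LR⁻ = (1−se)/sp. Delta-method
  variance on the log scale — Var ln LR⁺ = (1−se)/(se·n₊) + sp/((1−sp)·n₋)
  and symmetrically for LR⁻ — back-transformed to a natural-scale SE
  (SE = LR·√Var ln LR) and natural-scale Wald CI, the convention that
  matches the published SE/CI pairs; log-scale intervals are a config
  option. Degenerate tables yield ±∞/0 estimates with NaN uncertainty
  rather than raising. A 10,000-resample multinomial bootstrap agrees with
  the delta SEs within 10%.
- Bayes predictive values: PPV = se·π/(se·π+(1−sp)(1−π)) and
  NPV = sp(1−π)/(sp(1−π)+(1−se)π); at the sample prevalence they reproduce
  the table's direct PPV/NPV to machine precision.
- AUC: a weighted logistic model (statsmodels GLM, variance weights) of the
  binary outcome *alert behaved correctly* on continuous age, continuous
  BMI (chart-verified, falling back through the structured fields, median
  imputation as a last resort) and the two binary chart history flags. The
  AUC is the weighted concordance of the linear predictor (ties count ½,
  computed via `sklearn.metrics.roc_auc_score`; an O(n²) pair loop in the
  tests confirms exact agreement). CI via seeded bootstrap stratified by
  outcome class (2,000 resamples by default), refitting the model per
  resample. Complete separation is flagged with a warning and the fit falls
  back to a barely-regularized logistic model whose scores still rank the
  outcomes.
- Acceptability: sensitivity + specificity ≥ 150%; LR⁺ in [5, 10]
  acceptable (above: strong); LR⁻ in [0.1, 0.2] acceptable with (0.2, 0.5]
  labelled *informative*; AUC < 0.7 poor, [0.7, 0.8) acceptable, ≥ 0.8
  excellent (boundaries to the upper band).
- Report display rounds half away from zero at 2 decimals.

## Problem sizes

The shared recovery checks use one 50,000-visit calibrated cohort
(≈ 38,500 lab-ordered); the sampling-unbiasedness check uses a fixed
20,000-visit study population with 200 sampling replicates; oracle
comparisons for the AUC use n ≤ 200 where the O(n²) loop is exact and
cheap. The acceptance script bootstraps the simulated AUC with 200
resamples; pipeline defaults keep 2,000.

## What passing tests do and do not show

The generator reproduces the *marginal* and *operating-point* structure of a
real validation cohort: demographic mix, eligibility prevalence, the
confusion-cell proportions, and through them every downstream statistic. It
does not emulate: correlation between age/BMI and histories or insurance,
visit-level longitudinal structure, free-text notes (discordance is modeled
directly at the flag level), HbA1c *values*, input errors other than BMI
invisibility, or reviewer disagreement (the chart view is treated as exact
truth). Agreement of the simulated AUC (≈ 0.73–0.74) with the published one
is therefore a consistency observation, not a validation of the AUC model on
real data. Results on real cohorts depend on how well those simplifications
hold.
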