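# Methods

This note records the scoring conventions, statistical procedures,
synthetic-data model and design choices behind `hlhscreen`, and what the
package's tests do and do not demonstrate about real cohorts.

## Cohort model and censored ferritin

A patient record carries boolean clinical flags that are deliberately
three-valued (`True`/`False`/missing): in retrospective audits a feature
that was never assessed is not the same as one recorded absent, and the
two scoring engines make that distinction explicit. Ferritin is a
`CensoredValue` — the assay used by the emulated laboratory saturates at
16,500 ug/L, so a stored value can mean "exactly this" or "at least this".
Throughout the package a censored ferritin **contributes its ceiling value**
to means, comparisons and band assignments (`numeric_ferritin`, policy
`"ceiling"`). This is the only policy under which the fixture's published
group mean (14,706 ug/L) is reproducible, and it is conservative: it
*understates* the true mean of a censored group. An `"exclude"` policy is
available for sensitivity analyses. In input files a `>` prefix
(`>16,500`) or equality with the configured ceiling marks censoring;
thousands separators are stripped; serial presentations of one patient are
reduced to the peak-ferritin row, ties broken by record order.

## HScore conventions

Band boundaries follow the published scoring table, with boundaries
assigned as printed where the table is unambiguous and documented choices
where it is not:

- temperature: `t < 38.4 → 0`, `38.4 ≤ t < 39.4 → 33`, `t ≥ 39.4 → 49`
  (the printed bands overlap at 38.4 and 39.4; the higher band wins at
  each shared boundary);
- ferritin: 2,000 and 6,000 inclusive in the middle band; triglycerides:
  1.5 and 4 inclusive in the middle band;
- cytopaenia lineages use haemoglobin ≤ 90 g/L, platelets ≤ 100×10⁹/L,
  neutrophils ≤ 1×10⁹/L (the checklist thresholds, reused because the
  HScore column does not restate them; configurable in `HScorePolicy`);
- AST takes precedence; ALT ≥ 100 is consulted only when AST is missing —
  the substitution audits need because AST is rarely requested;
- a documented fever with no charted temperature scores 33 points
  (`documented_fever_points`, configurable);
- missing inputs score 0 under the default policy (`on_missing="zero"`);
  an unrequested test cannot contribute points. `on_missing="error"` is
  available for prospective use where missingness should halt scoring.

Positivity defaults to `total ≥ 169`; the strictly-greater reading is
selectable (`strict_cutoff`) and indistinguishable in practice, since no
observed positive scored exactly 169.

**Probability bands.** The score→probability mapping ships as a YAML table
of contiguous intervals anchored at the eleven observed (score, band)
pairs (174→"54" … 321→">99"). Interval boundaries *between* anchors are
interpolated at midpoints and flagged `interpolated: true`; only the
anchored pairs are guaranteed. Scores below 169 fall in a `"<54"` sentinel
band; out-of-range lookups clamp to the end bands.

## Revised HLH-04 conventions

Eight criteria, positive at ≥ 5. The triglycerides/fibrinogen pair awards
one point maximum. Boundary values qualify as printed (ferritin exactly
500, triglycerides exactly 3, fibrinogen exactly 1.5, sCD25 exactly
2,400). Hepatomegaly plays no role. Missing inputs leave a criterion unmet
under the default policy, so in cohorts where NK activity and sCD25 are
never assayed the attainable maximum is 6/8 while the threshold stays at
5 — this matches retrospective practice but is an assumption users should
be aware of: whether such cohorts "should" be scored out of 6 is not
decidable from the scoring table, and the policy object is the place to
change it.

## Screening rules

Rules are conjunctions of a **strict** ferritin cutoff (`ferritin >
cutoff`, censored values comparing as the ceiling), a fever requirement
and a strict platelet cutoff (`platelets < cutoff`). Missing required
inputs fail the rule by default (`missing=fail`) — a screen that cannot
fire on unknown data is the conservative choice — with an `exclude` policy
that drops the patient from the denominator instead. The default
reference standard is HLH-04 positivity: in the replicated audit the
printed rule sensitivities (94.1%, 82.4%) are integer fractions of the 17
checklist positives (16/17, 14/17), not of the 14 HScore positives. The
published specificities (68.3%, 59.6%, 81.6%, 72.7%) are **not**
reconstructible as integer fractions of any fixed denominator the
published counts allow, so the package treats them as approximate
descriptions — most plausibly reflecting undocumented handling of
patients with missing fever/platelet data — and never asserts them as
point targets. `rule_grid` evaluates a cutoff grid and ranks by Youden's
J (ties: lower ferritin cutoff, preferring the more sensitive screen).

## Replication statistics

- **Chi-squared**: Pearson Σ(O−E)²/E on 2×2 tables, 1 df, *no* Yates
  correction, no minimum-expected-count refusal (a
  `SmallExpectedCountWarning` is raised instead). These are the
  conventions of the simple online calculators the replicated audit used,
  and all eleven of its printed statistics (12.6515 … 3.639) reproduce
  exactly from the printed counts under them. Fisher's exact test is
  available as an explicitly non-replication alternative.
- **Mann-Whitney U**: midranks for ties; normal approximation with
  tie-corrected variance; z is negative when the first (below-cutoff)
  group is stochastically smaller; two-tailed p. A pooled sample with all
  values identical has zero variance: U is returned with z = p = NaN and
  a warning.
- **Mean CI**: mean ± z·σ/√n with σ the *population* (divide-by-n) SD —
  again the replicated tool's convention; the divide-by-(n−1) choice does
  not reproduce the published interval. `population_z_ci` returns raw
  floats. For whole-number display, `population_z_ci_display` rounds the
  mean and the margin of error *first* and forms the endpoints from the
  rounded pair: the published intervals (12,930–16,482 around 14,706;
  10,668–15,060 around 12,864) are each exactly centred on their rounded
  mean, which identifies this as the convention used, and direct endpoint
  rounding differs by 1 in the upper bound.
- `build_table3` splits a cohort at the HScore cutoff and rebuilds the
  group-comparison table: mean peak ferritin by Mann-Whitney, then eleven
  binary features by chi-squared. The feature definitions follow the
  comparison table's own wording (strict `<`/`>`), which differs in
  boundary treatment from the scoring engines' `≤`/`≥`; both are kept as
  printed in their respective contexts.

## Synthetic cohort generator

The generator emulates a 120-patient hyperferritinaemia cohort with a
latent HLH-like subgroup at prevalence 14/120. Within each group the
binary features are independent Bernoulli draws at the observed per-group
frequencies (e.g. fever 12/14 vs 37/106; splenomegaly 10/14 vs 18/106),
and each deranged/normal indicator is realised as a uniform lab value
inside/outside its band. Ferritin is log-normal per group, truncated below
at the 5,000 ug/L inclusion floor (inverse-CDF sampling) and censored at
16,500. The log-normal parameters were solved once, analytically, so the
*censored* group means equal the published 14,706 and 9,260 ug/L and the
positive group's ceiling-exceedance probability equals the observed 10/14:
positive group μ = 10.17692, σ = 1.39123; other group μ = 8.74527,
σ = 0.6. Test-request rates mirror the audit (triglycerides 20/120,
fibrinogen 78/120, AST 5/120; ALT and blood counts always available) and
are applied as masks independent of the values. NK activity and sCD25 are
always missing. A single `numpy.random.default_rng(seed)` stream drives
everything, so identical seeds give byte-identical serialised cohorts.

**What the generator does not emulate.** Features are independent within
group, because only marginal frequencies were published; real HLH features
are positively correlated (cytokine-driven), so the synthetic HScore
distribution is narrower in the positive group than reality's. Missingness
is independent of severity, whereas clinicians plausibly request
fibrinogen *because* a patient looks like HLH. Ferritin is reported at
peak only, with no trajectories. Consequently, passing truth-recovery
tests show the *pipeline* is correct and well calibrated under the stated
model — they do not validate the scores' clinical operating
characteristics on real patients. Under the default configuration the
number of score-positive patients per 120 varies widely across seeds
(roughly 2–16, median ≈ 9); the study's observed 14 lies inside this
distribution but above its median, consistent with feature independence
diluting positive-group scores.

## Problem sizes and numerical checks

The exhaustive engine oracles enumerate all 3,888 HScore band combinations
and all 256 HLH-04 criterion patterns. The Mann-Whitney implementation is
checked against a pairwise-count oracle on every sample-size pair up to
8×8 and against an independent asymptotic implementation at larger n. The
chi-squared type-I error check simulates 10,000 null 2×2 tables (two
Bernoulli(0.3) groups of 60 — group sizes of the order of the audit's,
with a mid-range feature rate) and requires the rejection fraction at
α = 0.05 to lie within 3 binomial standard errors of 0.05. Screening-rate
recovery uses a synthetic cohort of 10,000 so that binomial 95% bounds
around the configured rates are ±2 percentage points on the positive
group. Marginal-calibration tests use 8,000–20,000 patients at 3-SE
tolerances.

## Known limitations

- The probability-band boundaries between anchored scores are
  interpolations, not the original regression's values.
- The published screening specificities cannot be checked exactly (see
  above); nor can the checklist-positive group's Mann-Whitney z or its
  mean ferritin, which depend on 106 unpublished patient records.
- The generator's independence assumption makes joint-feature statistics
  (e.g. the co-occurrence of fever and thrombocytopaenia) unrealistic;
  configure `GroupRates` per group, but correlation structure itself is
  not modelled.
- The HLH-04 engine implements the revised adult-oriented checklist only;
  paediatric/genetic criteria variants are out of scope.
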