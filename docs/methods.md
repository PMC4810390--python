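# Methods

This note documents the models, procedures and design choices behind
`biobank_portal`, in the order the data flows: storage and querying,
de-identification, Charlson scoring, phenotyping, and the synthetic
cohort generator the tests run against.

## Star-schema store and panel queries

The store keeps one tall fact table of (patient_id, concept_code,
start_date, value, encounter_id) observations plus patient, note and
ontology dimension tables — the classic clinical-warehouse star schema.
Concept codes are namespaced (`ICD9:`, `MED:`, `LAB:`, `PROC:`, `NLP:`,
`SURVEY:`, `CONSENT:`, `SAMPLE:`, `GENO:`, `PHENO:`); files are
RFC-4180 CSV with ISO-8601 dates, and the load/write cycle is the
identity on all four tables.

Updates model a weekly refresh: they add new patients and facts, never
modify or delete existing rows (facts are append-only; nothing in the
workflow requires retraction), drop exact-duplicate fact rows so that
re-applying a delta is a no-op, and reject a "new" patient row whose
birth date contradicts the stored record.

Query semantics: terms inside a panel OR together; panels AND together.
The minimum-occurrence count applies per panel across all its expanded
terms combined — a patient with one fact of term A and one of term B
satisfies "≥ 2 occurrences" of the panel {A, B} — which reads the panel
as a single concept group rather than per-term thresholds. Date windows
are closed intervals evaluated on true (unshifted) dates; only exports
are obfuscated. Exclusion (NOT) panels are not implemented, and
aggregate counts are exact: the only obfuscations in this toolkit are
date shifting and zip truncation. Ontology paths are "/"-separated and
case-sensitive; expanding a folder yields the union of codes over all
descendant leaves.

## Coded limited dataset

Three parameters matter:

* `secret_key` — the HMAC key behind patient codes and date offsets.
  Rotating the key re-codes the whole population; keeping it fixed
  makes every refresh consistent with previous exports.
* `max_shift_days` — default 182 (about ±6 months). The offset is
  uniform on {−182, …, −1, +1, …, +182}; zero is excluded so every date
  provably moves. A ±6-month window preserves year-level analyses
  (ages computed from shifted dates are off by at most one year) while
  still decoupling exported dates from calendar reality.
* zip truncation to 3 digits, the coarse-geography convention for
  limited datasets.

Codes and offsets are HMAC-SHA256 outputs, not entries in a stored
crosswalk, so no linkage table exists to leak and determinism across
refreshes is structural. Within a patient all dates share one offset,
so intervals between clinical events are exactly preserved — the
property longitudinal analyses actually need. Charlson ages are
computed from true dates before any shifting; only emitted values are
obfuscated.

## Charlson age-comorbidity index

The scorer maps each patient's ICD-9 facts into 17 weighted categories
(weights 1×10, 2×4, 3, 6, 6), adds an age-band score (<50 → 0, one
point per decade from 50, capped at 5 for 90+), and converts the index
X through Y = e^(0.9X), Z = 0.983^Y to a 10-year survival probability.
Survival is held as a fraction internally and formatted as a
two-decimal percentage for display, which reproduces the standard
printed table (98.30 / 95.87 / 90.15 / 77.48 / 53.39 / 21.36 / 2.25 and
≤ 0.009 from X = 7).

Two decisions the formula itself does not dictate:

* **Severity dominance.** When both members of a graded pair are
  present (diabetes with/without chronic complications, mild vs
  moderate-or-severe liver disease, any malignancy vs metastatic solid
  tumor) only the higher-weight category counts. Double-counting would
  make survival non-monotone in a patient's recorded disease severity.
* **Code lists as data.** The ICD-9 → category lists ship as an
  editable CSV resource using standard administrative-data groupings
  (3-digit and 4-digit prefixes, matched at dot boundaries). Sites
  that curate their own lists can point the loader at a replacement
  file; the synthetic generator draws from the same resource, so the
  scorer and the generator can never silently disagree.

`healthy_controls` filters a patient set by a survival floor, and
`tag_healthy_bands` writes banded `PHENO:healthy_survival_ge{90,75,50}`
facts so "relatively healthy controls" become ordinary query terms.

## Phenotyping pipeline

The pipeline turns an anchor-code cohort (patients with ≥ 1 anchor
diagnosis fact) into a calibrated classifier:

1. **Features.** Counts of coded concepts and of narrative concept
   mentions, transformed log(1+count) — count data in cumulative
   records are heavy-tailed, and the log transform keeps a handful of
   prolific utilizers from dominating the fit — then standardized
   inside the fitting routine.
2. **Narrative extraction.** Case-insensitive whole-word dictionary
   matching of concept synonyms over tokenized notes. A mention is
   discarded as negated when a cue — "no", "denies", "negative for",
   "without", "ruled out" — ends within 6 tokens before it. This is a
   deliberately small surface: no parsing, section detection or
   concept normalization, which real deployments get from a clinical
   NLP system.
3. **Gold standard.** A simple random sample of the anchor cohort,
   labeled by a pluggable labeler (chart review in real use; the
   generator's truth in tests). When the requested size exceeds the
   anchor cohort — which happens at the default error rates for a
   1,000-patient cohort, whose anchor cohort runs ~130 — the whole
   anchor cohort is reviewed instead.
4. **Adaptive LASSO.** Stage 1 is a ridge-penalized logistic fit
   (C = 1) giving pilot coefficients β̃ — ridge rather than plain MLE so
   collinear feature blocks stay finite. Stage 2 is a weighted-L1
   logistic fit with per-feature penalty w_j = 1/|β̃_j|^γ, γ = 1
   (features the pilot zeroes get a large finite weight of 1e6),
   implemented by rescaling columns and applying a plain L1 penalty.
   The penalty λ is chosen from a log-spaced grid of 50 values in
   [1e-4, 1e2] by stratified 5-fold cross-validated deviance, ties
   toward the sparser (larger) λ. Coefficients are mapped back to the
   original log-count scale. Exactly duplicated feature columns are
   collapsed before fitting (the clone gets coefficient 0), which makes
   predictions invariant to redundant columns instead of letting the
   pilot split their weight arbitrarily.
5. **Threshold.** The smallest observed-probability threshold whose
   specificity on the labeled set reaches the floor (default 0.95);
   since sensitivity is non-increasing in the threshold this also
   maximizes sensitivity under the constraint. Thresholds are taken
   from the observed probabilities, so at least one patient is always
   classified positive; an unattainable floor raises an error carrying
   the maximum achievable specificity. Specificity is the default dial
   (a target-PPV criterion can be imposed by the caller scanning the
   same probabilities); lowering the floor buys sensitivity, which is
   how a study trades precision for power.
6. **Application.** Every anchored patient is scored; positives
   receive a `PHENO:<name>` fact carrying the probability, making the
   phenotype queryable and refreshable as the store grows.

Sensitivity and PPV are computed over the scored population — the
anchor cohort. True cases that never received an anchor code are
invisible to the pipeline by construction and are outside the
denominator; at the default 5% ICD false-negative rate this overstates
whole-population sensitivity by at most that factor.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
with defaults chosen as the study conditions for the test suite:

* prevalence 0.10; anchor-code false-positive rate 0.04 (non-cases
  acquiring the code) and false-negative rate 0.05 (cases never coded),
  which gives an expected anchored-to-true-case inflation ratio of
  [p(1−fn) + (1−p)fp] / [p(1−fn)] ≈ 1.38 — the qualitative pattern in
  which ICD-alone counts always exceed validated-phenotype counts;
* informative features as Poisson counts whose log-rate is shifted for
  true cases: anchor-code extra count with base rate 2.0 and effect
  β = 1.2, narrative-concept mentions with base rate 2.0 and β = 1.0.
  The base rates reflect cumulative longitudinal records — a billing
  false positive carries ~3 anchor codes in total where a true case
  carries ~7.6, and ~2 vs ~5.4 concept mentions across about five
  notes — rather than single-encounter snapshots;
* 8 label-independent Poisson(0.5) noise features;
* notes assembled from sentence templates with planted mentions,
  20% of them negated via explicit cues; positive-mention sentences
  precede negated ones inside a note so no cue can fall inside the
  negation window of a planted positive, keeping the bookkeeping
  exactly equal to what the extractor should find;
* comorbidities drawn per Charlson category at low chronic-disease
  rates from the same code resource the scorer uses (the anchor code is
  excluded from comorbidity emission so anchor bookkeeping stays
  exact); demographics, zips, recontact (90%), sample types
  (DNA 95% / plasma 85% / serum 85%), genotyped flag (35%);
* every stored patient is consented (a `CONSENT:biobank` fact), and
  flags are mirrored as queryable facts;
* each fact carries a distinct encounter id: two generated observations
  are never the same event, so append-only deduplication on refresh
  remains exact.

The same seed yields byte-identical files. What the generator does
*not* emulate: real clinical language (templates, not prose),
misspellings and abbreviation noise, correlated comorbidity structure,
informative missingness, visit-level temporal patterns, or genotype
content (genotyped status is a flag). Tests passing on this generator
therefore demonstrate the pipeline's statistical machinery — selection,
calibration, bookkeeping — not robustness to real clinical text.

## Problem sizes and numerics

The test suite runs cohorts of 200–5,000 patients and 20–50 pipeline
replicates per property, sizes at which every distributional assertion
(3-standard-error bands, ≥ 90%-of-replicates criteria) is comfortably
powered while the whole suite stays fast. Logistic fits use lbfgs
(ridge, tol 1e-10) and liblinear (L1, tol 1e-8); probabilities are
clipped at 1e-12 in deviance computations; undefined metrics (zero
denominators) are reported as `None`, never coerced to 0. The
Monte-Carlo check of the inflation ratio uses n = 20,000 and a
delta-method standard error around the closed form.

## Known limitations

* ICD-9 only; no ICD-10 or procedure-code mappings in the Charlson
  resource.
* The NLP stage is dictionary matching with a fixed cue list and token
  window; clause boundaries, hypotheticals ("if erosions develop") and
  family history are not modeled.
* The query engine has no NOT panels and no visit-level or temporal
  sequencing constraints.
* De-identification here is a coded limited dataset with extra
  obfuscation, not full Safe-Harbor de-identification; free-text notes
  are never exported at all.
* Adaptive-LASSO tuning (γ = 1, ridge pilot, 5 folds, the λ grid) is a
  reasonable default set, not the result of a tuning study.
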