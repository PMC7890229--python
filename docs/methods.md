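# Methods

## Data model

A patient record is a de-identified sequence of (ICD code, age-in-days)
events. Age in days replaces calendar dates deliberately: the only
temporal operations the algorithm needs are ordering and one age
threshold, so birth dates never enter the system. ICD-9 and ICD-10
codes share a single namespace of normalized strings (uppercase,
periods stripped); no cross-version mapping is attempted — filters
learned from a mixed-version sample simply contain codes of both
versions. Code-shape consistency with the declared version (ICD-9
starts with a digit or E/V, ICD-10 with a letter then a digit) is
enforced at ingest. Sub-day ordering of same-day events is undefined
and never relied upon; duplicate (code, age) events are retained, as
all downstream logic is set- or minimum-based.

"Group" criteria (e.g. the H90 hearing-loss family) are string-prefix
matches; ranges such as Q90–Q99 are expanded into explicit prefix sets
when criteria are loaded, so matching itself is always exact-or-prefix.

## Broad search

Inclusion requires at least one of the six LD-symptom codes; F80.9 is
deliberately absent from the set. Exclusion codes disqualify a record
wherever they occur in the timeline — they are record-level, not
interval, criteria, reflecting a conservative reading of codes like
chromosomal-testing entries. "Pediatric onset" means the *first* LD
code falls strictly before 6,574 days (18 × 365.25, rounded); the
threshold is configurable. Rejection reasons are recorded with fixed
precedence (no LD code → exclusion code → adult onset) so audit trails
are deterministic.

## Filter training and classification

Raw code lists are per-category unions over labeled records.
Categories 1–3 are not date-restricted; Category 4's raw list keeps
only codes dated on-or-before each record's first LD code, because
trauma must precede the language disorder to define acquired LD. The
inclusive (≤) reading of "preceding" is used — trauma coded the same
day as the first LD code counts — and is applied identically at
training and classification time; a strict (<) variant is available via
`cat4_inclusive=False` / `--cat4-rule strict`.

Subtraction (F₁ = R₁, F₂ = R₂ − R₁, F₃ = R₃ − R₂ − R₁,
F₄ = R₄ − R₃ − R₂ − R₁) yields pairwise-disjoint filters; subtracting
previously computed filters instead of raw lists provably gives the
same sets, which a property test asserts. LD codes are not removed
from raw lists: whenever any Category-1 record exists they end up in
F₁, which is why unclassified (category 0) records cannot occur when
classifying the training distribution, only on genuinely novel data.
Category 0 is still emitted — never silently defaulted to Category 1 —
and excluded from the DLD cohort.

Classification applies priority 4 > 3 > 2 > 1, with Category 4
re-evaluating the date rule per event. Two exact structural guarantees
follow from the subtraction construction, for any labeled sample and
seed: (i) every Category-1-labeled record reclassifies as Category 1,
because all its codes are in F₁ and none can survive into F₂–F₄;
(ii) no inclusion-labeled (category 1/2) record is ever
algorithm-excluded (d = 0, exclusion concordance 100%), because F₃ and
F₄ exclude every code occurring in inclusion-labeled records. The
acceptance script recomputes both from scratch.

An independent brute-force classifier (full event × filter enumeration,
no early exit, separate priority re-derivation) serves as a test oracle
and is checked against the production path on 10,000 randomized
records.

## Validation metrics

All metrics reduce to the a/b/c/d confusion counts at the
inclusion/exclusion level, or to per-category agreement (the proportion
of reference-category-k records predicted k — the interpretation used
for the four per-category table values, reconciling them with the
binary TPR/TNR formulas). Zero-denominator metrics are reported as
N/A, never 0 or 1. Rendering rounds half away from zero to whole
percents (prevalence to one decimal); every rendered figure is
recomputed from raw counts, never from cached rounded values.

## Synthetic cohort generator

The generator emulates exactly the structure the algorithm exploits:

- a shared common-condition pool (every record draws 3–8 codes from
  it), plus disjoint characteristic pools for categories 2, 3 and 4;
- every qualifying record has its first LD code at an age uniform on
  1–18 years; Category-4 records carry 1–2 trauma-pool codes 0–365 days
  before (inclusive of day 0) the first LD code;
- Category-2 records receive, with probability 0.25, a trauma-shaped
  code strictly *after* the first LD code, drawn from a dedicated
  late-trauma namespace disjoint from the Category-4 pool — the rubric
  treats post-onset trauma as a Category-2 presentation, and keeping
  the namespaces apart preserves exact label recovery on leakage-free
  cohorts;
- with probability `leakage` (default 0.2) a record gains one code from
  another category's characteristic pool at a random age, which is the
  only mechanism that produces held-out misclassification;
- non-qualifying records violate exactly one broad-search criterion
  each (no LD code / a real exclusion code / adult onset), tagged in
  the ground-truth metadata.

Synthetic category codes live in an X99-prefixed ICD-10-shaped
namespace that cannot collide with real codes; the LD and exclusion
codes are genuine so the default broad-search criteria are exercised.
A single `numpy` generator seeded from the run seed drives everything;
identical configuration and seed give byte-identical CSV output.

Default cohort size is 50 records per category plus 30 non-qualifying
records — large enough that each characteristic pool (15–25 codes) is
essentially fully covered by training draws, small enough that the full
suite runs in seconds. Property tests that need exact held-out recovery
use 250 records per category (a 1,000-record cohort, split in half),
where pool coverage by the training half is complete; the
leakage-monotonicity check uses 40 records per category over four seeds
per leakage level.

What the generator does *not* emulate: realistic ICD marginal
frequencies, comorbidity correlation structure, coder noise in the
manual labels, records whose category is ambiguous even to humans, and
demographic structure. Passing tests therefore demonstrate the
algorithm's logical correctness and its structural training-set
guarantees, not clinical performance on real EHRs — on real data the
manual labels themselves are imperfect and category signals overlap far
more heavily.

## Estimator interface

The trainable core is exposed as a scikit-learn-style estimator
(`DLDPhenotyper`: `fit`/`predict`/`get_params`, fitted state in
`filters_`), since filter training is a fit and classification a
predict; X is a sequence of structured `PatientRecord` objects rather
than a feature matrix, so sklearn utilities that require numeric arrays
(e.g. `check_array`-based validation) do not apply, but cloning,
parameter handling and accuracy scoring compose normally. Broad search
and the metric suite are stateless and remain plain functions.

## Known limitations

- Codes never seen in training belong to no filter and are ignored at
  classification; on small training samples this degrades held-out
  accuracy even without leakage (incomplete pool coverage), and on real
  data it makes the method conservative by construction.
- A record whose only Category-4 filter codes occur after its first LD
  code falls through to categories 3/2/1 by ordinary membership; the
  fall-through order is a design choice.
- The discovery-prevalence formula n_DLD / n_total_pediatric is
  implemented exactly as defined; published prevalence figures that
  round differently are not "corrected" for.
- No NLP: clinical notes are outside the algorithm; labels are consumed
  as data, and chart review itself is out of scope.
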