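# Methods

## Problem setting

The package analyses the comorbidity structure of an EMR cohort: which
chronic conditions accompany an index disease (lung cancer, ICD-10 C34) in
patients aged 65+, which conditions dominate the burden, which combinations
co-occur far beyond chance, and how the co-occurrence graph decomposes into
subnetworks.  The unit of analysis is the *transaction*: the set of
comorbidity categories coded for one eligible patient.  All association
statements are about co-occurrence, not causation, and no statistical
significance testing of rules is performed — rule screening is by the
classical support/confidence/lift thresholds alone.

## Cohort eligibility and cleaning

A record is eligible when it carries an index code, is aged ≥ 65 (the
`min_age` parameter), and has non-missing case number, gender and hospital.
Records are deduplicated on the composite primary key (case number, gender,
age), keeping the first occurrence in file order.  Exclusions are counted
under a fixed reason precedence — missing field, no index code, under-age,
duplicate key; first match wins — so the exclusion report is deterministic
and satisfies exact conservation (input = kept + excluded).  Filtering is
idempotent.

Category mapping is exact-string ICD-10 lookup with no hierarchy collapsing:
I25, I25.1 and I25.5 are three distinct categories because the reference
rule set treats them as separate rule elements.  The index disease is
excluded from transactions — it is present in every patient by construction
and would be an uninformative, trivially frequent item.  The packaged
default catalog assigns one representative ICD-10 code to each of the 31
reference categories whose codes were not published.

## Synthetic cohort model

The generator is the package's substitute for undepositable patient data.
Its structure is the minimal one that keeps every rule metric analytically
computable:

- diseases are independent Bernoulli draws at configured marginal
  prevalences (defaults: the 31 reference category counts divided by 1510);
- *planted dependencies* then rewrite targets in list order: when all
  sources of a dependency are present, the target is redrawn as
  Bernoulli(conditional probability), overriding its marginal draw.
  A target may never be a source of an earlier dependency, so the overrides
  form a forward chain and the joint law factorises along the list;
- ages are uniform within bands (65–74, 75–84, 85–95, at the reference
  proportions 74.4/21.8/3.8%), gender is Bernoulli(0.602 male), and
  nationality/occupation/marital status are sampled from the reference
  demographic proportions;
- data-quality defects are drawn after the disease draws (so toggling them
  never changes clean records): a configurable fraction of records has one
  of {case number, gender, hospital} blanked, and a fraction of
  *uncorrupted* records is re-emitted with an identical primary key.
  Restricting duplication to clean records keeps the exclusion accounting
  exact (excluded = corrupted + duplicates).

`expected_rule_metrics` computes exact population support/confidence/lift
for any candidate rule by propagating the joint distribution of the
dependency closure of the queried labels through the override sequence —
an exhaustive enumeration over at most 2^k cells, guarded at k = 20
diseases.  This oracle is what planted-rule recovery is judged against.

What the generator does *not* model: hospital-level clustering, repeat
admissions, longitudinal visits, age- or gender-dependent disease risks,
and any dependence beyond the planted overrides.  Passing recovery tests
therefore demonstrates correctness of the mining machinery under a known
generative law, not robustness to the messier dependence structure of real
EMR data.

The bundled recovery scenario plants the reference cardiac triad:
P(ischemic cardiomyopathy | atherosclerotic heart disease) chosen so that
P(both sources) = 0.01/0.92 (reproducing the published rule's support of
0.01), then P(heart failure | both) = 0.92.  At n = 20 000 this yields
roughly 220 source-pair carriers and a confidence standard error of about
0.018, so recovery within ±0.03 is a meaningful check rather than a coin
flip.

## Rank-frequency analysis

Diseases are sorted by patient count (descending, ties broken
lexicographically for determinism) and the head is the shortest prefix
whose cumulative share reaches the threshold (default 0.80).  The
cumulative denominator is a config switch because "covering 80% of the
population" is ambiguous under multimorbidity:

- `disease_instances` (default): share of all disease occurrences; the
  reference cohort's per-patient coverage number is not reconstructible
  from its published marginals, while instance share always is;
- `patients_with_comorbidity`: union coverage — the fraction of patients
  with ≥ 1 comorbidity who carry at least one of the top-k diseases.

Both denominators end at exactly 1, and raising the threshold can never
shrink the head.

## Association-rule mining

Frequent itemsets are found by level-wise Apriori: size-k candidates join
two frequent (k−1)-sets sharing a prefix, are pruned by downward closure,
and are counted by intersecting per-item transaction-id sets.  All three
rule thresholds are strict inequalities, matching the reference operating
point "support > 0.01, confidence > 0.5, lift > 2"; the itemset size cap
defaults to 3 (dyads and triads).  The support denominator is all eligible
patients, including those with zero comorbidities.

Metrics are computed from integer counts with one division each
(confidence = c(X∪Y)/c(X), lift = c(X∪Y)·n / (c(X)·c(Y))), so the
identities lift·P(Y) = confidence and confidence·P(X) = support hold to
within 1e-12 on every emitted rule — an invariant the tests enforce.

Deduplication groups rules by their combined itemset X ∪ {Y} and keeps the
maximum-confidence split (ties: maximum lift, then lexicographically
smallest consequent).  On the packaged 41-rule reference fixture this
yields 30 unique itemsets and keeps the 0.92-confidence split of the
cardiac triad over its 0.71 alternative.

An intentionally naive exhaustive enumerator (`brute_force_rules`, guarded
at 20 items) provides the independent oracle: the Apriori path must emit
exactly the same rule set on hundreds of random small transaction sets with
random thresholds.

Note on the reference tables: the published lifts are not reconstructible
from the published marginals under any obvious support denominator, and the
published comorbidity-count histogram sums to 1530 rather than 1510.  The
package treats these tables as fixtures for summary statistics and dedup
behaviour, and targets marginals — not the histogram or the printed lifts —
when calibrating the generator.

## Network and communities

The co-occurrence network is built over a chosen node set (typically the
Pareto head): node weight = carriers, edge weight = patients with both
endpoint diseases, edges below `min_cooccurrence` (default 1) omitted, and
isolated nodes retained.  Edge weights are raw co-occurrence counts, not
correlations or lifts, so edge width maps directly to patient counts.

Partitions are scored by weighted Newman–Girvan modularity, evaluated
directly from the edge list (resolution γ, default 1.0).  Community
detection runs networkx's seeded Louvain algorithm with eight deterministic
restarts (seeds seed+0 … seed+7), keeping the partition our own scorer
rates highest; the reported Q is therefore always recomputable from the
returned assignment to 1e-9.  On random weighted graphs of ≤ 8 nodes this
restart scheme reaches the exhaustive-search optimum in ≥ 95% of instances
(verified against full set-partition enumeration, Bell(8) = 4140
partitions).  Because comorbidity subnetworks tend to align with organ
systems, the ICD-10 chapter grouping is reported alongside the detected
partition (`chapter_partition`) without asserting that they agree.

## Reporting

Rule heatmaps are rule-by-morbidity matrices with the rule's metric in
every participating column and an L/R marker distinguishing antecedent
from consequent — an annotation rather than an arrow, preserving the
non-causal reading.  Rows keep mining order; columns follow Pareto rank.
Every figure has a CSV twin containing exactly the plotted numbers, and
`run_pipeline` writes a sorted-key `summary.json` with no timestamps, so
identical configurations produce byte-identical summaries.

## Problem sizes and numerical choices

Verification cohorts use n = 20 000 patients (recovery tolerances: planted
confidence within ±0.03, lift within ±10%, marginals within 3 binomial
standard errors), oracle-equivalence suites use ≤ 12 items × ≤ 60
transactions, and exhaustive modularity checks use ≤ 8 nodes; these sizes
make every statistical tolerance comfortably testable while the whole
suite runs in seconds.  Threshold comparisons are strict with no epsilon;
the Pareto prefix test uses a 1e-12 tolerance on the cumulative share so a
boundary that is exact in real arithmetic is not missed to rounding.
Degenerate inputs are defined outcomes, not errors: empty cohorts filter to
empty reports, all-empty transactions rank to an empty warning ranking, and
threshold sets that no rule survives produce an empty rule table and an
empty-summary marker.

## Limitations

- The generator's independence-plus-overrides law is far simpler than real
  EMR dependence; recovered tolerances say nothing about coding error,
  hospital effects or longitudinal confounding.
- Louvain with restarts is near-optimal on small graphs but carries no
  global optimality guarantee at scale.
- Rule screening is purely threshold-based; lift estimates for rare
  itemsets are noisy, and no multiplicity correction is applied.
- Exact-string ICD-10 matching means upstream coding variants (e.g. I25.10)
  must be normalised before ingestion.
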