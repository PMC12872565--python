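# Methods

## Setting and model

The package analyses spontaneous adverse-event reports (ICSRs) from a
reporting system such as EudraVigilance. Each report carries suspect
medicinal products (sets of active ingredients, so combination products
carry several), demographic metadata, and MedDRA-coded reactions with a
six-level outcome. The analysis contrasts a *target* exposure
(default: bempedoic acid, including combinations) with a *comparator*
(default: atorvastatin, including combinations). Reports exposed to
both drugs form a separate descriptive group and are excluded from all
2×2 tables; reports exposed to neither are retained but excluded from
every table and analysis.

All event counting is **report-level**: a report contributes at most
once to a SOC however many of its PTs map there, and at most one
(report, PT) record per preferred term. This convention is what makes
the descriptive SOC shares and the 2×2 margins consistent (e.g. the
musculoskeletal SOC share of the target-only cohort, 1,251/2,667,
renders as 47% only under report-level counting).

The disproportionality statistic is the reporting odds ratio
ROR = (a/b)/(c/d) with the Woolf (log-normal) 95% CI
exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.96. This estimator/CI pair
was chosen because it reproduces every published interval in the
reference analysis to the printed two decimals. The association test is
Pearson's chi-squared on the 2×2 without continuity correction
(closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), p from the χ²₁ survival
function); a Yates-corrected variant is available behind a flag. No
multiple-testing adjustment is applied — outputs carry raw p-values
only, and users scanning many SOCs/PTs should treat nominal
significance accordingly.

**Zero cells.** With any zero cell the ROR or its variance is
undefined. The default policy adds 0.5 to all four cells
(Haldane–Anscombe) before *all* computations — point estimate, CI and
chi-squared — and flags the result (`zero_cell_corrected`); a strict
policy that raises instead is available. Results with fewer than three
target events additionally carry `low_count_flag`; such rows are
rendered but should not be interpreted as signals.

## Vocabularies and mapping

PT → SOC mapping follows the primary-SOC convention: each PT maps to
exactly one SOC; conflicting mapping files are rejected. Lookups are
case-insensitive and fold the British/American spelling pair
necrotising/necrotizing myositis. Unknown PTs return an `UNMAPPED`
sentinel (logged, never raised). The licensed MedDRA dictionary is not
redistributable, so the package bundles a small synthetic mapping
(~60 terms) covering every PT and SOC the analyses and the simulator
use. Within it, "blood creatine phosphokinase increased" maps to
Investigations — the MedDRA primary-SOC convention — which is also what
keeps the musculoskeletal SOC counts of the reference dataset
consistent with its muscle-PT totals.

The muscle-related PT set (13 members: myalgia, blood creatine
phosphokinase increased, rhabdomyolysis, muscle spasms, muscular
weakness, myopathy, musculoskeletal stiffness, muscle disorder, muscle
discomfort, musculoskeletal pain, musculoskeletal discomfort, myositis,
necrotising myositis) refines the broad musculoskeletal SOC, which also
contains terms (arthralgia, back pain…) not unambiguously muscular. The
set is immutable by default and overridable in configuration.

## Ingestion and deduplication

Line listings are delimited text with a configurable dialect (delimiter,
multi-value separator, in-product ingredient separator, column map).
Rows sharing a case identifier merge into one report. Categorical
parsing is fail-soft: unrecognized qualification/area/age/sex/outcome
strings become the UNSPECIFIED/UNKNOWN level with a log record, because
registry exports are dirty and one malformed cell must not abort a run.
Reports with no parseable reaction are dropped (logged) — they cannot
enter any 2×2 table.

Duplicates are defined as exact case-identifier matches; the version
with the latest receive date wins, ties resolving to the last occurrence
in input order. Content-similarity record linkage is out of scope. Age
bands are closed-open on the printed boundaries [0,18), [18,65),
[65,86), [86,∞), so an 85-year-old is "Elderly". EEA membership is a
configuration list (default: EU-27 plus IS/LI/NO), not hard-coded,
since the composition changes over time.

## Severity

The severe-outcome subset is {fatal, recovered/resolved with sequelae,
not recovered/not resolved}. Severe proportions are always computed
from raw counts, never by summing rounded percentage cells; the two
conventions can disagree by a few tenths of a percentage point (e.g.
449+27+21 of 3,837 CPK records gives 12.95% raw, while the rounded
cells sum to 13.2%). Raw-count arithmetic is the defensible statistic
and is what the package reports.

## Synthetic data

`SimulationConfig`/`generate` draw datasets with fixed cohort sizes,
independent Bernoulli events per configured PT (so the population ROR
of every PT is known in closed form: [p_t/(1−p_t)]/[p_c/(1−p_c)]),
multinomial outcomes per (PT, group), categorical demographics from
marginals, an optional combination-product fraction, and injected
duplicate records (same case id, receive date +30 days) at a configured
rate. Defaults reproduce the reference study's conditions: cohort sizes
2,667 / 76,137 / 126, event and outcome probabilities equal to the
empirical per-group rates, pooled demographic marginals, and a 0.6%
duplicate rate (the reference extraction removed 472 of 79,402
retrieved records). A report whose Bernoulli draws produce no event
receives a background reaction ("fatigue"), since analysable reports
need at least one reaction.

What the generator deliberately does **not** model: PT co-occurrence
correlation within reports (the analyses are report-level marginal, so
only joint tables that are never computed would notice), reporting-delay
and calendar-time dynamics, under-reporting, and notoriety/alert bias.
Passing tests on synthetic data therefore validate the *arithmetic and
calibration* of the pipeline under known truth — not the epidemiological
interpretability of signals in real registry data, where those biases
dominate.

`reference_fixture()` is different: a deterministic 78,930-report
dataset constructed so that every published marginal — cohort sizes,
demographic blocks, report-level SOC presence, per-muscle-PT outcome
distributions — is hit exactly. SOC blocks are laid out consecutively
with wrap-around so every report gets at least one reaction; muscle PTs
occupy sub-ranges of the musculoskeletal block (the comparator group's
muscle-PT totals, 21,662, exceed its 21,474 musculoskeletal reports, so
188 reports necessarily carry two muscle PTs; similarly 15 in the
dual-exposure group). Within-report PT combinations are an artifact of
this construction and carry no epidemiological meaning.

## Numerical and design choices

- z = 1.959963984540054 (the exact normal quantile), not 1.96 rounded;
  at the published counts both round identically.
- Chi-squared p-values use `scipy.special.chdtrc`, numerically stable
  far into the tail.
- Sorting of result lists is by descending ROR; ties are left in
  category order (stable sort).
- Sex stratification excludes unspecified-sex reports before splitting;
  pooling the stratified 2×2 cells reproduces the unstratified table
  restricted to sex-specified reports (tested as an invariant). Only
  sex subgrouping is exercised, through a generic partition API.
- Percent rendering: ≥10% → whole percents, 0.05–10% → one decimal,
  below 0.05% → "<0.1%", true zero → "0%"; counts use thousands
  separators. Centralized so rendered tables are string-comparable
  with published ones.

## Problem sizes in the test suite

Unit and property tests run at hundreds to a few thousand synthetic
reports. The replication tests build the full 78,930-report reference
dataset once per session (a few seconds). CI-calibration uses 2,000
replicates of two binomials at n = 5,000 per arm, putting the
Monte-Carlo standard error of the coverage estimate near 0.5%; the
formula-equivalence check enumerates all 810,000 2×2 tables with cells
in 1..30 against an independent vectorised computation.

## Known limitations

- Disproportionality measures reporting, not risk; confounding by
  indication, notoriety bias and channeling are all invisible to the
  2×2 table.
- The bundled PT→SOC mapping covers only the analysis vocabulary; real
  listings will produce UNMAPPED rows until a licensed mapping file is
  supplied.
- Deduplication is identifier-based only.
- The dual-exposure ("both") group is described but never tested
  inferentially, matching the reference analysis.
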