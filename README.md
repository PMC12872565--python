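# pvdispro

Disproportionality analysis of spontaneous adverse-drug-reaction reports:
a tested pipeline from raw line-listing exports of individual case safety
reports (ICSRs) to reporting odds ratios, outcome-severity tables and
forest plots.

The package targets pharmacovigilance analysts who work with public
spontaneous-reporting line listings (for example the EudraVigilance
exports on adrreports.eu). The motivating analysis is the comparison of
muscle-related adverse-event reporting between **bempedoic acid** — a
lipid-lowering prodrug with negligible activation in skeletal muscle,
marketed as an option for statin-intolerant patients — and
**atorvastatin**, the most prescribed statin, whose musculoskeletal
adverse reactions (myalgia, CPK elevation, rhabdomyolysis) are the main
driver of therapy discontinuation.

## The statistic

For an event *E* (a MedDRA system organ class, SOC, or preferred term,
PT) and two exposure cohorts, the report-level 2×2 table is

|            | E reported | E not reported |
|------------|-----------:|---------------:|
| target     | a          | b              |
| comparator | c          | d              |

and the **reporting odds ratio** is

    ROR = (a/b) / (c/d),
    95% CI = exp( ln ROR ± 1.96 · √(1/a + 1/b + 1/c + 1/d) )   (Woolf)

with a Pearson chi-squared test of association (df = 1, no continuity
correction by default). When a cell is zero, the Haldane–Anscombe
correction (+0.5 to all four cells) is applied before every computation
and the result is flagged. An ROR is a reporting-disproportionality
signal, not a risk estimate: it says an event is reported relatively
more often under one drug, nothing about incidence or causation.

Around this core the package provides:

- **Line-listing I/O** (`pvdispro.line_listing`): configurable dialects,
  multi-value cells, combination products, fail-soft categorical
  parsing, case-level merging and latest-version-wins deduplication.
- **MedDRA mapping** (`pvdispro.meddra`): PT → primary SOC lookup from a
  two-column file, plus the predefined 13-member muscle-related PT set.
  A small synthetic mapping covering the analysis vocabulary is bundled
  (the licensed MedDRA dictionary cannot be redistributed).
- **Cohorting and description** (`pvdispro.cohorts`): target-only /
  comparator-only / both / neither partition and the demographics +
  per-SOC descriptive table with registry rendering conventions.
- **Analyses** (`pvdispro.disproportionality`, `pvdispro.outcomes`,
  `pvdispro.subgroup`): SOC- and muscle-PT-level ROR tables, per-PT
  outcome-severity distributions, and sex-stratified re-analysis.
- **Synthetic data** (`pvdispro.simulate`): a generator with closed-form
  ground-truth RORs, plus a deterministic 78,930-report dataset whose
  marginals equal the published bempedoic-acid/atorvastatin summary
  tables exactly.
- **CLI** (`pv-dispro`): `simulate`, `ingest`, `describe`, `analyze`,
  `outcomes`, `report`.

## Worked example

```python
from pvdispro import ContingencyTable, ror

# Musculoskeletal SOC: 1,251 of 2,667 bempedoic-acid-only reports vs
# 21,474 of 76,137 atorvastatin-only reports.
res = ror(ContingencyTable(a=1251, b=1416, c=21474, d=54663),
          event_label="Musculoskeletal and connective tissue disorders")
print(f"{res.event_label}: ROR {res.ror:.2f} "
      f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), "
      f"chi2 {res.chi2:.1f}, p {res.p_value:.2e}")
```

prints

```
Musculoskeletal and connective tissue disorders: ROR 2.25 (95% CI 2.08-2.43), chi2 439.2, p 1.63e-97
```

i.e. musculoskeletal events are reported about 2.25 times more often
(in odds terms) for bempedoic-acid-only reports than for
atorvastatin-only reports, with a confidence interval well clear of 1.

A full run from a synthetic listing:

```sh
pv-dispro simulate --out listing.csv --seed 1
pv-dispro analyze listing.csv --level mrpt --out ror_mrpt.csv --forest forest.svg
```

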