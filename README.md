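# cephvig

Pharmacovigilance disproportionality analysis of spontaneous adverse-drug-reaction
reports (ICSRs), built around the three questions antibiotic-stewardship teams ask
of a safety database: how often are **resistance**, **therapeutic
ineffectiveness**, and **off-label use** reported for a drug, and is any drug's
reporting of them disproportionate relative to its comparators?

The package provides:

- a data model and canonical CSV I/O for ICSR line listings (one row per
  reaction; reports merged by `report_id`),
- report classification into event categories via configurable MedDRA
  Preferred Term (PT) lists, counted at case level,
- descriptive tables: demographics, System Organ Class frequencies, category
  rates and distributions, and unfavorable-outcome breakdowns,
- drug-vs-drug **reporting odds ratio** (ROR) screening with Woolf 95%
  confidence intervals and the EMA minimum-case signal rule,
- a seeded synthetic ICSR generator whose packaged preset encodes the
  published EudraVigilance aggregates for the five WHO Reserve-group
  cephalosporins (ceftazidime/avibactam, ceftaroline, ceftolozane/tazobactam,
  ceftobiprole, cefiderocol; reports up to 26 January 2025), so the full
  analysis is reproducible offline.

## The statistic

For an index drug and a comparator, a 2×2 table of case counts is formed for
each event category:

|            | with event | without event |
|------------|-----------:|--------------:|
| index      | a          | b             |
| comparator | c          | d             |

The reporting odds ratio is **ROR = (a/b)/(c/d)**, with the Woolf (log-normal)
confidence interval

```
exp( ln ROR ± z₁₋α/₂ · √(1/a + 1/b + 1/c + 1/d) )
```

A pair is flagged **disproportionate** when the event counts are at least 5
and the CI lower bound exceeds 1.0; tables with fewer than 5 events on either
side, or a zero cell (unless the Haldane–Anscombe +0.5 correction is enabled),
are **not evaluable**. The ROR is a reporting-pattern statistic, not a risk
estimate: spontaneous databases have no denominator.

## Worked example

```python
import cephvig as cv

reports = cv.simulate_dataset(cv.reserve_fixture(seed=1))   # 2345 ICSRs
counts = {c.drug: c for c in cv.count_by_category(reports, cv.default_catalog())}

table = cv.build_table(counts["ceftazidime/avibactam"],
                       counts["ceftolozane/tazobactam"], "off_label")
res = cv.ror_estimate(table)
print(table.cells, res.rounded(2), res.verdict.value)
```

prints

```
(118, 786, 154, 406) (0.4, 0.3, 0.52) NotDisproportionate
```

i.e. 118 of ceftazidime/avibactam's 904 reports and 154 of
ceftolozane/tazobactam's 560 reports carry an off-label PT; off-label use is
reported for ceftazidime/avibactam with 0.40 times the odds of its comparator
(95% CI 0.30–0.52) — a significantly *lower* reporting probability, though not
a "signal" in the EMA sense, which flags only elevated reporting.

The same analysis end-to-end from the shell:

```bash
cephvig report --fixture --seed 1 --out-dir out/
# out/: line_listing.csv, demographics.csv, category_rates.csv,
#       category_distribution.csv, outcome_breakdown.csv, soc_frequency.csv,
#       ror_<category>.csv, signal_summary_<category>.csv, manifest.json
```

Real extracts are analysed by passing `--input listing.csv` (canonical columns
`report_id,drug,age_group,sex,origin,reporter,pt,soc,outcome`; other headers
and value spellings can be mapped via a dialect config), and bespoke PT lists
via `--catalog my_catalog.yaml`.

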