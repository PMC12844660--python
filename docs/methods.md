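# Methods

## Analysis model

The unit of analysis is the ICSR (case), not the reaction. A report belongs
to an event category (resistance, ineffectiveness, off-label use) iff at
least one of its reaction PTs is in that category's PT list, matched exactly
after case-folding and whitespace collapse — no substring or fuzzy matching,
since MedDRA PTs are a controlled vocabulary. A report can carry several
categories; within one category it counts once however many qualifying PTs
it lists. Case-level counting is what makes the published odds ratios
arithmetically consistent with the per-drug report totals.

Disproportionality is screened drug-vs-drug (not drug-vs-all-others): for an
index/comparator pair and category, the 2×2 table is
(a, b, c, d) = (index with event, index without, comparator with, comparator
without), ROR = (a/b)/(c/d), and the 95% CI is Woolf's log-normal interval
`exp(ln ROR ± z·SE)` with `SE = √(1/a+1/b+1/c+1/d)` and `z = Φ⁻¹(1−α/2)`
(1.959964 at the default α = 0.05). No multiple-testing adjustment is
applied; this matches standard signal-screening practice but means the
pairwise matrices are exploratory, not confirmatory — a known limitation.

### Signal rule

A pair is *Disproportionate* when it is evaluable and the CI lower bound
exceeds 1.0. Evaluability requires (i) no zero cell — unless the optional
Haldane–Anscombe correction (+0.5 to every cell when any cell is zero) is
enabled — and (ii) at least 5 event cases **on both sides** of the ratio
(min(a, c) ≥ 5). Applying the EMA minimum-case threshold symmetrically is a
deliberate design choice: an odds ratio resting on two comparator events is
no more screenable than one resting on two index events, and a symmetric
rule is the only one consistent with ROR reciprocity
(ROR(A,B) = 1/ROR(B,A)) — it cannot flag A-vs-B while declaring B-vs-A not
evaluable. `n_cases` still reports cell a. Full float precision is kept
internally; rendered outputs round half-up to 2 decimals (percentages to 1
decimal), the convention of regulatory tables, implemented with decimal
arithmetic because Python's built-in `round` is banker's rounding.

### Outcomes

Per-reaction outcomes are kept; report-level summaries use the worst outcome
under Fatal > Not recovered > Recovered with sequelae > Recovering >
Recovered > Unknown ("Recovering" outranks "Recovered" because the episode
is open). "Recovered/Resolved with sequelae" is shown as its own unfavorable
column by default; `count_sequelae=False` reclassifies it as favorable.
Unfavorable-outcome breakdowns cover, per category, only the reports in that
category, so they can never exceed the category counts.

## Synthetic data generator

The generator emulates an *aggregated* spontaneous-reporting extract in the
style of the EudraVigilance public line listings. Per drug it takes: total
report count; per-category case counts; demographic marginals for age group,
sex, origin (EEA/non-EEA), and reporter type (exact counts or probability
vectors); and per-category unfavorable-outcome counts. Category flags, exact
demographic counts, and outcome labels are **allocated** — assigned to report
slots deterministically and then shuffled with the seeded RNG — rather than
Bernoulli-sampled. Recomputing counts from a simulated dataset therefore
returns the configured values for every seed, and aggregate statistics (the
RORs above all) are reproduced exactly, not in expectation. Probability
marginals are the only sampled element and converge to their targets at the
usual √n rate. Categories occupy disjoint report subsets by default (no
public aggregate quantifies their overlap); a per-drug overlap configuration
assigns shared reports when wanted. Category reactions draw a PT uniformly
from the category list; reports without a category get one reaction from a
small built-in list of common PTs with SOC labels.

What the generator does *not* emulate: reporting delays and duplicates
(EudraVigilance deduplicates upstream), multi-drug suspect reports (each
simulated ICSR names exactly one suspected drug), correlation between
demographics and events, free-text narratives, and realistic SOC profiles
beyond the two SOCs pinned by the category PTs. Passing tests therefore
demonstrate correctness of counting, allocation, and estimation on data with
the configured marginals — not robustness to the messiness of real extracts
(miscoded PTs, conflicting duplicates, missing fields beyond NS levels).

## The packaged Reserve-cephalosporin preset

`reserve_fixture()` encodes the published aggregates for the five WHO
Reserve-group cephalosporins (EudraVigilance, reports up to 26 January
2025): report totals 904 (ceftazidime/avibactam), 559 (ceftaroline), 560
(ceftolozane/tazobactam), 176 (cefiderocol), 146 (ceftobiprole) — 2345 in
all — together with the per-drug category counts, full demographic tables,
and per-category fatal / not-recovered / sequelae counts. Three counts are
derived from published rates rather than printed directly: ceftobiprole
off-label 30 = round(20.5% × 146), cefiderocol ineffectiveness
25 = round(14.2% × 176), cefiderocol off-label 16 = round(9.1% × 176); each
is corroborated by an independently published ratio (e.g. only c = 30
reproduces the published 0.58 CI 0.37–0.91 for ceftazidime/avibactam vs
ceftobiprole). Two knobs remain genuinely undetermined by the public
aggregates:

- the ceftaroline / ceftolozane-tazobactam split of the 48 resistance cases
  not attributed drug-by-drug — exposed as `resistance_split`, default an
  even 24/24; no reproduced odds ratio depends on it;
- ceftobiprole's fatal ineffectiveness count: the published outcome
  breakdown attributes 7 fatal cases to a drug with only 2 ineffectiveness
  reports in total. The fixture caps the count at 2 (a case-level count
  cannot exceed the cases), so the fixture's across-drug ineffectiveness
  fatal total is 45 where the published breakdown sums to 50; the per-drug
  values for the other four drugs (21/14/7/1) are kept as published.

## Default PT catalog

The exact published PT lists are not publicly reproduced, so the shipped
default uses standard MedDRA terms at the published category sizes — 3
resistance PTs, 11 ineffectiveness PTs, 8 off-label PTs (e.g. "Drug
resistance", "Drug ineffective", "Off label use"). Any analysis against a
real extract should supply the extract's own lists via a YAML/JSON catalog
(`{category: [PT, ...]}`); classification, counting, and all downstream
statistics are catalog-agnostic.

## Problem sizes and numerical checks

The default test suite runs the full 2345-report preset, compares the ROR
and CI against an independent textbook computation and against statsmodels'
`Table2x2` on 1000 random tables (agreement to 1e-12 relative), and verifies
95% CI coverage of the null (true OR = 1, two binomial arms of n = 400,
p = 0.25) over 10⁴ replicates to within ±1 percentage point. Degenerate
inputs: zero-cell tables yield NaN estimates and NotEvaluable verdicts
rather than errors; zero-report drugs yield missing (NaN) percentages;
infeasible simulation configs (category counts exceeding totals, marginals
not summing, outcome counts exceeding category counts) fail validation
before any data is generated.
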