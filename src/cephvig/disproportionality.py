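"""Reporting odds ratio (ROR) disproportionality analysis.

For an index drug and a comparator drug and one event category, the 2x2
contingency table of report counts is

    =============  ==========  =============
                   with event  without event
    index drug          a            b
    comparator          c            d
    =============  ==========  =============

and the reporting odds ratio is ROR = (a/b) / (c/d). The 95% confidence
interval uses the Woolf log-normal method:

    exp( ln ROR  +/-  z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d) )

A pair is a *disproportionality signal* under the EMA screening convention
when the case counts are at least 5 and the CI lower bound exceeds 1.0.
The minimum-case rule is applied symmetrically: a table whose index (a) or
comparator (c) event count is below 5, or that has any zero cell (unless
the Haldane-Anscombe +0.5 correction is enabled), is not evaluable in
either direction — an odds ratio resting on a handful of events cannot be
screened, whichever side of the ratio they sit on. The ROR is a reporting-pattern statistic computed without a
population denominator; it is not a relative risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import norm

from ._util import round_half_up
from .errors import ValidationError
from .icsr import CategoryCounts

__all__ = [
    "ContingencyTable",
    "Verdict",
    "SignalResult",
    "MIN_CASES",
    "build_table",
    "ror_estimate",
    "pairwise_matrix",
    "matrix_to_frame",
    "signal_summary",
]

#: EMA screening rule: minimum event count (on either side) for an evaluable signal.
MIN_CASES = 5


class Verdict(str, Enum):
    DISPROPORTIONATE = "Disproportionate"
    NOT_DISPROPORTIONATE = "NotDisproportionate"
    NOT_EVALUABLE = "NotEvaluable"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report-count table for one (index, comparator, category) triple."""

    drug_a: str
    drug_b: str
    category: str
    a: int  # index drug, with event
    b: int  # index drug, without event
    c: int  # comparator, with event
    d: int  # comparator, without event

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class SignalResult:
    """ROR point estimate with Woolf CI and the signal verdict.

    ``ror``/``ci_low``/``ci_high`` are NaN when the table has a zero cell
    and no continuity correction is applied. ``n_cases`` is the uncorrected
    count of index-drug cases (cell a); evaluability additionally requires
    at least :data:`MIN_CASES` comparator cases (cell c).
    """

    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    n_cases: int
    verdict: Verdict

    @property
    def is_signal(self) -> bool:
        return self.verdict is Verdict.DISPROPORTIONATE

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(ror, ci_low, ci_high) rounded half-up, as rendered in reports."""
        return tuple(round_half_up(v, ndigits) for v in (self.ror, self.ci_low, self.ci_high))


def build_table(
    counts_a: CategoryCounts, counts_b: CategoryCounts, category: str
) -> ContingencyTable:
    """Assemble the 2x2 table for ``category`` from two drugs' counts."""
    for counts in (counts_a, counts_b):
        if category not in counts.n_by_category:
            raise ValidationError(
                f"category {category!r} not present in counts for {counts.drug!r}"
            )
    a = counts_a.n_by_category[category]
    c = counts_b.n_by_category[category]
    return ContingencyTable(
        drug_a=counts_a.drug,
        drug_b=counts_b.drug,
        category=category,
        a=a,
        b=counts_a.n_total - a,
        c=c,
        d=counts_b.n_total - c,
    )


def ror_estimate(
    table: ContingencyTable,
    alpha: float = 0.05,
    correction: str = "none",
) -> SignalResult:
    """ROR with Woolf log-normal CI and the EMA signal verdict.

    correction="haldane" adds 0.5 to every cell when any cell is zero
    (Haldane-Anscombe); the default leaves zero-cell tables NotEvaluable.
    Full float precision is retained; use :meth:`SignalResult.rounded`
    for the 2-decimal rendering.
    """
    if correction not in ("none", "haldane"):
        raise ValidationError(f"unknown correction {correction!r}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")

    a, b, c, d = (float(x) for x in table.cells)
    has_zero = min(a, b, c, d) == 0.0
    if has_zero and correction == "haldane":
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        has_zero = False

    if has_zero:
        ror = ci_low = ci_high = math.nan
    else:
        ror = (a / b) / (c / d)
        z = norm.ppf(1 - alpha / 2)
        half_width = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci_low = math.exp(math.log(ror) - half_width)
        ci_high = math.exp(math.log(ror) + half_width)

    n_cases = table.a
    if min(table.a, table.c) < MIN_CASES or math.isnan(ror):
        verdict = Verdict.NOT_EVALUABLE
    elif ci_low > 1.0:
        verdict = Verdict.DISPROPORTIONATE
    else:
        verdict = Verdict.NOT_DISPROPORTIONATE

    return SignalResult(
        table=table, ror=ror, ci_low=ci_low, ci_high=ci_high,
        n_cases=n_cases, verdict=verdict,
    )


def pairwise_matrix(
    all_counts: Sequence[CategoryCounts],
    index_drugs: Sequence[str],
    comparator_drugs: Sequence[str],
    category: str,
    alpha: float = 0.05,
    correction: str = "none",
) -> dict[tuple[str, str], SignalResult]:
    """One SignalResult per ordered (index, comparator) pair, index != comparator."""
    by_drug = {c.drug: c for c in all_counts}
    for drug in (*index_drugs, *comparator_drugs):
        if drug not in by_drug:
            raise ValidationError(f"no counts available for drug {drug!r}")
    results: dict[tuple[str, str], SignalResult] = {}
    for index in index_drugs:
        for comparator in comparator_drugs:
            if index == comparator:
                continue
            table = build_table(by_drug[index], by_drug[comparator], category)
            results[(index, comparator)] = ror_estimate(table, alpha=alpha, correction=correction)
    return results


def matrix_to_frame(matrix: Mapping[tuple[str, str], SignalResult]) -> pd.DataFrame:
    """Long-format frame: one row per pair, ready for CSV export."""
    rows = []
    for (index, comparator), res in matrix.items():
        t = res.table
        rows.append(
            {
                "index_drug": index,
                "comparator_drug": comparator,
                "category": t.category,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "ror": res.ror,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_cases": res.n_cases,
                "verdict": res.verdict.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "index_drug", "comparator_drug", "category", "a", "b", "c", "d",
            "ror", "ci_low", "ci_high", "n_cases", "verdict",
        ],
    )


def signal_summary(matrix: Mapping[tuple[str, str], SignalResult]) -> pd.DataFrame:
    """Per index drug: verdict counts and the strongest disproportionate signals.

    ``strongest_signals`` lists ``comparator (ROR)`` strings for the index
    drug's disproportionate pairs, sorted by descending ROR.
    """
    per_index: dict[str, dict[str, object]] = {}
    for (index, comparator), res in matrix.items():
        entry = per_index.setdefault(
            index,
            {v.value: 0 for v in Verdict} | {"_signals": []},
        )
        entry[res.verdict.value] += 1
        if res.is_signal:
            entry["_signals"].append((res.ror, comparator))
    rows = []
    for index, entry in per_index.items():
        signals = sorted(entry["_signals"], reverse=True)
        rows.append(
            {
                "index_drug": index,
                "n_disproportionate": entry[Verdict.DISPROPORTIONATE.value],
                "n_not_disproportionate": entry[Verdict.NOT_DISPROPORTIONATE.value],
                "n_not_evaluable": entry[Verdict.NOT_EVALUABLE.value],
                "strongest_signals": "; ".join(
                    f"{comp} ({round_half_up(ror, 2):.2f})" for ror, comp in signals
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "index_drug", "n_disproportionate", "n_not_disproportionate",
            "n_not_evaluable", "strongest_signals",
        ],
    )
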