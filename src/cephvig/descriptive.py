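"""Descriptive surfaces: demographics, SOC frequencies, category rates and
distributions, and unfavorable-outcome breakdowns.

All functions return tidy :class:`pandas.DataFrame` objects (one row per
drug x level cell) with both raw counts and percentages; percentages are
rounded half-up to one decimal, the convention of regulatory summary
tables. :func:`format_frequency_table` pivots a tidy table into the
familiar "count (pct%)" grid for pretty-printing.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from ._util import round_half_up
from .errors import ValidationError
from .icsr import (
    ICSR,
    AgeGroup,
    CategoryCounts,
    Origin,
    Outcome,
    PTCatalog,
    Reporter,
    Sex,
    classify_report,
    worst_outcome,
)

__all__ = [
    "demographics_table",
    "soc_frequency",
    "category_rates",
    "category_distribution",
    "outcome_breakdown",
    "format_frequency_table",
    "TOTAL_LABEL",
]

#: Drug label used for the across-drugs totals rows in outcome breakdowns.
TOTAL_LABEL = "(all drugs)"

_CHARACTERISTICS: dict[str, type] = {
    "age_group": AgeGroup,
    "sex": Sex,
    "origin": Origin,
    "reporter": Reporter,
}

#: Unfavorable report-level outcomes, worst first.
_UNFAVORABLE = (Outcome.FATAL, Outcome.NOT_RECOVERED, Outcome.RECOVERED_WITH_SEQUELAE)


def _drug_order(reports: Sequence[ICSR]) -> list[str]:
    order: list[str] = []
    for r in reports:
        if r.suspected_drug not in order:
            order.append(r.suspected_drug)
    return order


def demographics_table(reports: Sequence[ICSR]) -> pd.DataFrame:
    """Counts and percentages per drug for age group, sex, origin, reporter.

    Denominators are the per-drug report totals, so each characteristic
    block sums to the drug's n_total and its percentages to ~100.
    """
    if not reports:
        raise ValidationError("demographics_table requires a non-empty dataset")
    drugs = _drug_order(reports)
    n_total = {d: 0 for d in drugs}
    tally: dict[tuple[str, str, str], int] = {}
    for r in reports:
        n_total[r.suspected_drug] += 1
        for char, _ in _CHARACTERISTICS.items():
            level = getattr(r, char).value
            key = (char, level, r.suspected_drug)
            tally[key] = tally.get(key, 0) + 1
    rows = []
    for char, enum_cls in _CHARACTERISTICS.items():
        for member in enum_cls:
            for drug in drugs:
                count = tally.get((char, member.value, drug), 0)
                rows.append(
                    {
                        "characteristic": char,
                        "level": member.value,
                        "drug": drug,
                        "count": count,
                        "pct": round_half_up(100.0 * count / n_total[drug], 1),
                    }
                )
    return pd.DataFrame(rows, columns=["characteristic", "level", "drug", "count", "pct"])


def soc_frequency(reports: Sequence[ICSR]) -> pd.DataFrame:
    """Share of each drug's reports containing >=1 reaction in each SOC.

    Report-level: a report with several reactions in the same SOC counts
    once. Reactions with an empty SOC label are ignored.
    """
    if not reports:
        raise ValidationError("soc_frequency requires a non-empty dataset")
    drugs = _drug_order(reports)
    n_total = {d: 0 for d in drugs}
    tally: dict[tuple[str, str], int] = {}
    soc_order: list[str] = []
    for r in reports:
        n_total[r.suspected_drug] += 1
        for soc in dict.fromkeys(rx.soc for rx in r.reactions if rx.soc):
            if soc not in soc_order:
                soc_order.append(soc)
            key = (soc, r.suspected_drug)
            tally[key] = tally.get(key, 0) + 1
    rows = [
        {
            "soc": soc,
            "drug": drug,
            "count": tally.get((soc, drug), 0),
            "pct": round_half_up(100.0 * tally.get((soc, drug), 0) / n_total[drug], 1),
        }
        for soc in soc_order
        for drug in drugs
    ]
    return pd.DataFrame(rows, columns=["soc", "drug", "count", "pct"])


def category_rates(counts: Sequence[CategoryCounts]) -> pd.DataFrame:
    """Each category's share of the drug's own reports (count / n_total).

    Drugs with zero reports get a missing (NaN) rate.
    """
    rows = []
    for c in counts:
        for cat, n in c.n_by_category.items():
            pct = (
                round_half_up(100.0 * n / c.n_total, 1) if c.n_total > 0 else float("nan")
            )
            rows.append(
                {"drug": c.drug, "category": cat, "count": n, "n_total": c.n_total, "pct": pct}
            )
    return pd.DataFrame(rows, columns=["drug", "category", "count", "n_total", "pct"])


def category_distribution(counts: Sequence[CategoryCounts]) -> pd.DataFrame:
    """Each drug's share of a category's total reports across drugs.

    Categories with zero reports overall get missing (NaN) shares.
    """
    cats: list[str] = []
    for c in counts:
        for cat in c.n_by_category:
            if cat not in cats:
                cats.append(cat)
    totals = {cat: sum(c.n_by_category.get(cat, 0) for c in counts) for cat in cats}
    rows = []
    for c in counts:
        for cat in cats:
            n = c.n_by_category.get(cat, 0)
            pct = (
                round_half_up(100.0 * n / totals[cat], 1) if totals[cat] > 0 else float("nan")
            )
            rows.append(
                {
                    "drug": c.drug,
                    "category": cat,
                    "count": n,
                    "category_total": totals[cat],
                    "pct": pct,
                }
            )
    return pd.DataFrame(rows, columns=["drug", "category", "count", "category_total", "pct"])


def outcome_breakdown(
    reports: Sequence[ICSR],
    catalog: PTCatalog,
    count_sequelae: bool = True,
) -> pd.DataFrame:
    """Unfavorable report-level outcomes per category and drug.

    A report's outcome is its worst reaction outcome (Fatal > Not
    recovered > Recovered with sequelae > ...). For each category the
    breakdown covers only reports belonging to that category, so counts
    never exceed the category counts. Rows with drug ``(all drugs)`` carry
    the across-drug totals. ``count_sequelae=False`` treats
    "Recovered/Resolved with sequelae" as favorable and omits its column.
    """
    outcomes = _UNFAVORABLE if count_sequelae else _UNFAVORABLE[:2]
    colnames = {
        Outcome.FATAL: "fatal",
        Outcome.NOT_RECOVERED: "not_recovered",
        Outcome.RECOVERED_WITH_SEQUELAE: "recovered_with_sequelae",
    }
    drugs = _drug_order(reports)
    cats = list(catalog.categories)
    tally = {(cat, drug, o): 0 for cat in cats for drug in drugs for o in outcomes}
    for r in reports:
        w = worst_outcome(r)
        if w not in outcomes:
            continue
        for cat in classify_report(r, catalog):
            tally[(cat, r.suspected_drug, w)] += 1
    rows = []
    for cat in cats:
        for drug in drugs:
            rows.append(
                {"category": cat, "drug": drug}
                | {colnames[o]: tally[(cat, drug, o)] for o in outcomes}
            )
        rows.append(
            {"category": cat, "drug": TOTAL_LABEL}
            | {
                colnames[o]: sum(tally[(cat, d, o)] for d in drugs) for o in outcomes
            }
        )
    return pd.DataFrame(rows, columns=["category", "drug"] + [colnames[o] for o in outcomes])


def format_frequency_table(
    table: pd.DataFrame, row_fields: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pivot a tidy count/pct table to a "count (pct%)" grid, drugs as columns."""
    if row_fields is None:
        row_fields = [
            c for c in table.columns
            if c not in ("drug", "count", "pct", "n_total", "category_total")
        ]
    return table.assign(
        cell=[f"{c} ({p:.1f}%)" for c, p in zip(table["count"], table["pct"])]
    ).pivot(index=list(row_fields), columns="drug", values="cell")
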