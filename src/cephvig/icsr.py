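"""Data model and CSV I/O for ICSR line listings.

An ICSR (Individual Case Safety Report) is one spontaneous report of
suspected adverse drug reactions: a suspected drug, coarse demographics,
report origin and reporter type, and one or more reactions coded as MedDRA
Preferred Terms (PTs) with per-reaction outcomes.

The canonical line-listing format is a UTF-8 comma-separated file with one
row per *reaction* and report-level fields repeated::

    report_id,drug,age_group,sex,origin,reporter,pt,soc,outcome

Rows sharing ``report_id`` are merged into a single report on read; a
round-trip through :func:`write_line_listing` / :func:`read_line_listing`
is the identity on validated datasets.

Reports are assigned to event categories (resistance, ineffectiveness,
off-label use) through a :class:`PTCatalog`: a report belongs to a category
iff at least one of its reaction PTs is in the category's PT list, matched
exactly after case-folding and whitespace collapse. Counting is always at
report (case) level: a report contributes at most once to a category no
matter how many qualifying reactions it lists.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AgeGroup",
    "Sex",
    "Origin",
    "Reporter",
    "Outcome",
    "Reaction",
    "ICSR",
    "PTCatalog",
    "CategoryCounts",
    "LINE_LISTING_COLUMNS",
    "default_catalog",
    "load_catalog",
    "classify_report",
    "count_by_category",
    "worst_outcome",
    "read_line_listing",
    "write_line_listing",
]


# ---------------------------------------------------------------------------
# Enumerated fields


class AgeGroup(str, Enum):
    NS = "NS"
    MONTH_0_1 = "0-1 Month"
    MONTHS_2_YEARS_2 = "2 Months-2 Years"
    YEARS_3_11 = "3-11 Years"
    YEARS_12_17 = "12-17 Years"
    YEARS_18_64 = "18-64 Years"
    YEARS_65_85 = "65-85 Years"
    OVER_85 = ">85 Years"


class Sex(str, Enum):
    FEMALE = "Female"
    MALE = "Male"
    NS = "NS"


class Origin(str, Enum):
    EEA = "EEA"
    NON_EEA = "Non-EEA"
    NS = "NS"


class Reporter(str, Enum):
    HP = "HP"
    NON_HP = "Non-HP"
    NS = "NS"


class Outcome(str, Enum):
    FATAL = "Fatal"
    NOT_RECOVERED = "Not recovered/Not resolved"
    RECOVERED_WITH_SEQUELAE = "Recovered/Resolved with sequelae"
    RECOVERING = "Recovering/Resolving"
    RECOVERED = "Recovered/Resolved"
    UNKNOWN = "Unknown"


#: Worst-first severity ordering used for report-level outcome summaries.
#: "Recovering" ranks above "Recovered" because the episode is still open.
OUTCOME_SEVERITY: tuple[Outcome, ...] = (
    Outcome.FATAL,
    Outcome.NOT_RECOVERED,
    Outcome.RECOVERED_WITH_SEQUELAE,
    Outcome.RECOVERING,
    Outcome.RECOVERED,
    Outcome.UNKNOWN,
)

_SEVERITY_RANK = {o: i for i, o in enumerate(OUTCOME_SEVERITY)}


def _norm(value: str) -> str:
    """Case-fold, collapse whitespace, and map en-dashes to hyphens."""
    return " ".join(value.replace("–", "-").replace("—", "-").split()).casefold()


_BUILTIN_ALIASES: dict[str, dict[str, str]] = {
    "sex": {"m": "Male", "f": "Female", "not specified": "NS", "": "NS"},
    "origin": {
        "european economic area": "EEA",
        "non eea": "Non-EEA",
        "not specified": "NS",
        "": "NS",
    },
    "reporter": {
        "healthcare professional": "HP",
        "non healthcare professional": "Non-HP",
        "non-healthcare professional": "Non-HP",
        "consumer": "Non-HP",
        "not specified": "NS",
        "": "NS",
    },
    "age_group": {"not specified": "NS", "": "NS"},
    "outcome": {
        "died": "Fatal",
        "not recovered": "Not recovered/Not resolved",
        "not resolved": "Not recovered/Not resolved",
        "recovered with sequelae": "Recovered/Resolved with sequelae",
        "resolved with sequelae": "Recovered/Resolved with sequelae",
        "recovered": "Recovered/Resolved",
        "resolved": "Recovered/Resolved",
        "recovering": "Recovering/Resolving",
        "resolving": "Recovering/Resolving",
        "": "Unknown",
    },
}

_ENUM_FOR_FIELD: dict[str, type[Enum]] = {
    "age_group": AgeGroup,
    "sex": Sex,
    "origin": Origin,
    "reporter": Reporter,
    "outcome": Outcome,
}

_FALLBACK = {
    "age_group": AgeGroup.NS,
    "sex": Sex.NS,
    "origin": Origin.NS,
    "reporter": Reporter.NS,
    "outcome": Outcome.UNKNOWN,
}


def _parse_enum(field_name: str, raw: str, extra_aliases: Mapping[str, str] | None = None):
    """Map a raw cell to its enum member, case-insensitively.

    Returns ``(member, mapped_ok)``; unmappable values fall back to
    NS/Unknown with ``mapped_ok`` False so callers can count coercions.
    """
    enum_cls = _ENUM_FOR_FIELD[field_name]
    lookup = {_norm(m.value): m for m in enum_cls}
    for variant, canonical in _BUILTIN_ALIASES.get(field_name, {}).items():
        lookup[_norm(variant)] = enum_cls(canonical)
    if extra_aliases:
        for variant, canonical in extra_aliases.items():
            lookup[_norm(variant)] = enum_cls(canonical)
    member = lookup.get(_norm(raw))
    if member is None:
        return _FALLBACK[field_name], False
    return member, True


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class Reaction:
    """One coded adverse reaction: a MedDRA PT, its SOC (optional), outcome."""

    pt: str
    soc: str = ""
    outcome: Outcome = Outcome.UNKNOWN

    def __post_init__(self) -> None:
        if not isinstance(self.outcome, Outcome):
            raise ValidationError(f"outcome must be an Outcome, got {self.outcome!r}")
        if not self.pt:
            raise ValidationError("reaction PT must be non-empty")


@dataclass
class ICSR:
    """One Individual Case Safety Report."""

    report_id: str
    suspected_drug: str
    age_group: AgeGroup = AgeGroup.NS
    sex: Sex = Sex.NS
    origin: Origin = Origin.NS
    reporter: Reporter = Reporter.NS
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValidationError("report_id must be non-empty")
        if not self.reactions:
            raise ValidationError(f"report {self.report_id!r} has no reactions")
        for name, cls in (("age_group", AgeGroup), ("sex", Sex),
                          ("origin", Origin), ("reporter", Reporter)):
            if not isinstance(getattr(self, name), cls):
                raise ValidationError(f"{name} must be a {cls.__name__}")


def worst_outcome(report: ICSR) -> Outcome:
    """Report-level outcome: the most severe outcome among the reactions."""
    return min((r.outcome for r in report.reactions), key=_SEVERITY_RANK.__getitem__)


# ---------------------------------------------------------------------------
# PT catalog and classification

RESISTANCE_PTS: tuple[str, ...] = (
    "Drug resistance",
    "Pathogen resistance",
    "Multiple drug resistance",
)

INEFFECTIVENESS_PTS: tuple[str, ...] = (
    "Drug ineffective",
    "Drug effect decreased",
    "Drug effect delayed",
    "Therapeutic response decreased",
    "Therapeutic response delayed",
    "Therapeutic response unexpected",
    "Therapy non-responder",
    "Treatment failure",
    "Therapeutic product effect incomplete",
    "Therapeutic product ineffective",
    "Drug ineffective for unapproved indication",
)

OFF_LABEL_PTS: tuple[str, ...] = (
    "Off label use",
    "Product use in unapproved indication",
    "Intentional product use issue",
    "Product use issue",
    "Drug use for unknown indication",
    "Intentional use for unapproved indication",
    "Unintentional use for unapproved indication",
    "Contraindicated product administered",
)

#: SOC under which each default category's PTs are coded.
CATEGORY_SOC: dict[str, str] = {
    "resistance": "General disorders and administration site conditions",
    "ineffectiveness": "General disorders and administration site conditions",
    "off_label": "Injury, poisoning and procedural complications",
}


@dataclass(frozen=True)
class PTCatalog:
    """Named event categories, each an ordered list of MedDRA PTs.

    Category names are unique, PT lists non-empty, and a PT (after
    normalisation) belongs to at most one category.
    """

    categories: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        cats = {name: tuple(pts) for name, pts in self.categories.items()}
        object.__setattr__(self, "categories", cats)
        seen: dict[str, str] = {}
        for name, pts in cats.items():
            if not pts:
                raise ValidationError(f"category {name!r} has an empty PT list")
            for pt in pts:
                key = _norm(pt)
                if key in seen:
                    raise ValidationError(
                        f"PT {pt!r} appears in both {seen[key]!r} and {name!r}"
                    )
                seen[key] = name
        object.__setattr__(self, "_pt_to_category", seen)

    def category_of(self, pt: str) -> str | None:
        """Category containing ``pt`` (case/whitespace-insensitive), or None."""
        return self._pt_to_category.get(_norm(pt))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "PTCatalog":
        return cls({name: tuple(pts) for name, pts in mapping.items()})

    def to_mapping(self) -> dict[str, list[str]]:
        return {name: list(pts) for name, pts in self.categories.items()}


def default_catalog() -> PTCatalog:
    """Catalog of the three study categories: 3 resistance PTs, 11
    ineffectiveness PTs, and 8 off-label-use PTs (standard MedDRA terms;
    override via :func:`load_catalog` to use a bespoke list)."""
    return PTCatalog.from_mapping(
        {
            "resistance": RESISTANCE_PTS,
            "ineffectiveness": INEFFECTIVENESS_PTS,
            "off_label": OFF_LABEL_PTS,
        }
    )


def load_catalog(path: str | Path) -> PTCatalog:
    """Load a ``{category: [PT, ...]}`` catalog from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        mapping = json.loads(text)
    else:
        mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict):
        raise SchemaError(f"catalog file {path} must map category names to PT lists")
    return PTCatalog.from_mapping(mapping)


def classify_report(report: ICSR, catalog: PTCatalog) -> set[str]:
    """Categories for which the report lists at least one qualifying PT.

    Order of reactions is irrelevant; a report may carry several categories
    or none.
    """
    return {
        cat
        for r in report.reactions
        if (cat := catalog.category_of(r.pt)) is not None
    }


@dataclass(frozen=True)
class CategoryCounts:
    """Per-drug report counts: total, and per category (report-level)."""

    drug: str
    n_total: int
    n_by_category: Mapping[str, int]

    def __post_init__(self) -> None:
        for cat, n in self.n_by_category.items():
            if not 0 <= n <= self.n_total:
                raise ValidationError(
                    f"{self.drug}: count for {cat!r} ({n}) outside [0, {self.n_total}]"
                )


def count_by_category(
    reports: Iterable[ICSR], catalog: PTCatalog
) -> list[CategoryCounts]:
    """Report-level category counts per drug.

    A report contributes at most once to each category, regardless of how
    many qualifying PTs it lists. Drugs are returned in first-seen order.
    """
    totals: Counter[str] = Counter()
    by_cat: dict[str, Counter[str]] = {}
    order: list[str] = []
    for report in reports:
        drug = report.suspected_drug
        if drug not in totals:
            order.append(drug)
            by_cat[drug] = Counter()
        totals[drug] += 1
        for cat in classify_report(report, catalog):
            by_cat[drug][cat] += 1
    if not order:
        raise ValidationError("count_by_category requires a non-empty dataset")
    cats = list(catalog.categories)
    return [
        CategoryCounts(
            drug=drug,
            n_total=totals[drug],
            n_by_category={c: by_cat[drug].get(c, 0) for c in cats},
        )
        for drug in order
    ]


# ---------------------------------------------------------------------------
# Line-listing I/O

LINE_LISTING_COLUMNS: tuple[str, ...] = (
    "report_id",
    "drug",
    "age_group",
    "sex",
    "origin",
    "reporter",
    "pt",
    "soc",
    "outcome",
)

_DEMOGRAPHIC_FIELDS = ("drug", "age_group", "sex", "origin", "reporter")


def read_line_listing(path: str | Path, dialect: Mapping | None = None) -> list[ICSR]:
    """Read a canonical line-listing CSV into a list of ICSRs.

    ``dialect`` optionally carries ``{"columns": {file_col: canonical_col},
    "aliases": {field: {variant: canonical_value}}}`` so exports with
    different headers or value spellings can be ingested without editing
    the file. Rows sharing ``report_id`` are merged into one report with
    several reactions; their report-level fields must agree. Unmappable
    enum values are coerced to NS/Unknown and counted in a logged warning.
    """
    dialect = dialect or {}
    col_map = {str(k): str(v) for k, v in dialect.get("columns", {}).items()}
    aliases = dialect.get("aliases", {})

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames
        if header is None:
            raise SchemaError(f"{path}: empty file, expected a header row")
        canonical_header = [col_map.get(c, c) for c in header]
        missing = [c for c in LINE_LISTING_COLUMNS if c not in canonical_header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

        n_coerced = 0
        merged: dict[str, ICSR] = {}
        conflicts: dict[str, set[str]] = {}
        for lineno, raw_row in enumerate(reader, start=2):
            row = {col_map.get(k, k): (v or "") for k, v in raw_row.items() if k is not None}
            rid = row["report_id"].strip()
            if not rid:
                raise ValidationError(f"{path}:{lineno}: empty report_id")
            parsed: dict[str, object] = {}
            for fld in ("age_group", "sex", "origin", "reporter", "outcome"):
                member, ok = _parse_enum(fld, row[fld], aliases.get(fld))
                if not ok:
                    n_coerced += 1
                parsed[fld] = member
            reaction = Reaction(
                pt=" ".join(row["pt"].split()),
                soc=" ".join(row["soc"].split()),
                outcome=parsed["outcome"],  # type: ignore[arg-type]
            )
            if rid in merged:
                existing = merged[rid]
                incoming = (row["drug"].strip(), parsed["age_group"], parsed["sex"],
                            parsed["origin"], parsed["reporter"])
                current = (existing.suspected_drug, existing.age_group, existing.sex,
                           existing.origin, existing.reporter)
                if incoming != current:
                    bad = {
                        f for f, a, b in zip(_DEMOGRAPHIC_FIELDS, current, incoming) if a != b
                    }
                    conflicts.setdefault(rid, set()).update(bad)
                existing.reactions.append(reaction)
            else:
                merged[rid] = ICSR(
                    report_id=rid,
                    suspected_drug=row["drug"].strip(),
                    age_group=parsed["age_group"],  # type: ignore[arg-type]
                    sex=parsed["sex"],  # type: ignore[arg-type]
                    origin=parsed["origin"],  # type: ignore[arg-type]
                    reporter=parsed["reporter"],  # type: ignore[arg-type]
                    reactions=[reaction],
                )

    if conflicts:
        detail = "; ".join(
            f"{rid} ({', '.join(sorted(fields))})" for rid, fields in sorted(conflicts.items())
        )
        raise ValidationError(f"{path}: conflicting report-level fields for id(s): {detail}")
    if n_coerced:
        logger.warning("%s: %d unmappable field value(s) coerced to NS/Unknown", path, n_coerced)
    return list(merged.values())


def write_line_listing(reports: Iterable[ICSR], path: str | Path) -> None:
    """Write reports to the canonical line-listing CSV (one row per reaction)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LINE_LISTING_COLUMNS)
        for rep in reports:
            for rx in rep.reactions:
                writer.writerow(
                    (
                        rep.report_id,
                        rep.suspected_drug,
                        rep.age_group.value,
                        rep.sex.value,
                        rep.origin.value,
                        rep.reporter.value,
                        rx.pt,
                        rx.soc,
                        rx.outcome.value,
                    )
                )
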