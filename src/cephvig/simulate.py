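"""Seeded synthetic ICSR generator.

The generator emulates an aggregated spontaneous-reporting extract (in the
style of the EudraVigilance public line listings): per drug it takes the
total number of reports, report-level event-category counts, demographic
marginals, and unfavorable-outcome counts per category, and materialises a
concrete list of :class:`~cephvig.icsr.ICSR` records.

Category flags and outcome labels are *allocated* exactly (assigned to
report slots and then shuffled with a seeded RNG), never Bernoulli-sampled:
recomputing category counts from a simulated dataset returns the configured
counts for every seed, so downstream odds ratios computed from aggregate
counts are reproduced exactly rather than in expectation. Demographic
marginals may be exact counts (allocated the same way) or probability
vectors (sampled). Identical seeds give byte-identical line listings.

:func:`reserve_fixture` loads a packaged preset encoding the published
per-drug aggregates of the five WHO Reserve-group cephalosporins from the
EudraVigilance portal (reports up to 26 January 2025).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import InfeasibleConfigError
from .icsr import (
    CATEGORY_SOC,
    ICSR,
    Outcome,
    PTCatalog,
    Reaction,
    _ENUM_FOR_FIELD,
    default_catalog,
)

__all__ = [
    "DrugConfig",
    "SimConfig",
    "simulate_dataset",
    "reserve_fixture",
    "FILLER_REACTIONS",
    "RESERVE_DRUGS",
    "WATCH_DRUGS",
]

#: The five Reserve-group cephalosporins, in canonical order.
RESERVE_DRUGS: tuple[str, ...] = (
    "cefiderocol",
    "ceftaroline",
    "ceftazidime/avibactam",
    "ceftobiprole",
    "ceftolozane/tazobactam",
)

#: The fourteen Watch-group cephalosporin comparators.
WATCH_DRUGS: tuple[str, ...] = (
    "cefepime",
    "cefpirome",
    "cefcapene pivoxil",
    "cefdinir",
    "cefditoren pivoxil",
    "cefixime",
    "cefodizime",
    "cefoperazone",
    "cefotaxime",
    "cefpodoxime proxetil",
    "ceftazidime",
    "ceftibuten",
    "ceftizoxime",
    "ceftriaxone",
)

#: Common (non-category) reactions used to fill reports that carry no
#: study-category PT, with their SOCs.
FILLER_REACTIONS: tuple[tuple[str, str], ...] = (
    ("Pyrexia", "General disorders and administration site conditions"),
    ("Diarrhoea", "Gastrointestinal disorders"),
    ("Rash", "Skin and subcutaneous tissue disorders"),
    ("Acute kidney injury", "Renal and urinary disorders"),
    ("Thrombocytopenia", "Blood and lymphatic system disorders"),
    ("Seizure", "Nervous system disorders"),
    ("Hepatic enzyme increased", "Hepatobiliary disorders"),
    ("Infusion site reaction", "General disorders and administration site conditions"),
    ("Clostridium difficile colitis", "Infections and infestations"),
    ("Hypersensitivity", "Immune system disorders"),
)

_OUTCOME_NAMES: dict[str, Outcome] = {
    "Fatal": Outcome.FATAL,
    "NotRecovered": Outcome.NOT_RECOVERED,
    "RecoveredWithSequelae": Outcome.RECOVERED_WITH_SEQUELAE,
    "Recovering": Outcome.RECOVERING,
    "Recovered": Outcome.RECOVERED,
    "Unknown": Outcome.UNKNOWN,
} | {o.value: o for o in Outcome}

_PROB_TOL = 1e-9


@dataclass
class DrugConfig:
    """Per-drug simulation marginals.

    demographics maps field name (age_group/sex/origin/reporter) to a
    level->value mapping; integer values are exact counts (must sum to
    n_total), float values are probabilities (must sum to 1). outcomes maps
    category -> outcome-name -> exact count within that category's reports;
    unallocated category reports get outcome Unknown. category_overlap
    lists pairs of categories sharing reports (default: categories are
    assigned to disjoint report subsets).
    """

    name: str
    n_total: int
    category_counts: dict[str, int] = field(default_factory=dict)
    demographics: dict[str, dict[str, float]] = field(default_factory=dict)
    outcomes: dict[str, dict[str, int]] = field(default_factory=dict)
    category_overlap: dict[tuple[str, str], int] = field(default_factory=dict)
    abbrev: str = ""

    def validate(self, catalog: PTCatalog) -> None:
        if self.n_total < 0:
            raise InfeasibleConfigError(f"{self.name}: n_total must be >= 0")
        for cat, n in self.category_counts.items():
            if cat not in catalog.categories:
                raise InfeasibleConfigError(f"{self.name}: unknown category {cat!r}")
            if not 0 <= n <= self.n_total:
                raise InfeasibleConfigError(
                    f"{self.name}: category {cat!r} count {n} exceeds n_total {self.n_total}"
                )
        overlap_total = 0
        for (c1, c2), n in self.category_overlap.items():
            if c1 == c2:
                raise InfeasibleConfigError(f"{self.name}: overlap pair ({c1!r}, {c2!r}) is degenerate")
            for c in (c1, c2):
                if c not in self.category_counts:
                    raise InfeasibleConfigError(f"{self.name}: overlap names unconfigured category {c!r}")
            if n < 0 or n > min(self.category_counts[c1], self.category_counts[c2]):
                raise InfeasibleConfigError(f"{self.name}: overlap count {n} infeasible for ({c1}, {c2})")
            overlap_total += n
        distinct = sum(self.category_counts.values()) - overlap_total
        if distinct > self.n_total:
            raise InfeasibleConfigError(
                f"{self.name}: category counts need {distinct} distinct reports, "
                f"only {self.n_total} available"
            )
        for fld, marg in self.demographics.items():
            if fld not in _ENUM_FOR_FIELD or fld == "outcome":
                raise InfeasibleConfigError(f"{self.name}: unknown demographic field {fld!r}")
            enum_cls = _ENUM_FOR_FIELD[fld]
            valid = {m.value for m in enum_cls}
            for level in marg:
                if level not in valid:
                    raise InfeasibleConfigError(
                        f"{self.name}: {fld} level {level!r} not in {sorted(valid)}"
                    )
            values = list(marg.values())
            if all(float(v).is_integer() for v in values):
                if int(sum(values)) != self.n_total:
                    raise InfeasibleConfigError(
                        f"{self.name}: {fld} counts sum to {int(sum(values))}, expected {self.n_total}"
                    )
            else:
                if abs(sum(values) - 1.0) > _PROB_TOL:
                    raise InfeasibleConfigError(
                        f"{self.name}: {fld} probabilities sum to {sum(values)}, expected 1"
                    )
                if any(v < 0 for v in values):
                    raise InfeasibleConfigError(f"{self.name}: {fld} has negative probability")
        for cat, outc in self.outcomes.items():
            if cat not in self.category_counts:
                raise InfeasibleConfigError(
                    f"{self.name}: outcomes given for unconfigured category {cat!r}"
                )
            for name, n in outc.items():
                if name not in _OUTCOME_NAMES:
                    raise InfeasibleConfigError(f"{self.name}: unknown outcome {name!r}")
                if n < 0:
                    raise InfeasibleConfigError(f"{self.name}: negative outcome count")
            if sum(outc.values()) > self.category_counts[cat]:
                raise InfeasibleConfigError(
                    f"{self.name}: outcome counts for {cat!r} exceed its report count"
                )


@dataclass
class SimConfig:
    """A full simulation scenario: per-drug marginals plus the RNG seed."""

    drugs: list[DrugConfig]
    seed: int = 0

    def validate(self, catalog: PTCatalog | None = None) -> None:
        catalog = catalog or default_catalog()
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise InfeasibleConfigError("duplicate drug names in config")
        for drug in self.drugs:
            drug.validate(catalog)

    # -- serialisation ------------------------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        drugs = []
        for name, spec in data["drugs"].items():
            overlap = {
                (entry["categories"][0], entry["categories"][1]): int(entry["count"])
                for entry in spec.get("category_overlap", [])
            }
            drugs.append(
                DrugConfig(
                    name=name,
                    n_total=int(spec["n_total"]),
                    category_counts={k: int(v) for k, v in spec.get("categories", {}).items()},
                    demographics={
                        fld: dict(marg) for fld, marg in spec.get("demographics", {}).items()
                    },
                    outcomes={
                        cat: {k: int(v) for k, v in outc.items()}
                        for cat, outc in spec.get("outcomes", {}).items()
                    },
                    category_overlap=overlap,
                    abbrev=spec.get("abbrev", ""),
                )
            )
        return cls(drugs=drugs, seed=int(data.get("seed", 0)))

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed, "drugs": {}}
        for d in self.drugs:
            spec: dict = {"n_total": d.n_total}
            if d.abbrev:
                spec["abbrev"] = d.abbrev
            if d.category_counts:
                spec["categories"] = dict(d.category_counts)
            if d.demographics:
                spec["demographics"] = {f: dict(m) for f, m in d.demographics.items()}
            if d.outcomes:
                spec["outcomes"] = {c: dict(o) for c, o in d.outcomes.items()}
            if d.category_overlap:
                spec["category_overlap"] = [
                    {"categories": list(pair), "count": n}
                    for pair, n in d.category_overlap.items()
                ]
            out["drugs"][d.name] = spec
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False, allow_unicode=True)


def _slug(name: str) -> str:
    return "".join(ch for ch in name.upper() if ch.isalnum())[:8]


def _allocate_levels(rng: np.random.Generator, n: int, marg: Mapping[str, float],
                     enum_cls) -> list:
    """Assign one enum level per slot: exact counts shuffled, or sampled."""
    levels = list(marg)
    values = list(marg.values())
    if all(float(v).is_integer() for v in values):
        pool = np.repeat(np.arange(len(levels)), [int(v) for v in values])
        rng.shuffle(pool)
        idx = pool
    else:
        p = np.asarray(values, dtype=float)
        idx = rng.choice(len(levels), size=n, p=p / p.sum())
    return [enum_cls(levels[i]) for i in idx]


def simulate_dataset(config: SimConfig, catalog: PTCatalog | None = None) -> list[ICSR]:
    """Materialise a list of ICSRs realising ``config`` exactly.

    Category flags, exact demographic counts, and outcome labels are
    deterministic allocations shuffled by the seeded RNG; only
    probability-specified demographics involve sampling. The same config
    and seed always produce the same dataset.
    """
    catalog = catalog or default_catalog()
    config.validate(catalog)
    rng = np.random.default_rng(config.seed)
    cat_order = list(catalog.categories)
    reports: list[ICSR] = []

    for drug in config.drugs:
        n = drug.n_total
        slot_cats: list[list[str]] = [[] for _ in range(n)]
        cursor = 0
        # shared slots for overlapping category pairs, then disjoint remainders
        assigned = {c: 0 for c in drug.category_counts}
        for (c1, c2), k in sorted(drug.category_overlap.items()):
            for _ in range(k):
                slot_cats[cursor].extend((c1, c2))
                cursor += 1
            assigned[c1] += k
            assigned[c2] += k
        for cat in sorted(drug.category_counts):
            for _ in range(drug.category_counts[cat] - assigned[cat]):
                slot_cats[cursor].append(cat)
                cursor += 1

        # per-slot, per-category outcomes (allocation order, pre-shuffle)
        slot_outcomes: list[dict[str, Outcome]] = [{} for _ in range(n)]
        slots_of_cat = {
            cat: [i for i in range(n) if cat in slot_cats[i]] for cat in drug.category_counts
        }
        for cat, outc in drug.outcomes.items():
            pool: list[Outcome] = []
            for name, k in outc.items():
                pool.extend([_OUTCOME_NAMES[name]] * k)
            pool.extend([Outcome.UNKNOWN] * (len(slots_of_cat[cat]) - len(pool)))
            for i, slot in enumerate(slots_of_cat[cat]):
                slot_outcomes[slot][cat] = pool[i]

        perm = rng.permutation(n)
        slot_cats = [slot_cats[i] for i in perm]
        slot_outcomes = [slot_outcomes[i] for i in perm]

        demo: dict[str, list] = {}
        for fld in ("age_group", "sex", "origin", "reporter"):
            enum_cls = _ENUM_FOR_FIELD[fld]
            if fld in drug.demographics:
                demo[fld] = _allocate_levels(rng, n, drug.demographics[fld], enum_cls)
            else:
                demo[fld] = [enum_cls("NS")] * n

        prefix = drug.abbrev or _slug(drug.name)
        for i in range(n):
            reactions: list[Reaction] = []
            for cat in cat_order:
                if cat in slot_cats[i]:
                    pts = catalog.categories[cat]
                    pt = pts[int(rng.integers(len(pts)))]
                    reactions.append(
                        Reaction(
                            pt=pt,
                            soc=CATEGORY_SOC.get(cat, ""),
                            outcome=slot_outcomes[i].get(cat, Outcome.UNKNOWN),
                        )
                    )
            if not reactions:
                pt, soc = FILLER_REACTIONS[int(rng.integers(len(FILLER_REACTIONS)))]
                reactions.append(Reaction(pt=pt, soc=soc, outcome=Outcome.UNKNOWN))
            reports.append(
                ICSR(
                    report_id=f"{prefix}-{i + 1:05d}",
                    suspected_drug=drug.name,
                    age_group=demo["age_group"][i],
                    sex=demo["sex"][i],
                    origin=demo["origin"][i],
                    reporter=demo["reporter"][i],
                    reactions=reactions,
                )
            )
    return reports


def reserve_fixture(
    resistance_split: tuple[int, int] = (24, 24),
    seed: int | None = None,
) -> SimConfig:
    """Preset encoding the published Reserve-cephalosporin aggregates.

    The five drugs' report totals (904/559/560/176/146), per-category
    report counts, demographic marginals, and unfavorable-outcome counts
    are taken from the published aggregated tables. The split of the 48
    resistance reports between ceftaroline and ceftolozane/tazobactam is
    not published; it is exposed as ``resistance_split`` (ceftaroline
    first) and defaults to an even 24/24. No published odds ratio depends
    on that split.
    """
    ref = importlib.resources.files("cephvig").joinpath("data/reserve_fixture.yaml")
    config = SimConfig.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))
    ctr, ctz = resistance_split
    if ctr + ctz != 48 or min(ctr, ctz) < 0:
        raise InfeasibleConfigError(
            f"resistance_split must be two non-negative counts summing to 48, got {resistance_split}"
        )
    for drug in config.drugs:
        if drug.name == "ceftaroline":
            drug.category_counts["resistance"] = ctr
        elif drug.name == "ceftolozane/tazobactam":
            drug.category_counts["resistance"] = ctz
    if seed is not None:
        config.seed = seed
    return config
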