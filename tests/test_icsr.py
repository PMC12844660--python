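"""Data model, PT classification, and line-listing I/O."""

import pytest

from cephvig import (
    ICSR,
    AgeGroup,
    Origin,
    Outcome,
    PTCatalog,
    Reaction,
    Reporter,
    SchemaError,
    Sex,
    ValidationError,
    classify_report,
    count_by_category,
    default_catalog,
    load_catalog,
    read_line_listing,
    worst_outcome,
    write_line_listing,
)

HEADER = "report_id,drug,age_group,sex,origin,reporter,pt,soc,outcome\n"


def make_report(rid="R1", drug="ceftaroline", pts=("Pyrexia",), outcome=Outcome.UNKNOWN):
    return ICSR(
        report_id=rid,
        suspected_drug=drug,
        reactions=[Reaction(pt=pt, outcome=outcome) for pt in pts],
    )


class TestCatalog:
    def test_default_catalog_category_sizes(self, catalog):
        sizes = {name: len(pts) for name, pts in catalog.categories.items()}
        assert sizes == {"resistance": 3, "ineffectiveness": 11, "off_label": 8}

    def test_pt_membership_is_case_and_whitespace_insensitive(self, catalog):
        assert catalog.category_of("  drug   RESISTANCE ") == "resistance"
        assert catalog.category_of("Off label use") == "off_label"
        assert catalog.category_of("Pyrexia") is None

    def test_duplicate_pt_across_categories_rejected(self):
        with pytest.raises(ValidationError, match="appears in both"):
            PTCatalog.from_mapping({"a": ["Drug ineffective"], "b": ["drug  ineffective"]})

    def test_empty_pt_list_rejected(self):
        with pytest.raises(ValidationError, match="empty PT list"):
            PTCatalog.from_mapping({"a": []})

    def test_catalog_yaml_round_trip(self, tmp_path, catalog):
        path = tmp_path / "catalog.yaml"
        import yaml

        path.write_text(yaml.safe_dump(catalog.to_mapping()))
        assert load_catalog(path).categories == catalog.categories


class TestClassification:
    def test_single_category_membership(self, catalog):
        rep = make_report(pts=("Drug resistance",))
        assert classify_report(rep, catalog) == {"resistance"}

    def test_multiple_categories_and_no_category(self, catalog):
        both = make_report(pts=("Drug resistance", "Off label use"))
        assert classify_report(both, catalog) == {"resistance", "off_label"}
        assert classify_report(make_report(pts=("Pyrexia",)), catalog) == set()

    def test_reaction_order_irrelevant(self, catalog):
        pts = ("Drug ineffective", "Pyrexia", "Off label use")
        fwd = make_report(pts=pts)
        rev = make_report(pts=pts[::-1])
        assert classify_report(fwd, catalog) == classify_report(rev, catalog)

    def test_report_level_counting_single_contribution(self, catalog):
        # two resistance PTs on one report still count one resistance case
        rep = make_report(pts=("Drug resistance", "Pathogen resistance"))
        counts = count_by_category([rep], catalog)
        assert counts[0].n_by_category["resistance"] == 1
        assert counts[0].n_total == 1

    def test_totals_partition_dataset(self, catalog):
        reports = [make_report(rid=f"R{i}", drug=d) for i, d in
                   enumerate(["a", "b", "a", "c", "b", "a"])]
        counts = count_by_category(reports, catalog)
        assert sum(c.n_total for c in counts) == len(reports)


class TestWorstOutcome:
    @pytest.mark.parametrize(
        "outcomes,expected",
        [
            ((Outcome.RECOVERED, Outcome.FATAL), Outcome.FATAL),
            ((Outcome.UNKNOWN, Outcome.RECOVERING), Outcome.RECOVERING),
            ((Outcome.RECOVERED, Outcome.RECOVERING), Outcome.RECOVERING),
            ((Outcome.NOT_RECOVERED, Outcome.RECOVERED_WITH_SEQUELAE), Outcome.NOT_RECOVERED),
            ((Outcome.UNKNOWN,), Outcome.UNKNOWN),
        ],
    )
    def test_severity_ordering(self, outcomes, expected):
        rep = ICSR(
            report_id="R1",
            suspected_drug="x",
            reactions=[Reaction(pt="Pyrexia", outcome=o) for o in outcomes],
        )
        assert worst_outcome(rep) == expected


class TestLineListingIO:
    def test_rows_merge_by_report_id(self, tmp_path):
        path = tmp_path / "ll.csv"
        path.write_text(
            HEADER
            + "R1,ceftaroline,18-64 Years,Male,EEA,HP,Pyrexia,,Unknown\n"
            + "R1,ceftaroline,18-64 Years,Male,EEA,HP,Drug resistance,,Fatal\n"
            + "R2,ceftaroline,NS,NS,NS,NS,Rash,,Unknown\n"
        )
        reports = read_line_listing(path)
        assert len(reports) == 2
        by_id = {r.report_id: r for r in reports}
        assert len(by_id["R1"].reactions) == 2
        assert by_id["R1"].age_group is AgeGroup.YEARS_18_64

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(HEADER)
        assert read_line_listing(path) == []

    def test_value_aliases_map_case_insensitively(self, tmp_path):
        path = tmp_path / "ll.csv"
        path.write_text(
            HEADER
            + "R1,x,18–64 Years,male,eea,healthcare professional,Pyrexia,,recovered\n"
            + "R2,x,ns,M,Non EEA,hp,Rash,,died\n"
        )
        r1, r2 = read_line_listing(path)
        assert (r1.sex, r2.sex) == (Sex.MALE, Sex.MALE)
        assert (r1.origin, r2.origin) == (Origin.EEA, Origin.NON_EEA)
        assert (r1.reporter, r2.reporter) == (Reporter.HP, Reporter.HP)
        assert r1.reactions[0].outcome is Outcome.RECOVERED
        assert r2.reactions[0].outcome is Outcome.FATAL

    def test_unmappable_values_coerced_with_warning(self, tmp_path, caplog):
        path = tmp_path / "ll.csv"
        path.write_text(HEADER + "R1,x,bogus,??,EEA,HP,Pyrexia,,whatever\n")
        with caplog.at_level("WARNING", logger="cephvig.icsr"):
            (rep,) = read_line_listing(path)
        assert rep.age_group is AgeGroup.NS
        assert rep.sex is Sex.NS
        assert rep.reactions[0].outcome is Outcome.UNKNOWN
        assert "3 unmappable" in caplog.text

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("report_id,drug,age_group,sex,origin,reporter,pt,soc\n")
        with pytest.raises(SchemaError, match="outcome"):
            read_line_listing(path)

    def test_dialect_column_renames(self, tmp_path):
        path = tmp_path / "ev.csv"
        path.write_text(
            "case_id,drug,age_group,sex,origin,reporter,reaction_pt,soc,outcome\n"
            "R1,x,NS,NS,NS,NS,Pyrexia,,Unknown\n"
        )
        reports = read_line_listing(
            path, dialect={"columns": {"case_id": "report_id", "reaction_pt": "pt"}}
        )
        assert reports[0].report_id == "R1"
        assert reports[0].reactions[0].pt == "Pyrexia"

    def test_conflicting_demographics_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            HEADER
            + "R1,x,18-64 Years,Male,EEA,HP,Pyrexia,,Unknown\n"
            + "R1,x,18-64 Years,Female,EEA,HP,Rash,,Unknown\n"
        )
        with pytest.raises(ValidationError, match=r"R1 \(sex\)"):
            read_line_listing(path)

    def test_round_trip_identity(self, tmp_path, catalog):
        from cephvig import DrugConfig, SimConfig, simulate_dataset

        config = SimConfig(
            drugs=[DrugConfig(name="drug-a", n_total=60,
                              category_counts={"resistance": 10, "off_label": 5}),
                   DrugConfig(name="drug-b", n_total=40,
                              category_counts={"ineffectiveness": 7})],
            seed=11,
        )
        reports = simulate_dataset(config, catalog)
        assert len(reports) == 100
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_line_listing(reports, p1)
        again = read_line_listing(p1)
        assert again == reports
        write_line_listing(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_preserves_category_counts(self, tmp_path, fixture_reports, catalog):
        path = tmp_path / "fixture.csv"
        write_line_listing(fixture_reports, path)
        before = count_by_category(fixture_reports, catalog)
        after = count_by_category(read_line_listing(path), catalog)
        assert after == before

    def test_empty_report_list_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_line_listing([], path)
        assert path.read_text() == HEADER
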