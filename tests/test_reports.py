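"""Report store: dialect I/O, deduplication, filtering, case summaries."""

from __future__ import annotations

import datetime as dt
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal import (
    FilterCriteria,
    Outcome,
    ReporterType,
    Role,
    Sex,
    TermSet,
    deduplicate,
    filter_reports,
    load_reports,
    summarize_cases,
    write_reports,
)
from pvsignal.termsets import (
    load_term_sets,
    noninfectious_myopericarditis_smq,
    pericarditis_inducing_drugs,
    pericarditis_pt,
    pre_existing_disease_terms,
)

from conftest import make_report


# ---------------------------------------------------------------------------
# term sets
# ---------------------------------------------------------------------------

class TestTermSets:
    def test_membership_is_case_and_whitespace_insensitive(self):
        ts = TermSet("x", frozenset({"Systemic  Lupus Erythematosus"}))
        assert "systemic lupus erythematosus" in ts
        assert " SYSTEMIC LUPUS  ERYTHEMATOSUS " in ts
        assert "lupus" not in ts

    def test_empty_term_set_rejected(self):
        with pytest.raises(ValueError):
            TermSet("x", frozenset())
        with pytest.raises(ValueError):
            TermSet("x", frozenset({"  "}))

    def test_bundled_sets_load(self):
        assert len(noninfectious_myopericarditis_smq()) == 10
        assert "pericarditis" in noninfectious_myopericarditis_smq()
        assert len(pericarditis_pt()) == 1
        assert "systemic lupus erythematosus" in pre_existing_disease_terms()
        assert "sulfasalazine" in pericarditis_inducing_drugs()

    def test_term_file_round_trip(self, tmp_path):
        p = tmp_path / "terms.tsv"
        p.write_text("set_name\tterm\ns1\tFoo Bar\ns1\tbaz\ns2\tqux\n")
        sets = load_term_sets(p)
        assert set(sets) == {"s1", "s2"}
        assert "foo bar" in sets["s1"] and len(sets["s1"]) == 2


# ---------------------------------------------------------------------------
# simple_tabular dialect
# ---------------------------------------------------------------------------

def _write_simple(tmp_path, reports_rows, drugs_rows, events_rows):
    (tmp_path / "reports.csv").write_text(
        "report_id,version_date,receipt_quarter,reporter_type,sex,age_years,outcomes\n"
        + "".join(r + "\n" for r in reports_rows))
    (tmp_path / "drugs.csv").write_text(
        "report_id,name,role,indication,start_date\n"
        + "".join(r + "\n" for r in drugs_rows))
    (tmp_path / "events.csv").write_text(
        "report_id,pt,onset_date\n" + "".join(r + "\n" for r in events_rows))


class TestSimpleTabular:
    def test_five_row_fixture_nests_into_two_reports(self, tmp_path):
        _write_simple(
            tmp_path,
            ["r1,2021-05-01,2021Q2,healthcare_professional,female,44,death|hospitalization",
             "r2,2020-01-15,2020Q1,consumer,male,,"],
            ["r1,Adalimumab,PS,ankylosing spondylitis,2020-06-01",
             "r1,methotrexate,C,,",
             "r2,INFLIXIMAB,SS,,"],
            ["r1,Pericarditis,2021-04-20", "r2,nausea,"],
        )
        reports = load_reports(tmp_path)
        assert len(reports) == 2
        r1 = next(r for r in reports if r.report_id == "r1")
        assert r1.sex is Sex.female and r1.age_years == 44
        assert r1.outcomes == {Outcome.death, Outcome.hospitalization}
        assert {d.name for d in r1.drugs} == {"adalimumab", "methotrexate"}
        assert r1.drugs[0].role is Role.primary_suspect
        assert r1.drugs[0].indication == "ankylosing spondylitis"
        assert r1.events[0].pt == "pericarditis"
        assert r1.events[0].onset_date == dt.date(2021, 4, 20)
        r2 = next(r for r in reports if r.report_id == "r2")
        assert r2.age_years is None and r2.outcomes == frozenset()
        assert r2.drugs[0].name == "infliximab"

    def test_header_only_gives_empty_collection(self, tmp_path):
        _write_simple(tmp_path, [], [], [])
        assert load_reports(tmp_path) == []

    def test_role_code_c_maps_to_concomitant(self, tmp_path):
        _write_simple(tmp_path,
                      ["r1,2021-05-01,2021Q2,unspecified,missing,,"],
                      ["r1,drugx,C,,"], [])
        (r,) = load_reports(tmp_path)
        assert r.drugs[0].role is Role.concomitant

    def test_unknown_role_warns_and_maps_to_concomitant(self, tmp_path):
        _write_simple(tmp_path,
                      ["r1,2021-05-01,2021Q2,unspecified,missing,,"],
                      ["r1,drugx,XX,,"], [])
        with pytest.warns(UserWarning, match="unknown role"):
            (r,) = load_reports(tmp_path)
        assert r.drugs[0].role is Role.concomitant

    def test_malformed_row_names_file_and_line(self, tmp_path):
        _write_simple(tmp_path,
                      ["r1,2021-05-01,2021Q2,unspecified,missing,,",
                       "r2,not-a-date,2021Q2,unspecified,missing,,"],
                      [], [])
        with pytest.raises(ValueError, match=r"reports\.csv:3"):
            load_reports(tmp_path)

    def test_round_trip_preserves_every_field(self, tmp_path):
        reports = [
            make_report("r1", drugs=[("adalimumab", Role.primary_suspect,
                                      "ankylosing spondylitis", dt.date(2019, 3, 4))],
                        events=[("pericarditis", dt.date(2020, 1, 10)), "nausea"],
                        sex=Sex.female, age=44.5,
                        reporter=ReporterType.healthcare_professional,
                        outcomes=[Outcome.death]),
            make_report("r2", drugs=["infliximab"], quarter="2010Q4",
                        vdate=dt.date(2010, 11, 3)),
        ]
        write_reports(reports, tmp_path / "out")
        assert load_reports(tmp_path / "out") == reports

    def test_missing_directory_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_reports(tmp_path / "nope")


class TestFaersAscii:
    def test_demo_drug_reac_nesting(self, tmp_path):
        (tmp_path / "DEMO23Q1.txt").write_text(
            "primaryid$caseid$fda_dt$sex$age$age_cod$occp_cod\n"
            "1001$100$20210215$F$44$YR$MD\n"
            "2001$200$20200120$$24$MON$CN\n")
        (tmp_path / "DRUG23Q1.txt").write_text(
            "primaryid$drug_seq$role_cod$drugname\n"
            "1001$1$PS$ADALIMUMAB\n1001$2$C$Methotrexate\n2001$1$SS$infliximab\n")
        (tmp_path / "REAC23Q1.txt").write_text(
            "primaryid$pt\n1001$Pericarditis\n2001$Nausea\n")
        (tmp_path / "INDI23Q1.txt").write_text(
            "primaryid$indi_drug_seq$indi_pt\n1001$1$Ankylosing spondylitis\n")
        (tmp_path / "OUTC23Q1.txt").write_text(
            "primaryid$outc_cod\n1001$DE\n1001$HO\n")
        reports = load_reports(tmp_path, dialect="faers_ascii")
        assert len(reports) == 2
        r1 = next(r for r in reports if r.report_id == "100")
        assert r1.receipt_quarter == "2021Q1" and r1.sex is Sex.female
        assert r1.reporter_type is ReporterType.healthcare_professional
        assert r1.outcomes == {Outcome.death, Outcome.hospitalization}
        assert r1.drugs[0].indication == "ankylosing spondylitis"
        assert r1.drugs[1].indication is None
        r2 = next(r for r in reports if r.report_id == "200")
        assert r2.sex is Sex.missing and r2.age_years == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

class TestDeduplicate:
    def test_latest_version_wins(self):
        old = make_report("A1", quarter="2020Q1", vdate=dt.date(2020, 2, 1),
                          events=["nausea"])
        new = make_report("A1", quarter="2021Q3", vdate=dt.date(2021, 8, 1),
                          events=["pericarditis"])
        assert deduplicate([old, new]) == [new]
        assert deduplicate([new, old]) == [new]

    def test_no_duplicates_is_identity_sorted(self):
        reports = [make_report("B"), make_report("A")]
        assert deduplicate(reports) == sorted(reports, key=lambda r: r.report_id)

    def test_date_tie_broken_by_version_marker_deterministically(self):
        versions = [
            make_report("A1", vdate=dt.date(2020, 2, 1), version_id="100-1"),
            make_report("A1", vdate=dt.date(2021, 8, 1), version_id="100-2"),
            make_report("A1", vdate=dt.date(2021, 8, 1), version_id="100-3"),
        ]
        for perm in itertools.permutations(versions):
            (kept,) = deduplicate(perm)
            assert kept.version_id == "100-3"

    @given(st.permutations(list(range(6))))
    @settings(deadline=None)
    def test_idempotent_and_order_invariant(self, order):
        base = [
            make_report("A", vdate=dt.date(2020, 1, 1), version_id="1"),
            make_report("A", vdate=dt.date(2021, 1, 1), version_id="2"),
            make_report("B", vdate=dt.date(2019, 1, 1), version_id="1"),
            make_report("B", vdate=dt.date(2019, 1, 1), version_id="2"),
            make_report("C", vdate=dt.date(2018, 1, 1)),
            make_report("C", vdate=dt.date(2018, 6, 1)),
        ]
        shuffled = [base[i] for i in order]
        once = deduplicate(shuffled)
        assert deduplicate(once) == once
        assert once == deduplicate(base)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@pytest.fixture
def ten_reports():
    lupus = "systemic lupus erythematosus"
    reports = []
    for i in range(10):
        events = ["nausea"]
        if i < 3:
            events.append(lupus)
        reporter = (ReporterType.healthcare_professional if i < 4
                    else ReporterType.consumer)
        reports.append(make_report(
            f"r{i}", drugs=[("drugx", Role.primary_suspect if i % 2 else Role.concomitant)],
            events=events, reporter=reporter,
            quarter="2019Q1" if i < 5 else "2021Q3"))
    return reports


class TestFilterReports:
    def test_event_exclusion_drops_carriers(self, ten_reports):
        crit = FilterCriteria(exclude_event_terms=TermSet(
            "excl", frozenset({"systemic lupus erythematosus"})))
        assert len(filter_reports(ten_reports, crit)) == 7

    def test_all_none_is_identity(self, ten_reports):
        assert filter_reports(ten_reports, FilterCriteria()) == ten_reports

    def test_reporter_restriction(self, ten_reports):
        crit = FilterCriteria(
            reporter_types=frozenset({ReporterType.healthcare_professional}))
        assert len(filter_reports(ten_reports, crit)) == 4

    def test_quarter_window_and_drug_exclusion(self, ten_reports):
        crit = FilterCriteria(quarter_window=("2019Q1", "2019Q4"))
        assert len(filter_reports(ten_reports, crit)) == 5
        crit = FilterCriteria(exclude_drugs=frozenset({"DrugX"}))
        assert filter_reports(ten_reports, crit) == []

    def test_conjunction_equals_sequential_application_any_order(self, ten_reports):
        c1 = FilterCriteria(reporter_types=frozenset({ReporterType.healthcare_professional}))
        c2 = FilterCriteria(exclude_event_terms=TermSet(
            "excl", frozenset({"systemic lupus erythematosus"})))
        both = FilterCriteria(
            reporter_types=frozenset({ReporterType.healthcare_professional}),
            exclude_event_terms=TermSet("excl", frozenset({"systemic lupus erythematosus"})))
        seq_12 = filter_reports(filter_reports(ten_reports, c1), c2)
        seq_21 = filter_reports(filter_reports(ten_reports, c2), c1)
        assert filter_reports(ten_reports, both) == seq_12 == seq_21

    def test_empty_exclude_drugs_rejected(self):
        with pytest.raises(ValueError):
            FilterCriteria(exclude_drugs=frozenset())


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------

class TestSummarizeCases:
    def test_sex_percentages(self, pericarditis_terms):
        reports = [make_report(f"r{i}", drugs=["drugx"], events=["pericarditis"],
                               sex=Sex.female) for i in range(5)]
        reports.append(make_report("r5", drugs=["drugx"], events=["pericarditis"]))
        df = summarize_cases(reports, "drugx", pericarditis_terms)
        sex = df[df.section == "sex"].set_index("category")
        assert sex.loc["female", "percent"] == pytest.approx(83.3, abs=0.05)
        assert sex.loc["missing", "percent"] == pytest.approx(16.7, abs=0.05)

    def test_singleton_death_outcome(self, pericarditis_terms):
        reports = [make_report("r0", drugs=["drugx"], events=["pericarditis"],
                               outcomes=[Outcome.death])]
        df = summarize_cases(reports, "drugx", pericarditis_terms)
        row = df[(df.section == "outcome") & (df.category == "death")]
        assert row["count"].item() == 1 and row["percent"].item() == 100.0

    def test_drug_in_two_roles_counts_in_both_rows(self, pericarditis_terms):
        r = make_report("r0", drugs=[("drugx", Role.primary_suspect),
                                     ("drugx", Role.secondary_suspect)],
                        events=["pericarditis"])
        df = summarize_cases([r], "drugx", pericarditis_terms)
        role = df[df.section == "role"].set_index("category")
        assert role.loc["PS", "count"] == 1 and role.loc["SS", "count"] == 1
        # role percentages may exceed 100% in total
        assert role["percent"].sum() == 200.0

    def test_partition_percentages_sum_to_100(self, pericarditis_terms):
        reports = [make_report(f"r{i}", drugs=["drugx"], events=["pericarditis"],
                               sex=[Sex.male, Sex.female, Sex.missing][i % 3],
                               age=[20, 44, 70, None][i % 4],
                               quarter=["2005Q2", "2012Q1", "2016Q3", "2021Q4"][i % 4])
                   for i in range(11)]
        df = summarize_cases(reports, "drugx", pericarditis_terms)
        for section in ("sex", "age_band", "report_year"):
            total = df[df.section == section]["percent"].sum()
            assert total == pytest.approx(100.0, abs=1e-9)

    def test_no_matching_cases_gives_empty_table(self, pericarditis_terms):
        df = summarize_cases([make_report("r0", drugs=["drugy"])],
                             "drugx", pericarditis_terms)
        assert df.empty and df.attrs["n_cases"] == 0

    def test_co_reported_events_exclude_index_terms(self, pericarditis_terms):
        r = make_report("r0", drugs=["drugx"], events=["pericarditis", "nausea"])
        df = summarize_cases([r], "drugx", pericarditis_terms)
        co = df[df.section == "co_reported_event"]
        assert list(co.category) == ["nausea"]
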