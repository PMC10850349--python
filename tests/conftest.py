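"""Shared fixtures: small hand-built report collections and random-collection
builders used by the brute-force oracle tests."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from pvsignal import (
    DrugMention,
    EventMention,
    Outcome,
    ReportRecord,
    ReporterType,
    Role,
    Sex,
    TermSet,
)


def make_report(rid: str, drugs=(), events=(), sex=Sex.missing, age=None,
                reporter=ReporterType.unspecified, quarter="2020Q1",
                vdate=dt.date(2020, 2, 1), outcomes=(), version_id="") -> ReportRecord:
    """Terse report builder: drugs as (name, role[, indication]) tuples,
    events as PT strings or (pt, onset) tuples."""
    drug_mentions = []
    for d in drugs:
        if isinstance(d, str):
            d = (d, Role.secondary_suspect)
        name, role, *rest = d
        drug_mentions.append(DrugMention(
            name=name, role=role,
            indication=rest[0] if rest else None,
            start_date=rest[1] if len(rest) > 1 else None))
    event_mentions = []
    for e in events:
        if isinstance(e, str):
            event_mentions.append(EventMention(pt=e))
        else:
            event_mentions.append(EventMention(pt=e[0], onset_date=e[1]))
    return ReportRecord(
        report_id=rid, version_date=vdate, receipt_quarter=quarter,
        reporter_type=reporter, sex=sex, age_years=age,
        drugs=tuple(drug_mentions), events=tuple(event_mentions),
        outcomes=frozenset(outcomes), version_id=version_id)


@pytest.fixture
def pericarditis_terms() -> TermSet:
    return TermSet("pericarditis", frozenset({"pericarditis"}))


@pytest.fixture
def twelve_report_fixture(pericarditis_terms):
    """3 drugx+event, 2 drugx only, 4 event only, 3 neither."""
    reports = []
    for i in range(3):
        reports.append(make_report(f"A{i}", drugs=["drugx"], events=["pericarditis"]))
    for i in range(2):
        reports.append(make_report(f"B{i}", drugs=["drugx"], events=["nausea"]))
    for i in range(4):
        reports.append(make_report(f"C{i}", drugs=["drugy"], events=["pericarditis"]))
    for i in range(3):
        reports.append(make_report(f"D{i}", drugs=["drugz"], events=["headache"]))
    return reports


DRUG_POOL = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
EVENT_POOL = ["pericarditis", "nausea", "headache", "rash"]


def random_collection(rng: np.random.Generator, n: int) -> list[ReportRecord]:
    """Random small collection exercising roles, indications, demographics,
    duplicate event mentions, and multi-drug reports."""
    roles = list(Role)
    reports = []
    for i in range(n):
        n_drugs = int(rng.integers(1, 4))
        drug_idx = rng.choice(len(DRUG_POOL), size=n_drugs, replace=False)
        drugs = tuple(
            DrugMention(
                name=DRUG_POOL[j],
                role=roles[int(rng.integers(0, len(roles)))],
                indication="ankylosing spondylitis" if rng.random() < 0.5 else None,
            )
            for j in drug_idx
        )
        n_events = int(rng.integers(0, 4))
        events = tuple(
            EventMention(pt=EVENT_POOL[int(rng.integers(0, len(EVENT_POOL)))])
            for _ in range(n_events)
        )
        quarter = f"{int(rng.integers(2004, 2023))}Q{int(rng.integers(1, 5))}"
        sex = [Sex.male, Sex.female, Sex.missing][int(rng.integers(0, 3))]
        reports.append(ReportRecord(
            report_id=f"R{i:05d}",
            version_date=dt.date(2020, 1, 1) + dt.timedelta(days=int(rng.integers(0, 1000))),
            receipt_quarter=quarter,
            reporter_type=list(ReporterType)[int(rng.integers(0, 3))],
            sex=sex,
            age_years=float(rng.integers(10, 90)) if rng.random() < 0.6 else None,
            drugs=drugs,
            events=events,
            outcomes=frozenset({Outcome.death} if rng.random() < 0.1 else ()),
        ))
    return reports
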