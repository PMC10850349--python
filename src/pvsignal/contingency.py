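"""Report-count contingency tables for the case/non-case design.

Every table counts deduplicated reports, each exactly once per cell, no
matter how many matching drug or event mentions it lists.  The 2x2 table
cross-classifies exposure (any index drug with a counted role) against the
event (any PT of a term set); the 2x2x2 table adds a second drug axis for
interaction surveillance.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .reports import (
    ReportRecord,
    Role,
    Sex,
    age_band,
    normalize_drug_name,
    quarter_year,
    year_bucket,
)
from .termsets import TermSet

__all__ = [
    "ContingencyTable",
    "TripleTable",
    "Comparator",
    "ExposureOptions",
    "build_2x2",
    "build_strata",
    "build_triple",
]

#: Default roles counted as exposure: suspects plus concomitants.
DEFAULT_ROLES = frozenset({Role.primary_suspect, Role.secondary_suspect, Role.concomitant})


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report counts: exposed/non-exposed x event/no-event."""

    n11: int  # exposed, event
    n10: int  # exposed, no event
    n01: int  # not exposed, event
    n00: int  # not exposed, no event

    def __post_init__(self) -> None:
        for cell in ("n11", "n10", "n01", "n00"):
            if getattr(self, cell) < 0:
                raise ValueError(f"{cell} negative")

    @property
    def drug_total(self) -> int:
        return self.n11 + self.n10

    @property
    def event_total(self) -> int:
        return self.n11 + self.n01

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @classmethod
    def from_margins(cls, n11: int, drug_total: int, event_total: int, total: int
                     ) -> "ContingencyTable":
        """Build the table from its observed cell and three margins — the form
        in which published screens print their counts."""
        n10 = drug_total - n11
        n01 = event_total - n11
        n00 = total - drug_total - n01
        return cls(n11=n11, n10=n10, n01=n01, n00=n00)


@dataclass(frozen=True)
class TripleTable:
    """2x2x2 report counts over (drug A) x (drug B) x (event).

    ``n_ab1``/``n_ab0`` are event/no-event counts in the exposure cell
    (a, b); ``nab_total(a, b)`` is that cell's report total.
    """

    n111: int
    n110: int
    n101: int
    n100: int
    n011: int
    n010: int
    n001: int
    n000: int

    def __post_init__(self) -> None:
        for cell in ("n111", "n110", "n101", "n100", "n011", "n010", "n001", "n000"):
            if getattr(self, cell) < 0:
                raise ValueError(f"{cell} negative")

    def event_count(self, a: int, b: int) -> int:
        return getattr(self, f"n{a}{b}1")

    def cell_total(self, a: int, b: int) -> int:
        return getattr(self, f"n{a}{b}1") + getattr(self, f"n{a}{b}0")

    @property
    def total(self) -> int:
        return sum(self.cell_total(a, b) for a in (0, 1) for b in (0, 1))

    def swapped(self) -> "TripleTable":
        """The same table with the two drug axes exchanged."""
        return TripleTable(n111=self.n111, n110=self.n110, n101=self.n011, n100=self.n010,
                           n011=self.n101, n010=self.n100, n001=self.n001, n000=self.n000)


class Comparator(str, enum.Enum):
    """Who the non-exposed arm is: everything else in the database, or only
    reports listing a named comparator drug."""

    rest_of_database = "rest_of_database"
    named_drug_list = "named_drug_list"


@dataclass(frozen=True)
class ExposureOptions:
    """How exposure and the comparator arm are defined.

    ``indication_restriction`` applies to the exposed arm only by default
    (the comparator is the unrestricted rest of the database); set
    ``restrict_comparator_indication`` to impose it on a named comparator
    arm as well.  A report listing both an index and a comparator drug is
    counted as exposed only (case/non-case exclusivity).
    """

    drug_names: frozenset[str]
    roles_counted: frozenset[Role] = DEFAULT_ROLES
    indication_restriction: TermSet | None = None
    comparator: Comparator = Comparator.rest_of_database
    comparator_drugs: frozenset[str] = frozenset()
    restrict_comparator_indication: bool = False

    def __post_init__(self) -> None:
        names = frozenset(normalize_drug_name(d) for d in self.drug_names)
        if not names:
            raise ValueError("drug_names must be non-empty")
        comp = frozenset(normalize_drug_name(d) for d in self.comparator_drugs)
        if self.comparator is Comparator.named_drug_list and not comp:
            raise ValueError("named_drug_list comparator needs comparator_drugs")
        if names & comp:
            raise ValueError(f"comparator_drugs overlap drug_names: {sorted(names & comp)}")
        object.__setattr__(self, "drug_names", names)
        object.__setattr__(self, "comparator_drugs", comp)
        object.__setattr__(self, "roles_counted", frozenset(self.roles_counted))

    def with_drugs(self, drug_names: Iterable[str]) -> "ExposureOptions":
        return replace(self, drug_names=frozenset(drug_names))

    def is_exposed(self, report: ReportRecord) -> bool:
        if not report.has_drug(self.drug_names, self.roles_counted):
            return False
        if self.indication_restriction is not None:
            return report.has_indication(self.indication_restriction)
        return True

    def in_comparator(self, report: ReportRecord) -> bool:
        """Membership in the non-exposed arm for a report already known not
        to be exposed."""
        if self.comparator is Comparator.rest_of_database:
            return True
        if not report.has_drug(self.comparator_drugs, self.roles_counted):
            return False
        if self.restrict_comparator_indication and self.indication_restriction is not None:
            return report.has_indication(self.indication_restriction)
        return True


def build_2x2(reports: Iterable[ReportRecord], event_terms: TermSet,
              options: ExposureOptions) -> ContingencyTable:
    """Cross-classify reports into the case/non-case 2x2 table.

    Exposed: any index drug with a counted role (and the indication
    restriction, if set).  Non-exposed: every remaining report under
    ``rest_of_database``, or remaining reports listing a comparator drug
    under ``named_drug_list``.  Event: any PT of ``event_terms``.
    """
    n11 = n10 = n01 = n00 = 0
    for r in reports:
        event = r.has_event(event_terms)
        if options.is_exposed(r):
            if event:
                n11 += 1
            else:
                n10 += 1
        elif options.in_comparator(r):
            if event:
                n01 += 1
            else:
                n00 += 1
    if n11 + n10 == 0:
        warnings.warn(
            f"no exposed reports for drugs {sorted(options.drug_names)}; "
            "ROR/IC will be degenerate"
        )
    return ContingencyTable(n11=n11, n10=n10, n01=n01, n00=n00)


class Stratifier(str, enum.Enum):
    sex = "sex"
    age_band = "age_band"
    year_bucket = "year_bucket"
    cumulative_quarter = "cumulative_quarter"


def build_strata(reports: Sequence[ReportRecord], event_terms: TermSet,
                 options: ExposureOptions, stratifier: str | Stratifier
                 ) -> dict[str, ContingencyTable]:
    """One 2x2 table per stratum.

    ``sex`` and ``age_band`` strata exclude missing-valued reports (they are
    retained in the unstratified analysis).  ``cumulative_quarter`` builds
    one table per distinct receipt quarter present, over all reports
    received up to and including that quarter.
    """
    strat = Stratifier(stratifier)
    out: dict[str, ContingencyTable] = {}
    if strat is Stratifier.sex:
        for sex in (Sex.male, Sex.female):
            sub = [r for r in reports if r.sex is sex]
            out[sex.value] = build_2x2(sub, event_terms, options)
    elif strat is Stratifier.age_band:
        for band in ("0-24", "25-65", ">65"):
            sub = [r for r in reports if age_band(r.age_years) == band]
            out[band] = build_2x2(sub, event_terms, options)
    elif strat is Stratifier.year_bucket:
        buckets = sorted({year_bucket(quarter_year(r.receipt_quarter)) for r in reports})
        for bucket in buckets:
            sub = [r for r in reports
                   if year_bucket(quarter_year(r.receipt_quarter)) == bucket]
            out[bucket] = build_2x2(sub, event_terms, options)
    else:  # cumulative_quarter
        quarters = sorted({r.receipt_quarter for r in reports})
        for q in quarters:
            sub = [r for r in reports if r.receipt_quarter <= q]
            out[q] = build_2x2(sub, event_terms, options)
    return out


def build_triple(reports: Iterable[ReportRecord], drug_a: Iterable[str],
                 drug_b: Iterable[str], event_terms: TermSet,
                 options: ExposureOptions | None = None) -> TripleTable:
    """Cross-classify by presence of drug set A x drug set B x event.

    Role counting and the indication restriction (applied to reports
    exposed to either drug set) follow ``options``; drug sets must be
    disjoint.
    """
    set_a = frozenset(normalize_drug_name(d) for d in drug_a)
    set_b = frozenset(normalize_drug_name(d) for d in drug_b)
    if not set_a or not set_b:
        raise ValueError("both drug sets must be non-empty")
    if set_a & set_b:
        raise ValueError(f"drug sets overlap: {sorted(set_a & set_b)}")
    roles = options.roles_counted if options is not None else DEFAULT_ROLES
    cells = {(a, b, e): 0 for a in (0, 1) for b in (0, 1) for e in (0, 1)}
    for r in reports:
        a = int(r.has_drug(set_a, roles))
        b = int(r.has_drug(set_b, roles))
        e = int(r.has_event(event_terms))
        cells[(a, b, e)] += 1
    return TripleTable(
        n111=cells[(1, 1, 1)], n110=cells[(1, 1, 0)],
        n101=cells[(1, 0, 1)], n100=cells[(1, 0, 0)],
        n011=cells[(0, 1, 1)], n010=cells[(0, 1, 0)],
        n001=cells[(0, 0, 1)], n000=cells[(0, 0, 0)],
    )
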