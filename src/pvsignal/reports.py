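"""Report-level data model, readers/writers, deduplication, and filtering.

The counting unit throughout the package is the individual case safety
report (ICSR): one spontaneous adverse-event report carrying a list of drug
mentions (with role codes and indications), a list of event preferred terms,
demographics, reporter type, and outcome flags.  Collections of
:class:`ReportRecord` are plain lists; all downstream statistics count each
deduplicated report exactly once per contingency cell.

Two on-disk dialects are supported:

``simple_tabular``
    Three UTF-8 delimited tables in one directory — ``reports.csv``,
    ``drugs.csv``, ``events.csv`` — with ISO-8601 dates and empty string for
    missing.  This is the package's native interchange format and round-trips
    losslessly.

``faers_ascii``
    The ``$``-delimited quarterly extract layout (DEMO/DRUG/REAC/INDI/OUTC
    files keyed by primaryid/caseid); only the columns mapping onto the data
    model are read.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .termsets import TermSet, normalize_term

__all__ = [
    "Role",
    "ReporterType",
    "Sex",
    "Outcome",
    "DrugMention",
    "EventMention",
    "ReportRecord",
    "FilterCriteria",
    "load_reports",
    "write_reports",
    "deduplicate",
    "filter_reports",
    "summarize_cases",
]


class Role(str, enum.Enum):
    """Drug role code on a report.

    ``interacting`` is accepted on input but treated as ``concomitant``
    everywhere downstream (it is vanishingly rare and carries no separate
    meaning in the case/non-case design used here).
    """

    primary_suspect = "PS"
    secondary_suspect = "SS"
    concomitant = "C"
    interacting = "I"


class ReporterType(str, enum.Enum):
    healthcare_professional = "healthcare_professional"
    consumer = "consumer"
    unspecified = "unspecified"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    missing = "missing"


class Outcome(str, enum.Enum):
    death = "death"
    life_threatening = "life_threatening"
    hospitalization = "hospitalization"
    disability = "disability"
    congenital_anomaly = "congenital_anomaly"
    other_serious = "other_serious"


#: Age bands used for subgroup strata and descriptive summaries.
AGE_BANDS = ("0-24", "25-65", ">65")

#: Calendar-year buckets used in descriptive summaries.
YEAR_BUCKETS = ("2004-2008", "2009-2013", "2014-2018", "2019-2022")


def normalize_drug_name(name: str) -> str:
    """Case-fold, trim, collapse internal whitespace.

    No ingredient dictionary is applied; pass a ``name_map`` to
    :func:`load_reports` to fold brand names onto active substances.
    """
    return " ".join(name.split()).casefold()


def age_band(age_years: float | None) -> str | None:
    """Band an age in years; None stays None (missing)."""
    if age_years is None:
        return None
    if age_years < 25:
        return "0-24"
    if age_years <= 65:
        return "25-65"
    return ">65"


def year_bucket(year: int) -> str:
    """Five/four-year reporting-period bucket; years outside 2004-2022 get
    their own label so nothing is silently dropped."""
    for bucket in YEAR_BUCKETS:
        lo, hi = bucket.split("-")
        if int(lo) <= year <= int(hi):
            return bucket
    return "other"


def _parse_quarter(text: str) -> str:
    """Validate and canonicalize a year-quarter token like ``2020Q3``.

    The canonical form sorts lexicographically in chronological order, so
    plain string comparison is used for quarter windows.
    """
    token = text.strip().upper().replace("-", "")
    if len(token) != 6 or token[4] != "Q" or not token[:4].isdigit() or token[5] not in "1234":
        raise ValueError(f"bad receipt_quarter {text!r}; expected e.g. 2020Q3")
    return token


def quarter_year(quarter: str) -> int:
    return int(quarter[:4])


@dataclass(frozen=True)
class DrugMention:
    """One drug listed on a report, with its role and per-drug indication."""

    name: str
    role: Role = Role.concomitant
    indication: str | None = None
    start_date: dt.date | None = None

    def __post_init__(self) -> None:
        norm = normalize_drug_name(self.name)
        if not norm:
            raise ValueError("drug name empty after normalization")
        object.__setattr__(self, "name", norm)
        if self.indication is not None:
            object.__setattr__(self, "indication", normalize_term(self.indication) or None)

    @property
    def effective_role(self) -> Role:
        """Role with ``interacting`` folded into ``concomitant``."""
        return Role.concomitant if self.role is Role.interacting else self.role


@dataclass(frozen=True)
class EventMention:
    """One adverse-event preferred term on a report."""

    pt: str
    onset_date: dt.date | None = None

    def __post_init__(self) -> None:
        norm = normalize_term(self.pt)
        if not norm:
            raise ValueError("event PT empty after normalization")
        object.__setattr__(self, "pt", norm)


@dataclass(frozen=True)
class ReportRecord:
    """One ICSR version.  ``report_id`` identifies the case; several versions
    of the same case may coexist before :func:`deduplicate`."""

    report_id: str
    version_date: dt.date
    receipt_quarter: str
    reporter_type: ReporterType = ReporterType.unspecified
    sex: Sex = Sex.missing
    age_years: float | None = None
    drugs: tuple[DrugMention, ...] = ()
    events: tuple[EventMention, ...] = ()
    outcomes: frozenset[Outcome] = frozenset()
    version_id: str = ""

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        object.__setattr__(self, "receipt_quarter", _parse_quarter(self.receipt_quarter))
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "outcomes", frozenset(self.outcomes))
        if self.age_years is not None:
            a = float(self.age_years)
            if not (0 <= a < 130):
                raise ValueError(f"report {self.report_id}: age_years {a} out of range")
            object.__setattr__(self, "age_years", a)

    @property
    def drug_names(self) -> frozenset[str]:
        try:
            return self._drug_names
        except AttributeError:
            names = frozenset(d.name for d in self.drugs)
            object.__setattr__(self, "_drug_names", names)  # lazy cache
            return names

    @property
    def event_pts(self) -> frozenset[str]:
        try:
            return self._event_pts
        except AttributeError:
            pts = frozenset(e.pt for e in self.events)
            object.__setattr__(self, "_event_pts", pts)
            return pts

    def has_drug(self, names: Iterable[str], roles: Iterable[Role] | None = None) -> bool:
        """True if any of ``names`` appears with one of ``roles`` (any role if
        None); role comparison folds ``interacting`` into ``concomitant``."""
        wanted = {normalize_drug_name(n) for n in names}
        if roles is None:
            return not wanted.isdisjoint(self.drug_names)
        allowed = {Role.concomitant if r is Role.interacting else r for r in roles}
        return any(d.name in wanted and d.effective_role in allowed for d in self.drugs)

    def has_event(self, terms: TermSet) -> bool:
        return not terms.terms.isdisjoint(self.event_pts)

    def has_indication(self, terms: TermSet) -> bool:
        """True if ANY drug mention carries an indication in ``terms``."""
        return any(d.indication is not None and d.indication in terms.terms for d in self.drugs)


@dataclass(frozen=True)
class FilterCriteria:
    """Conjunctive report filter.  A report survives iff it matches every
    criterion that is set; unset criteria are ignored.

    ``indication_terms``     keep reports where any drug mention's indication matches.
    ``required_roles``       keep reports where any drug carries an allowed role.
    ``reporter_types``       keep reports from the listed reporter types.
    ``exclude_event_terms``  drop reports carrying ANY listed event PT.
    ``exclude_drugs``        drop reports carrying ANY listed drug (any role).
    ``quarter_window``       inclusive (start, end) receipt-quarter window.
    """

    indication_terms: TermSet | None = None
    required_roles: frozenset[Role] | None = None
    reporter_types: frozenset[ReporterType] | None = None
    exclude_event_terms: TermSet | None = None
    exclude_drugs: frozenset[str] | None = None
    quarter_window: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.required_roles is not None:
            object.__setattr__(self, "required_roles", frozenset(self.required_roles))
        if self.reporter_types is not None:
            object.__setattr__(self, "reporter_types", frozenset(self.reporter_types))
        if self.exclude_drugs is not None:
            norm = frozenset(normalize_drug_name(d) for d in self.exclude_drugs)
            if not norm:
                raise ValueError("exclude_drugs set but empty")
            object.__setattr__(self, "exclude_drugs", norm)
        if self.quarter_window is not None:
            lo, hi = self.quarter_window
            object.__setattr__(self, "quarter_window", (_parse_quarter(lo), _parse_quarter(hi)))

    def is_empty(self) -> bool:
        return all(
            getattr(self, f) is None
            for f in (
                "indication_terms",
                "required_roles",
                "reporter_types",
                "exclude_event_terms",
                "exclude_drugs",
                "quarter_window",
            )
        )

    def matches(self, report: ReportRecord) -> bool:
        if self.indication_terms is not None and not report.has_indication(self.indication_terms):
            return False
        if self.required_roles is not None:
            allowed = {Role.concomitant if r is Role.interacting else r for r in self.required_roles}
            if not any(d.effective_role in allowed for d in report.drugs):
                return False
        if self.reporter_types is not None and report.reporter_type not in self.reporter_types:
            return False
        if self.exclude_event_terms is not None and report.has_event(self.exclude_event_terms):
            return False
        if self.exclude_drugs is not None and not self.exclude_drugs.isdisjoint(report.drug_names):
            return False
        if self.quarter_window is not None:
            lo, hi = self.quarter_window
            if not (lo <= report.receipt_quarter <= hi):
                return False
        return True


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_ROLE_CODES = {"PS": Role.primary_suspect, "SS": Role.secondary_suspect,
               "C": Role.concomitant, "I": Role.interacting}


def _parse_role(code: str, where: str) -> Role:
    code = code.strip().upper()
    if code in _ROLE_CODES:
        return _ROLE_CODES[code]
    warnings.warn(f"{where}: unknown role code {code!r}, mapped to concomitant")
    return Role.concomitant


def _parse_date(text: str, where: str) -> dt.date | None:
    text = text.strip()
    if not text:
        return None
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise ValueError(f"{where}: bad date {text!r}") from exc


def load_reports(path: str | Path, dialect: str = "simple_tabular",
                 name_map: dict[str, str] | None = None) -> list[ReportRecord]:
    """Read a report collection.  ``path`` is the directory holding the
    dialect's files.  No deduplication is performed; one record per raw case
    version.  ``name_map`` optionally folds drug synonyms (normalized keys)
    onto canonical names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "simple_tabular":
        return _load_simple_tabular(path, name_map)
    if dialect == "faers_ascii":
        return _load_faers_ascii(path, name_map)
    raise ValueError(f"unknown dialect {dialect!r}")


def _apply_name_map(name: str, name_map: dict[str, str] | None) -> str:
    norm = normalize_drug_name(name)
    if name_map:
        return name_map.get(norm, norm)
    return norm


def _read_rows(path: Path, required: Sequence[str], delimiter: str = ",") -> list[dict[str, str]]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header expected")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        rows = []
        for i, row in enumerate(reader, start=2):
            if any(v is None for v in row.values()) or None in row:
                raise ValueError(f"{path}:{i}: malformed row (field count mismatch)")
            rows.append(row)
        return rows


def _load_simple_tabular(path: Path, name_map: dict[str, str] | None) -> list[ReportRecord]:
    rep_rows = _read_rows(path / "reports.csv",
                          ["report_id", "version_date", "receipt_quarter", "reporter_type",
                           "sex", "age_years", "outcomes"])
    drug_rows = _read_rows(path / "drugs.csv",
                           ["report_id", "name", "role", "indication", "start_date"])
    event_rows = _read_rows(path / "events.csv", ["report_id", "pt", "onset_date"])

    drugs: dict[str, list[DrugMention]] = {}
    for i, row in enumerate(drug_rows, start=2):
        where = f"{path / 'drugs.csv'}:{i}"
        drugs.setdefault(_row_key(row), []).append(
            DrugMention(
                name=_apply_name_map(row["name"], name_map),
                role=_parse_role(row["role"], where),
                indication=row["indication"] or None,
                start_date=_parse_date(row["start_date"], where),
            )
        )
    events: dict[str, list[EventMention]] = {}
    for i, row in enumerate(event_rows, start=2):
        where = f"{path / 'events.csv'}:{i}"
        events.setdefault(_row_key(row), []).append(
            EventMention(pt=row["pt"], onset_date=_parse_date(row["onset_date"], where))
        )

    out: list[ReportRecord] = []
    for i, row in enumerate(rep_rows, start=2):
        where = f"{path / 'reports.csv'}:{i}"
        rid = row["report_id"].strip()
        if not rid:
            raise ValueError(f"{where}: empty report_id")
        vdate = _parse_date(row["version_date"], where)
        if vdate is None:
            raise ValueError(f"{where}: version_date is required")
        try:
            reporter = ReporterType(row["reporter_type"].strip() or "unspecified")
        except ValueError as exc:
            raise ValueError(f"{where}: bad reporter_type {row['reporter_type']!r}") from exc
        try:
            sex = Sex(row["sex"].strip() or "missing")
        except ValueError as exc:
            raise ValueError(f"{where}: bad sex {row['sex']!r}") from exc
        age = float(row["age_years"]) if row["age_years"].strip() else None
        tokens = [t for t in row["outcomes"].split("|") if t.strip()]
        try:
            outcomes = frozenset(Outcome(t.strip()) for t in tokens)
        except ValueError as exc:
            raise ValueError(f"{where}: bad outcome token in {row['outcomes']!r}") from exc
        key = _row_key(row)
        out.append(
            ReportRecord(
                report_id=rid,
                version_date=vdate,
                receipt_quarter=row["receipt_quarter"],
                reporter_type=reporter,
                sex=sex,
                age_years=age,
                drugs=tuple(drugs.get(key, ())),
                events=tuple(events.get(key, ())),
                outcomes=outcomes,
                version_id=row.get("version_id", "") or "",
            )
        )
    return out


def _row_key(row: dict[str, str]) -> str:
    """Link key between the three tables: report_id plus optional version_id."""
    return row["report_id"].strip() + "\x00" + (row.get("version_id") or "").strip()


def write_reports(reports: Iterable[ReportRecord], path: str | Path) -> None:
    """Write a collection in the simple_tabular dialect (lossless round-trip)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    def fmt_date(d: dt.date | None) -> str:
        return d.isoformat() if d is not None else ""

    with open(path / "reports.csv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["report_id", "version_id", "version_date", "receipt_quarter",
                    "reporter_type", "sex", "age_years", "outcomes"])
        for r in reports:
            w.writerow([
                r.report_id, r.version_id, r.version_date.isoformat(), r.receipt_quarter,
                r.reporter_type.value, r.sex.value,
                "" if r.age_years is None else f"{r.age_years:g}",
                "|".join(sorted(o.value for o in r.outcomes)),
            ])
    with open(path / "drugs.csv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["report_id", "version_id", "name", "role", "indication", "start_date"])
        for r in reports:
            for d in r.drugs:
                w.writerow([r.report_id, r.version_id, d.name, d.role.value,
                            d.indication or "", fmt_date(d.start_date)])
    with open(path / "events.csv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["report_id", "version_id", "pt", "onset_date"])
        for r in reports:
            for e in r.events:
                w.writerow([r.report_id, r.version_id, e.pt, fmt_date(e.onset_date)])


# FAERS quarterly ASCII column subsets actually read.
_FAERS_ROLE = {"PS": Role.primary_suspect, "SS": Role.secondary_suspect,
               "C": Role.concomitant, "I": Role.interacting}
_FAERS_OUTC = {"DE": Outcome.death, "LT": Outcome.life_threatening,
               "HO": Outcome.hospitalization, "DS": Outcome.disability,
               "CA": Outcome.congenital_anomaly, "OT": Outcome.other_serious,
               "RI": Outcome.other_serious}


def _faers_file(path: Path, stem: str) -> Path | None:
    hits = sorted(path.glob(f"{stem}*.txt")) + sorted(path.glob(f"{stem}*.TXT"))
    return hits[0] if hits else None


def _load_faers_ascii(path: Path, name_map: dict[str, str] | None) -> list[ReportRecord]:
    demo_path = _faers_file(path, "DEMO") or _faers_file(path, "demo")
    if demo_path is None:
        raise FileNotFoundError(f"no DEMO*.txt under {path}")

    def read(stem: str) -> pd.DataFrame | None:
        p = _faers_file(path, stem) or _faers_file(path, stem.lower())
        if p is None:
            return None
        return pd.read_csv(p, sep="$", dtype=str, keep_default_na=False, engine="python")

    demo = read("DEMO")
    drug = read("DRUG")
    reac = read("REAC")
    indi = read("INDI")
    outc = read("OUTC")
    for name, df in (("DEMO", demo), ("DRUG", drug), ("REAC", reac)):
        if df is None:
            raise FileNotFoundError(f"no {name}*.txt under {path}")
    demo.columns = [c.lower() for c in demo.columns]
    drug.columns = [c.lower() for c in drug.columns]
    reac.columns = [c.lower() for c in reac.columns]

    indications: dict[tuple[str, str], str] = {}
    if indi is not None:
        indi.columns = [c.lower() for c in indi.columns]
        seq_col = "indi_drug_seq" if "indi_drug_seq" in indi.columns else "drug_seq"
        for _, row in indi.iterrows():
            term = row.get("indi_pt", "").strip()
            if term:
                indications[(row["primaryid"], row.get(seq_col, ""))] = term

    outcomes: dict[str, set[Outcome]] = {}
    if outc is not None:
        outc.columns = [c.lower() for c in outc.columns]
        for _, row in outc.iterrows():
            code = row.get("outc_cod", "").strip().upper()
            if code in _FAERS_OUTC:
                outcomes.setdefault(row["primaryid"], set()).add(_FAERS_OUTC[code])

    drug_map: dict[str, list[DrugMention]] = {}
    seq_col = "drug_seq" if "drug_seq" in drug.columns else None
    for i, row in drug.iterrows():
        name = row.get("drugname", "").strip()
        if not name:
            continue
        pid = row["primaryid"]
        role = _parse_role(row.get("role_cod", ""), f"DRUG row {i + 2}")
        seq = row.get(seq_col, "") if seq_col else ""
        drug_map.setdefault(pid, []).append(
            DrugMention(name=_apply_name_map(name, name_map), role=role,
                        indication=indications.get((pid, seq)))
        )

    event_map: dict[str, list[EventMention]] = {}
    for _, row in reac.iterrows():
        pt = row.get("pt", "").strip()
        if pt:
            event_map.setdefault(row["primaryid"], []).append(EventMention(pt=pt))

    out: list[ReportRecord] = []
    for i, row in demo.iterrows():
        pid = row["primaryid"]
        caseid = row.get("caseid", "") or pid
        fda_dt = row.get("fda_dt", "").strip()
        if len(fda_dt) == 8 and fda_dt.isdigit():
            vdate = dt.date(int(fda_dt[:4]), int(fda_dt[4:6]), int(fda_dt[6:8]))
        else:
            raise ValueError(f"{demo_path}:{i + 2}: bad fda_dt {fda_dt!r}")
        quarter = f"{vdate.year}Q{(vdate.month - 1) // 3 + 1}"
        occp = row.get("occp_cod", "").strip().upper()
        reporter = {"MD": ReporterType.healthcare_professional,
                    "PH": ReporterType.healthcare_professional,
                    "HP": ReporterType.healthcare_professional,
                    "OT": ReporterType.unspecified,
                    "CN": ReporterType.consumer,
                    "LW": ReporterType.consumer}.get(occp, ReporterType.unspecified)
        sex_code = row.get("sex", row.get("gndr_cod", "")).strip().upper()
        sex = {"M": Sex.male, "F": Sex.female}.get(sex_code, Sex.missing)
        age: float | None = None
        age_txt = row.get("age", "").strip()
        if age_txt:
            try:
                age_val = float(age_txt)
                unit = row.get("age_cod", "YR").strip().upper() or "YR"
                factor = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.18,
                          "DY": 1 / 365.25, "HR": 1 / 8766.0}.get(unit)
                if factor is not None:
                    age = age_val * factor
                    if not (0 <= age < 130):
                        age = None
            except ValueError:
                age = None
        out.append(
            ReportRecord(
                report_id=caseid,
                version_id=pid,
                version_date=vdate,
                receipt_quarter=quarter,
                reporter_type=reporter,
                sex=sex,
                age_years=age,
                drugs=tuple(drug_map.get(pid, ())),
                events=tuple(event_map.get(pid, ())),
                outcomes=frozenset(outcomes.get(pid, set())),
            )
        )
    return out


# ---------------------------------------------------------------------------
# deduplication & filtering
# ---------------------------------------------------------------------------

def deduplicate(reports: Iterable[ReportRecord]) -> list[ReportRecord]:
    """One analyzable record per case: keep the version with the latest
    ``version_date`` (ties broken by lexicographically greatest
    ``version_id``).  Output is sorted by ``report_id`` so repeated runs are
    deterministic regardless of input order."""
    best: dict[str, ReportRecord] = {}
    for r in reports:
        cur = best.get(r.report_id)
        if cur is None or (r.version_date, r.version_id) > (cur.version_date, cur.version_id):
            best[r.report_id] = r
    return [best[k] for k in sorted(best)]


def filter_reports(reports: Iterable[ReportRecord], criteria: FilterCriteria) -> list[ReportRecord]:
    """Keep reports matching every set criterion (conjunction; order-free)."""
    for name in ("indication_terms", "exclude_event_terms"):
        ts = getattr(criteria, name)
        if ts is not None and len(ts.terms) == 0:  # unreachable via TermSet, guard anyway
            raise ValueError(f"{name} is set but empty")
    return [r for r in reports if criteria.matches(r)]


# ---------------------------------------------------------------------------
# descriptive case summary
# ---------------------------------------------------------------------------

def summarize_cases(reports: Sequence[ReportRecord], drug: str, event_terms: TermSet,
                    top_k: int = 10) -> pd.DataFrame:
    """Descriptive table for the cases of one drug-event pair.

    A case is a (deduplicated) report listing ``drug`` in any role AND any PT
    in ``event_terms``.  Returns a long-format frame with columns
    (section, category, count, percent).  Percentages use the number of cases
    as the denominator throughout; the role section can exceed 100% because a
    report may list the drug under several roles, and the co-reported-event
    section counts reports, not mentions.
    """
    name = normalize_drug_name(drug)
    cases = [r for r in reports if name in r.drug_names and r.has_event(event_terms)]
    n = len(cases)
    rows: list[tuple[str, str, int, float]] = []

    def emit(section: str, counts: dict[str, int], order: Sequence[str]) -> None:
        for cat in order:
            c = counts.get(cat, 0)
            rows.append((section, cat, c, 100.0 * c / n if n else 0.0))

    if n:
        yb: dict[str, int] = {}
        rep: dict[str, int] = {}
        role_counts: dict[str, int] = {}
        sex_counts: dict[str, int] = {}
        age_counts: dict[str, int] = {}
        out_counts: dict[str, int] = {}
        co_events: dict[str, int] = {}
        for r in cases:
            yb[year_bucket(quarter_year(r.receipt_quarter))] = yb.get(
                year_bucket(quarter_year(r.receipt_quarter)), 0) + 1
            rep[r.reporter_type.value] = rep.get(r.reporter_type.value, 0) + 1
            # a report may list the drug under several roles; count each once
            roles_here = {d.effective_role for d in r.drugs if d.name == name}
            for role in roles_here:
                role_counts[role.value] = role_counts.get(role.value, 0) + 1
            sex_counts[r.sex.value] = sex_counts.get(r.sex.value, 0) + 1
            band = age_band(r.age_years) or "missing"
            age_counts[band] = age_counts.get(band, 0) + 1
            for o in r.outcomes:
                out_counts[o.value] = out_counts.get(o.value, 0) + 1
            for pt in r.event_pts - event_terms.terms:
                co_events[pt] = co_events.get(pt, 0) + 1

        emit("report_year", yb, [*YEAR_BUCKETS, "other"] if "other" in yb else YEAR_BUCKETS)
        emit("reporter", rep, [t.value for t in ReporterType])
        emit("role", role_counts, [Role.primary_suspect.value, Role.secondary_suspect.value,
                                   Role.concomitant.value])
        emit("sex", sex_counts, [s.value for s in Sex])
        emit("age_band", age_counts, [*AGE_BANDS, "missing"])
        emit("outcome", out_counts, [o.value for o in Outcome])
        top = sorted(co_events.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        for pt, c in top:
            rows.append(("co_reported_event", pt, c, 100.0 * c / n))

    df = pd.DataFrame(rows, columns=["section", "category", "count", "percent"])
    df.attrs["n_cases"] = n
    df.attrs["drug"] = name
    df.attrs["event_set"] = event_terms.name
    return df
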