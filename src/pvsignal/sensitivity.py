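"""Robustness machinery: sensitivity arms with consistency grading,
time-trend IC series, and time-to-onset summaries.

Three sensitivity arms probe a drug-event signal for confounding:

``competition_bias``
    drop reports co-medicated with any drug known to cause the event
    (in any role — the conservative reading), countering masking by
    co-reported causal drugs;
``pre_existing``
    drop reports carrying any event PT that records a pre-existing disease
    which is an alternative cause;
``suspect_hcp``
    restrict to reports from healthcare professionals AND count only
    primary/secondary-suspect roles as exposure (one combined arm).

The consistency grade is a pure function of how many arms still signal
(IC_025 > 0; an arm with zero observed cases contributes no signal):
3/3 Strong, 2/3 Intermediate, 1/3 Weak, 0/3 No signal.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contingency import ContingencyTable, ExposureOptions, build_2x2
from .reports import FilterCriteria, ReportRecord, ReporterType, Role, filter_reports
from .stats import DisproResult, dispro
from .termsets import TermSet

__all__ = [
    "Arm",
    "ArmResult",
    "SensitivityResult",
    "TrendSeries",
    "grade_from_ic025",
    "run_sensitivity",
    "time_trend",
    "year_windows",
    "time_to_onset",
]


class Arm(str, enum.Enum):
    competition_bias = "competition_bias"
    suspect_hcp = "suspect_hcp"
    pre_existing = "pre_existing"


GRADE_LABELS = {3: "Strong (3/3)", 2: "Intermediate (2/3)",
                1: "Weak (1/3)", 0: "No signal (0/3)"}


def grade_from_ic025(arm_values: Sequence[tuple[int, float | None]]) -> tuple[int, str]:
    """(n_signals, grade label) from per-arm (n, IC_025) pairs.

    An arm counts as signalling iff its observed count is positive and its
    IC_025 exceeds zero; an arm with n = 0 has no computable IC_025 and may
    pass ``None``.
    """
    if len(arm_values) != 3:
        raise ValueError("exactly three sensitivity arms expected")
    n_signals = sum(
        1 for n, lo in arm_values
        if n > 0 and lo is not None and not math.isnan(lo) and lo > 0.0
    )
    return n_signals, GRADE_LABELS[n_signals]


@dataclass(frozen=True)
class ArmResult:
    """One sensitivity arm: the restricted analysis and its surviving counts."""

    arm: Arm
    result: DisproResult
    exposed_total: int
    table: ContingencyTable

    @property
    def signals(self) -> bool:
        return self.result.n > 0 and self.result.ic_025 > 0.0


@dataclass(frozen=True)
class SensitivityResult:
    arms: Mapping[Arm, ArmResult]
    n_signals: int
    grade: str

    def to_row(self) -> dict:
        """Flat dict shaped like one row of a published sensitivity table:
        per-arm "n/exposed" counts and IC_025, plus the grade."""
        row: dict = {}
        for arm, res in self.arms.items():
            row[f"{arm.value}_n"] = res.result.n
            row[f"{arm.value}_exposed"] = res.exposed_total
            row[f"{arm.value}_ic_025"] = res.result.ic_025 if res.result.n > 0 else math.nan
        row["n_signals"] = self.n_signals
        row["grade"] = self.grade
        return row


def run_sensitivity(reports: Sequence[ReportRecord], options: ExposureOptions,
                    event_terms: TermSet, pre_existing: TermSet,
                    co_drugs: Iterable[str]) -> SensitivityResult:
    """Run the three sensitivity arms for one exposure definition.

    ``options`` is the primary-analysis exposure; each arm restricts the
    report collection and/or the counted roles, then rebuilds the 2x2 table
    and both statistics.  Arms are independent of one another.
    """
    co_drugs = frozenset(co_drugs)
    if not co_drugs:
        raise ValueError("co_drugs list must be non-empty")

    def run_arm(arm: Arm) -> ArmResult:
        arm_reports: Sequence[ReportRecord] = reports
        arm_options = options
        if arm is Arm.competition_bias:
            arm_reports = filter_reports(reports, FilterCriteria(exclude_drugs=co_drugs))
        elif arm is Arm.pre_existing:
            # curated pre-existing-disease lists routinely contain the index
            # event itself (prior disease as history); excluding it as an
            # event PT would empty the case series, so index terms are
            # dropped from the exclusion set
            effective = pre_existing.terms - event_terms.terms
            if not effective:
                raise ValueError(
                    "pre-existing exclusion list contains only the index event terms")
            arm_reports = filter_reports(
                reports,
                FilterCriteria(exclude_event_terms=TermSet(pre_existing.name, effective)),
            )
        else:  # suspect_hcp: HCP reporters AND suspect-only exposure roles
            arm_reports = filter_reports(
                reports,
                FilterCriteria(reporter_types=frozenset({ReporterType.healthcare_professional})),
            )
            arm_options = replace(
                options,
                roles_counted=frozenset({Role.primary_suspect, Role.secondary_suspect}),
            )
        table = build_2x2(arm_reports, event_terms, arm_options)
        return ArmResult(arm=arm, result=dispro(table),
                         exposed_total=table.drug_total, table=table)

    arms = {arm: run_arm(arm) for arm in Arm}
    n_signals, grade = grade_from_ic025(
        [(a.result.n, a.result.ic_025) for a in arms.values()])
    return SensitivityResult(arms=arms, n_signals=n_signals, grade=grade)


@dataclass(frozen=True)
class TrendSeries:
    """Ordered per-window IC series; ``cumulative`` says whether each window
    accumulates all reports received up to its end."""

    windows: tuple[tuple[str, str], ...]
    n: tuple[int, ...]
    ic: tuple[float, ...]
    ic_025: tuple[float, ...]
    ic_975: tuple[float, ...]
    cumulative: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_start": [w[0] for w in self.windows],
            "window_end": [w[1] for w in self.windows],
            "n": self.n, "ic": self.ic,
            "ic_025": self.ic_025, "ic_975": self.ic_975,
        })


def year_windows(first_year: int, last_year: int) -> list[tuple[str, str]]:
    """Calendar-year windows at quarterly granularity, the default trend grid."""
    return [(f"{y}Q1", f"{y}Q4") for y in range(first_year, last_year + 1)]


def time_trend(reports: Sequence[ReportRecord], options: ExposureOptions,
               event_terms: TermSet, windows: Sequence[tuple[str, str]],
               cumulative: bool = True) -> TrendSeries:
    """IC over time.

    ``windows`` are inclusive (start, end) quarter bounds with strictly
    increasing ends.  Cumulative mode analyzes all reports received up to
    each window end (the conventional signal-stability view); non-cumulative
    mode analyzes each window in isolation.
    """
    if not windows:
        raise ValueError("at least one window required")
    ends = [w[1] for w in windows]
    if any(b <= a for a, b in zip(ends, ends[1:])):
        raise ValueError("window ends must be strictly increasing")

    from .stats import ic as ic_stat

    ns, ics, los, his = [], [], [], []
    for start, end in windows:
        if cumulative:
            sub = [r for r in reports if r.receipt_quarter <= end]
        else:
            sub = [r for r in reports if start <= r.receipt_quarter <= end]
        table = build_2x2(sub, event_terms, options)
        if table.total == 0:
            ns.append(0)
            ics.append(math.nan), los.append(math.nan), his.append(math.nan)
            continue
        center, lo, hi, _ = ic_stat(table)
        ns.append(table.n11)
        ics.append(center), los.append(lo), his.append(hi)
    return TrendSeries(windows=tuple(tuple(w) for w in windows),
                       n=tuple(ns), ic=tuple(ics),
                       ic_025=tuple(los), ic_975=tuple(his),
                       cumulative=cumulative)


@dataclass(frozen=True)
class TimeToOnsetSummary:
    """Days from drug start to event onset among matched cases.

    ``median``/``q1``/``q3`` summarize the non-negative onsets only;
    reports where the event precedes the drug are tallied separately in
    ``n_negative`` (in spontaneous reports they usually flag an event that
    cannot be drug-induced, e.g., a pre-existing condition).
    """

    n_cases: int
    n_computable: int
    n_negative: int
    median: float
    q1: float
    q3: float


def time_to_onset(reports: Sequence[ReportRecord], drug_names: Iterable[str],
                  event_terms: TermSet) -> TimeToOnsetSummary:
    """Summarize time to onset for cases of one drug set and event set.

    Per case the earliest start date among matching drug mentions and the
    earliest onset among matching events are used; cases missing either
    date are not computable.
    """
    names = frozenset(d.casefold().strip() for d in drug_names)
    deltas: list[int] = []
    n_cases = 0
    for r in reports:
        if names.isdisjoint(r.drug_names) or not r.has_event(event_terms):
            continue
        n_cases += 1
        starts = [d.start_date for d in r.drugs
                  if d.name in names and d.start_date is not None]
        onsets = [e.onset_date for e in r.events
                  if e.pt in event_terms.terms and e.onset_date is not None]
        if not starts or not onsets:
            continue
        deltas.append((min(onsets) - min(starts)).days)

    positives = sorted(d for d in deltas if d >= 0)
    n_negative = len(deltas) - len(positives)

    def quantile(q: float) -> float:
        if not positives:
            return math.nan
        idx = q * (len(positives) - 1)
        lo = math.floor(idx)
        hi = math.ceil(idx)
        frac = idx - lo
        return positives[lo] * (1 - frac) + positives[hi] * frac

    return TimeToOnsetSummary(
        n_cases=n_cases,
        n_computable=len(deltas),
        n_negative=n_negative,
        median=quantile(0.5),
        q1=quantile(0.25),
        q3=quantile(0.75),
    )
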