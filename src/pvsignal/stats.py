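"""Disproportionality statistics: ROR with Wald CI, shrinkage IC with
credibility bounds, the multi-PT screen, and the between-stratum IC delta.

Two measures are computed on every 2x2 report-count table:

* the reporting odds ratio ``ROR = (n11 n00) / (n10 n01)`` with the Wald
  95% interval ``exp(ln ROR +/- 1.96 SE)``, ``SE = sqrt(sum 1/n_ij)``; and
* the information component ``IC = log2((n + 0.5) / (E + 0.5))`` with
  ``E = drug_total * event_total / N``, a shrunken observed-to-expected
  log-ratio whose 95% credibility bounds use the standard analytic
  approximations

      IC_025 = IC - 3.3 (n+0.5)^-1/2 - 2 (n+0.5)^-3/2
      IC_975 = IC + 2.4 (n+0.5)^-1/2 + 0.5 (n+0.5)^-3/2.

The +0.5 shrinkage pulls small-count signals toward the null; the interval
width decays with the observed count.  A signal is flagged when ROR_025 > 1
(frequentist) or IC_025 > 0 (Bayesian).  No multiple-testing adjustment is
applied anywhere; a screen over many PTs reports every row with its own
unadjusted interval.

The IC delta contrasts reporting between two disjoint strata of the same
drug-event pair: the index stratum's observed count against the count
expected if the index stratum reported at the reference stratum's rate,
shrunken and bounded with the same constants as the IC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contingency import ContingencyTable, ExposureOptions, build_2x2
from .reports import ReportRecord
from .termsets import TermSet

__all__ = [
    "DisproResult",
    "DeltaResult",
    "ror",
    "ic",
    "dispro",
    "screen",
    "screen_tables",
    "ic_delta",
    "DEFAULT_MIN_COUNT",
]

#: Screens keep rows with n strictly greater than this by default
#: ("more than five" reports).
DEFAULT_MIN_COUNT = 5

_Z = 1.96
# credibility-interval constants of the shrinkage IC approximation
_LO = (3.3, 2.0)
_HI = (2.4, 0.5)


@dataclass(frozen=True)
class DisproResult:
    """Both disproportionality measures for one drug-event pair.

    ``ror``/``ror_025``/``ror_975`` are NaN when any 2x2 cell is zero (no
    continuity correction is applied); the IC is defined for any table with
    a positive grand total.
    """

    n: int
    expected: float
    ror: float
    ror_025: float
    ror_975: float
    ic: float
    ic_025: float
    ic_975: float
    meets_min_count: bool = True

    @property
    def ror_defined(self) -> bool:
        return not math.isnan(self.ror)

    @property
    def signal_ror(self) -> bool:
        return self.ror_defined and self.ror_025 > 1.0

    @property
    def signal_ic(self) -> bool:
        return self.n > 0 and self.ic_025 > 0.0


def ror(table: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with 95% Wald bounds.

    Any zero cell makes the ROR and its interval undefined (NaN); no
    Haldane-Anscombe correction is applied, so printed screen values are
    reproduced exactly on tables with all cells positive.
    """
    cells = (table.n11, table.n10, table.n01, table.n00)
    if any(c == 0 for c in cells):
        return (math.nan, math.nan, math.nan)
    point = (table.n11 * table.n00) / (table.n10 * table.n01)
    se = math.sqrt(sum(1.0 / c for c in cells))
    return (point, point * math.exp(-_Z * se), point * math.exp(_Z * se))


def _ic_bounds(n: float, center: float) -> tuple[float, float]:
    s = n + 0.5
    lo = center - _LO[0] * s ** -0.5 - _LO[1] * s ** -1.5
    hi = center + _HI[0] * s ** -0.5 + _HI[1] * s ** -1.5
    return lo, hi


def ic(table: ContingencyTable) -> tuple[float, float, float, float]:
    """Shrinkage information component: (ic, ic_025, ic_975, expected)."""
    total = table.total
    if total == 0:
        raise ValueError("empty table: IC undefined for N = 0")
    expected = table.drug_total * table.event_total / total
    center = math.log2((table.n11 + 0.5) / (expected + 0.5))
    lo, hi = _ic_bounds(table.n11, center)
    return (center, lo, hi, expected)


def dispro(table: ContingencyTable, min_count: int = DEFAULT_MIN_COUNT) -> DisproResult:
    """Both measures plus signal/min-count flags for one table."""
    r, r_lo, r_hi = ror(table)
    center, lo, hi, expected = ic(table)
    return DisproResult(
        n=table.n11, expected=expected,
        ror=r, ror_025=r_lo, ror_975=r_hi,
        ic=center, ic_025=lo, ic_975=hi,
        meets_min_count=table.n11 > min_count,
    )


def _screen_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(
        rows,
        columns=["event_set", "n", "expected", "ror", "ror_025", "ror_975",
                 "ic", "ic_025", "ic_975", "signal_ror", "signal_ic",
                 "meets_min_count"],
    )
    return df.sort_values(["n", "event_set"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


def screen_tables(tables: Mapping[str, ContingencyTable],
                  min_count: int = DEFAULT_MIN_COUNT) -> pd.DataFrame:
    """Screen over pre-built tables (e.g., published margins): one row per
    named table, sorted by observed count descending."""
    rows = []
    for name, table in tables.items():
        if table.total == 0:
            # empty collection: report a flagged all-zero row, not an error
            rows.append({
                "event_set": name, "n": 0, "expected": 0.0,
                "ror": math.nan, "ror_025": math.nan, "ror_975": math.nan,
                "ic": math.nan, "ic_025": math.nan, "ic_975": math.nan,
                "signal_ror": False, "signal_ic": False,
                "meets_min_count": False,
            })
            continue
        res = dispro(table, min_count=min_count)
        rows.append({
            "event_set": name, "n": res.n, "expected": res.expected,
            "ror": res.ror, "ror_025": res.ror_025, "ror_975": res.ror_975,
            "ic": res.ic, "ic_025": res.ic_025, "ic_975": res.ic_975,
            "signal_ror": res.signal_ror, "signal_ic": res.signal_ic,
            "meets_min_count": res.meets_min_count,
        })
    return _screen_frame(rows)


def screen(reports: Sequence[ReportRecord], options: ExposureOptions,
           event_sets: Iterable[TermSet],
           min_count: int = DEFAULT_MIN_COUNT) -> pd.DataFrame:
    """Disproportionality screen of one exposure against several event sets
    (typically the PTs of an SMQ, one single-PT set each).

    Rows failing the minimum-count rule are reported but flagged, never
    silently dropped.  Output shape is forest-plot ready.
    """
    event_sets = list(event_sets)
    if not event_sets:
        raise ValueError("event_sets must be non-empty")
    tables = {ts.name: build_2x2(reports, ts, options) for ts in event_sets}
    return screen_tables(tables, min_count=min_count)


@dataclass(frozen=True)
class DeltaResult:
    """IC delta between an index and a reference stratum.

    ``expected_index`` scales the reference stratum's event rate to the
    index stratum's exposed total; a significantly positive (negative)
    delta reflects over- (under-) reporting in the index stratum at the
    5% level.
    """

    n_index: int
    expected_index: float
    ic_delta: float
    ic_delta_025: float
    ic_delta_975: float

    @property
    def significant_over(self) -> bool:
        return self.ic_delta_025 > 0.0

    @property
    def significant_under(self) -> bool:
        return self.ic_delta_975 < 0.0


def ic_delta(index_table: ContingencyTable, reference_table: ContingencyTable) -> DeltaResult:
    """Observed-to-expected contrast between two disjoint strata.

    Both tables must come from the same drug/event definitions.  The
    expected index count is ``index drug_total x (reference n11 / reference
    drug_total)``; shrinkage and credibility bounds use the IC constants on
    the index count.
    """
    if reference_table.drug_total == 0:
        raise ValueError("reference stratum has no exposed reports")
    n_index = index_table.n11
    expected = index_table.drug_total * (reference_table.n11 / reference_table.drug_total)
    center = math.log2((n_index + 0.5) / (expected + 0.5))
    lo, hi = _ic_bounds(n_index, center)
    return DeltaResult(n_index=n_index, expected_index=expected,
                       ic_delta=center, ic_delta_025=lo, ic_delta_975=hi)
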