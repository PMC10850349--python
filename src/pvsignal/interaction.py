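"""Shrinkage omega statistic for drug-drug interaction surveillance.

Given the 2x2x2 report-count table over (drug A) x (drug B) x (event), the
observed event proportions in the four exposure cells are

    f_ab = n_ab1 / n_ab.        (a, b in {0, 1}),

and the no-interaction expectation for the co-exposed cell combines the two
single-drug risks additively on the 1/(1 - p) scale:

    1 / (1 - g11) = 1 / (1 - f10) + 1 / (1 - f01) - 1 / (1 - f00).

With E111 = g11 * n11. the statistic is the shrunken log2
observed-to-expected ratio

    omega = log2((n111 + 0.5) / (E111 + 0.5)),

with 95% credibility bounds using the same analytic constants as the
information component, on (n111 + 0.5).  An interaction signal is flagged
when omega_025 > 0.  The harmonic combination makes the expectation at
least as large as each single-drug risk alone, which is what makes this
the conservative choice among interaction screens at small risks.

By default g11 is not floored at max(f10, f01); pass ``floor_g11=True`` to
clamp the expectation from below (a stricter variant some implementations
use).  The model is symmetric in the two drugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .contingency import ExposureOptions, TripleTable, build_triple
from .reports import ReportRecord
from .termsets import TermSet

__all__ = ["OmegaResult", "omega", "omega_batch"]

_LO = (3.3, 2.0)
_HI = (2.4, 0.5)


@dataclass(frozen=True)
class OmegaResult:
    """Omega statistic for one drug pair and event set."""

    n111: int
    f11: float
    f10: float
    f01: float
    f00: float
    g11: float
    expected_n111: float
    omega: float
    omega_025: float
    omega_975: float

    @property
    def signal(self) -> bool:
        return self.omega_025 > 0.0


def omega(triple: TripleTable, floor_g11: bool = False) -> OmegaResult:
    """Compute the shrinkage omega statistic from a 2x2x2 table.

    Raises ``ValueError`` when any exposure cell is empty (its event
    proportion is undefined) or when a proportion equals 1 (the harmonic
    transform diverges).
    """
    totals = {}
    props = {}
    for a in (0, 1):
        for b in (0, 1):
            tot = triple.cell_total(a, b)
            if tot == 0:
                raise ValueError(f"exposure cell n{a}{b}. is empty; omega undefined")
            f = triple.event_count(a, b) / tot
            if f >= 1.0:
                raise ValueError(f"event proportion f{a}{b} = 1; omega undefined")
            totals[(a, b)] = tot
            props[(a, b)] = f

    inv = (1.0 / (1.0 - props[(1, 0)])
           + 1.0 / (1.0 - props[(0, 1)])
           - 1.0 / (1.0 - props[(0, 0)]))
    g11 = 1.0 - 1.0 / inv
    if floor_g11:
        g11 = max(g11, props[(1, 0)], props[(0, 1)])
    if inv <= 0.0 or g11 < 0.0:
        # background risk so far above both single-drug risks that the
        # harmonic expectation is non-positive; the log ratio is undefined
        raise ValueError(
            "no-interaction expectation g11 is non-positive "
            f"(f10={props[(1, 0)]:.4g}, f01={props[(0, 1)]:.4g}, "
            f"f00={props[(0, 0)]:.4g}); consider floor_g11=True")
    expected = g11 * totals[(1, 1)]

    n111 = triple.n111
    center = math.log2((n111 + 0.5) / (expected + 0.5))
    s = n111 + 0.5
    lo = center - _LO[0] * s ** -0.5 - _LO[1] * s ** -1.5
    hi = center + _HI[0] * s ** -0.5 + _HI[1] * s ** -1.5
    return OmegaResult(
        n111=n111,
        f11=props[(1, 1)], f10=props[(1, 0)], f01=props[(0, 1)], f00=props[(0, 0)],
        g11=g11, expected_n111=expected,
        omega=center, omega_025=lo, omega_975=hi,
    )


def omega_batch(reports: Sequence[ReportRecord],
                pairs: Iterable[tuple[str, str]],
                event_terms: TermSet,
                options: ExposureOptions | None = None,
                floor_g11: bool = False) -> pd.DataFrame:
    """Omega for a list of drug pairs against one event set.

    Pairs whose triple table has an empty exposure cell are reported with
    NaN statistics and ``computable = False`` rather than aborting the
    batch.
    """
    rows = []
    for a, b in pairs:
        row: dict = {"drug_a": a, "drug_b": b, "computable": True}
        try:
            triple = build_triple(reports, {a}, {b}, event_terms, options)
            res = omega(triple, floor_g11=floor_g11)
            row.update(
                n111=res.n111, expected_n111=res.expected_n111, g11=res.g11,
                omega=res.omega, omega_025=res.omega_025, omega_975=res.omega_975,
                signal=res.signal,
            )
        except ValueError:
            row.update(
                n111=0, expected_n111=math.nan, g11=math.nan,
                omega=math.nan, omega_025=math.nan, omega_975=math.nan,
                signal=False, computable=False,
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["drug_a", "drug_b", "n111", "expected_n111", "g11",
                 "omega", "omega_025", "omega_975", "signal", "computable"],
    )
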