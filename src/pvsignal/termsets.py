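"""Named sets of MedDRA-style preferred terms (PTs).

A :class:`TermSet` is the unit of event definition throughout the package:
a single PT ("pericarditis"), a standardized MedDRA query (SMQ) transcribed
as a flat PT list, or an exclusion list used by a sensitivity analysis.
Membership is case-insensitive and whitespace-normalized, matching the way
spontaneous-report databases store verbatim-coded terms.

No MedDRA hierarchy is traversed here: SMQs are flat, user-supplied lists.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator


def normalize_term(term: str) -> str:
    """Case-fold, trim, and collapse internal whitespace."""
    return " ".join(term.split()).casefold()


@dataclass(frozen=True)
class TermSet:
    """A named set of preferred terms with case-insensitive membership."""

    name: str
    terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("TermSet name must be non-empty")
        normalized = frozenset(normalize_term(t) for t in self.terms if t.strip())
        if not normalized:
            raise ValueError(f"TermSet {self.name!r} has no terms")
        object.__setattr__(self, "terms", normalized)

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self.terms

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.terms))

    def __len__(self) -> int:
        return len(self.terms)

    def matches_any(self, terms: Iterable[str]) -> bool:
        """True if any of ``terms`` (already normalized or not) is a member."""
        return any(t in self for t in terms)


def load_term_sets(path: str | Path) -> dict[str, TermSet]:
    """Read term sets from a two-column delimited file (set_name, term).

    The delimiter is sniffed from {tab, comma}. Lines starting with ``#``
    and blank lines are skipped. Returns a mapping name -> TermSet.
    """
    path = Path(path)
    groups: dict[str, set[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample else ","
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns (set_name, term)")
            name, term = row[0].strip(), row[1].strip()
            if lineno == 1 and (name, term) == ("set_name", "term"):
                continue
            groups.setdefault(name, set()).add(term)
    return {name: TermSet(name, frozenset(terms)) for name, terms in groups.items()}


def load_term_set(path: str | Path, name: str | None = None) -> TermSet:
    """Read a single term set; ``name`` selects one when the file has several."""
    sets = load_term_sets(path)
    if name is None:
        if len(sets) != 1:
            raise ValueError(
                f"{path} holds {len(sets)} term sets; pass name= to choose one"
            )
        return next(iter(sets.values()))
    if name not in sets:
        raise KeyError(f"term set {name!r} not found in {path}")
    return sets[name]


def _bundled(filename: str) -> Path:
    return Path(str(resources.files("pvsignal").joinpath("data", filename)))


def pericarditis_pt() -> TermSet:
    """The single-PT set for pericarditis, the index event of interest."""
    return load_term_set(_bundled("pericarditis_pt.tsv"))


def noninfectious_myopericarditis_smq() -> TermSet:
    """Flat PT list of the noninfectious myocarditis/pericarditis SMQ (10 PTs)."""
    return load_term_set(_bundled("smq_noninfectious_myopericarditis.tsv"))


def pre_existing_disease_terms() -> TermSet:
    """PTs recording pre-existing diseases that are alternative causes of
    pericarditis; reports carrying any of these are dropped in the
    corresponding sensitivity arm."""
    return load_term_set(_bundled("pre_existing_diseases.tsv"))


def pericarditis_inducing_drugs() -> frozenset[str]:
    """Normalized names of co-treated drugs known to induce pericarditis
    (competition-bias exclusion list)."""
    ts = load_term_set(_bundled("pericarditis_co_drugs.tsv"))
    return ts.terms
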