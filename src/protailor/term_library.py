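"""Data model for the PRO-CTCAE term catalogue.

The PRO-CTCAE item library describes symptomatic adverse events as *terms*
(e.g. ``fatigue``), each carrying up to three *attribute* questions drawn
from five kinds: presence (yes/no), severity, interference with usual or
daily activities, frequency, and amount.  Terms are grouped into organ
system domains, which is the unit of the reliability analysis.

The full library shipped with this package has 80 terms carrying 124
attribute questions in total (78 distinct adverse events; depression and
irregular menstruation each contribute two terms).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AttributeKind",
    "Term",
    "TermLibrary",
    "TermLibraryFormatError",
    "TermLibraryValidationError",
    "UnknownTermError",
    "UnknownDomainError",
    "load_term_library",
    "write_term_library",
    "load_full_library",
    "load_tailored_library",
    "item_count",
    "domain_terms",
]


class AttributeKind(str, enum.Enum):
    """One of the five PRO-CTCAE attribute question kinds.

    ``presence`` is binary (levels 0-1); the other four are 5-level
    ordinal scales (levels 0-4).
    """

    PRESENCE = "presence"
    SEVERITY = "severity"
    INTERFERENCE = "interference"
    FREQUENCY = "frequency"
    AMOUNT = "amount"

    @property
    def max_level(self) -> int:
        return 1 if self is AttributeKind.PRESENCE else 4


#: attribute kinds carrying a 0-4 ordinal scale, in pipeline step order
ORDINAL_KINDS = (
    AttributeKind.SEVERITY,
    AttributeKind.INTERFERENCE,
    AttributeKind.FREQUENCY,
    AttributeKind.AMOUNT,
)


class TermLibraryFormatError(ValueError):
    """Raised when a term-library file does not have the expected layout."""


class TermLibraryValidationError(ValueError):
    """Raised when term-library content violates an invariant."""


class UnknownTermError(KeyError):
    """Raised on lookup of a term_id absent from the library."""


class UnknownDomainError(KeyError):
    """Raised on lookup of a domain absent from the library."""


@dataclass(frozen=True)
class Term:
    """A single symptomatic adverse-event term.

    ``attributes`` is the non-empty set of attribute questions asked for
    this term (at most three).  Presence-only terms carry exactly
    ``{presence}``; presence is never combined with an ordinal attribute.
    """

    term_id: str
    display_name: str
    domain: str
    attributes: frozenset[AttributeKind]

    def __post_init__(self) -> None:
        if not self.term_id:
            raise TermLibraryValidationError("term_id must be non-empty")
        if not self.attributes:
            raise TermLibraryValidationError(
                f"term {self.term_id!r} has an empty attribute set"
            )
        if len(self.attributes) > 3:
            raise TermLibraryValidationError(
                f"term {self.term_id!r} has more than 3 attributes"
            )
        if AttributeKind.PRESENCE in self.attributes and len(self.attributes) > 1:
            raise TermLibraryValidationError(
                f"term {self.term_id!r} combines presence with other attributes"
            )

    @property
    def n_items(self) -> int:
        """Number of survey items (attribute questions) for this term."""
        return len(self.attributes)

    @property
    def presence_only(self) -> bool:
        return self.attributes == frozenset({AttributeKind.PRESENCE})


class TermLibrary:
    """An immutable, keyed collection of :class:`Term`.

    Iteration order is insertion (file) order; domain listings are
    lexicographic for determinism.
    """

    def __init__(self, terms: Iterable[Term]):
        mapping: dict[str, Term] = {}
        for term in terms:
            if term.term_id in mapping:
                raise TermLibraryValidationError(
                    f"duplicate term_id {term.term_id!r}"
                )
            mapping[term.term_id] = term
        if not mapping:
            raise TermLibraryValidationError("term library is empty")
        self._terms: Mapping[str, Term] = dict(mapping)
        domains: dict[str, list[str]] = {}
        for term in self._terms.values():
            domains.setdefault(term.domain, []).append(term.term_id)
        self._domains = {d: tuple(sorted(ts)) for d, ts in sorted(domains.items())}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self):
        return iter(self._terms.values())

    def __contains__(self, term_id: object) -> bool:
        return term_id in self._terms

    def __getitem__(self, term_id: str) -> Term:
        try:
            return self._terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermLibrary):
            return NotImplemented
        return list(self) == list(other)

    # -- views ---------------------------------------------------------------
    @property
    def term_ids(self) -> tuple[str, ...]:
        return tuple(self._terms)

    @property
    def domains(self) -> Mapping[str, tuple[str, ...]]:
        """Domain name -> lexicographically sorted tuple of term_ids."""
        return self._domains

    def domain_of(self, term_id: str) -> str:
        return self[term_id].domain

    def item_count(self, term_ids: Iterable[str] | None = None) -> int:
        """Total number of attribute questions across ``term_ids``.

        With no argument, counts the whole library (124 for the full
        PRO-CTCAE fixture).
        """
        ids = self.term_ids if term_ids is None else tuple(term_ids)
        return sum(self[t].n_items for t in ids)

    def domain_terms(self, domain: str) -> tuple[str, ...]:
        try:
            return self._domains[domain]
        except KeyError:
            raise UnknownDomainError(domain) from None

    def subset(self, term_ids: Iterable[str]) -> "TermLibrary":
        """New library restricted to ``term_ids`` (library order preserved)."""
        keep = set(term_ids)
        missing = keep - set(self._terms)
        if missing:
            raise UnknownTermError(sorted(missing)[0])
        return TermLibrary(t for t in self if t.term_id in keep)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for term in self:
            row = {
                "term_id": term.term_id,
                "display_name": term.display_name,
                "domain": term.domain,
            }
            for kind in AttributeKind:
                row[kind.value] = int(kind in term.attributes)
            rows.append(row)
        return pd.DataFrame(rows)


_REQUIRED_COLUMNS = ("term_id", "display_name", "domain") + tuple(
    k.value for k in AttributeKind
)


def load_term_library(source) -> TermLibrary:
    """Read a term library from a delimited text file.

    Expected header: ``term_id,display_name,domain,presence,severity,
    interference,frequency,amount`` with the five attribute columns as
    0/1 flags.
    """
    try:
        frame = pd.read_csv(source, dtype={"term_id": str, "domain": str})
    except pd.errors.EmptyDataError as exc:
        raise TermLibraryFormatError("term library file is empty") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TermLibraryFormatError(f"missing columns: {missing}")
    unknown = [
        c for c in frame.columns if c not in _REQUIRED_COLUMNS
    ]
    if unknown:
        raise TermLibraryFormatError(f"unknown columns: {unknown}")
    if frame.empty:
        raise TermLibraryValidationError("term library has no rows")
    terms = []
    for row in frame.itertuples(index=False):
        flags = {k: int(getattr(row, k.value)) for k in AttributeKind}
        bad = [k.value for k, v in flags.items() if v not in (0, 1)]
        if bad:
            raise TermLibraryValidationError(
                f"term {row.term_id!r}: attribute flags must be 0/1 ({bad})"
            )
        attributes = frozenset(k for k, v in flags.items() if v)
        terms.append(
            Term(
                term_id=str(row.term_id),
                display_name=str(row.display_name),
                domain=str(row.domain),
                attributes=attributes,
            )
        )
    return TermLibrary(terms)


def write_term_library(library: TermLibrary, path) -> None:
    """Write ``library`` in the same CSV dialect accepted by the loader."""
    library.to_frame().to_csv(path, index=False)


def item_count(term_ids: Iterable[str], library: TermLibrary) -> int:
    """Sum of attribute-question counts over ``term_ids`` (order-free)."""
    return library.item_count(term_ids)


def domain_terms(library: TermLibrary, domain: str) -> tuple[str, ...]:
    """All and only the terms of ``domain``, in lexicographic order."""
    return library.domain_terms(domain)


def _data_path(name: str) -> Path:
    return Path(resources.files("protailor.data") / name)


def load_full_library() -> TermLibrary:
    """The shipped 80-term / 124-item PRO-CTCAE library."""
    return load_term_library(_data_path("proctcae_library.csv"))


def load_tailored_library() -> TermLibrary:
    """The shipped 30-term tailored core survey (58 items, 11 domains)."""
    return load_term_library(_data_path("tailored_library.csv"))
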