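"""Per-term metrics used for survey tailoring.

Two families of scores drive term elimination:

* **Prevalence** — the fraction of administered surveys in which *any*
  attribute of a term was above its null level (for presence-only terms,
  the fraction answering "yes").
* **Attribute proportion scores** — among surveys where the attribute was
  above its null level, the fraction at or above a fixed cut: severity >=
  "moderate", interference >= "somewhat", frequency >= "occasionally",
  amount >= "somewhat" (all level 2 on the 0-4 scale).

The physician panel analogue, the **impact proportion score**, divides by
*all* ratings of a term, not the symptomatic subset.

Scores are stored at full precision; display rounding (one-decimal
percent, round half up) is a separate concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np
import pandas as pd

from .response_data import PooledResponses
from .term_library import AttributeKind, ORDINAL_KINDS, TermLibrary

__all__ = [
    "CUT_LEVEL",
    "HIGH_END_LEVEL",
    "NOT_ASKED",
    "NotAsked",
    "ProportionScore",
    "ScoreTable",
    "prevalence",
    "attribute_proportion_score",
    "high_end_proportion",
    "impact_proportion_score",
    "impact_table",
    "score_table",
    "round_half_up_percent",
]

#: elimination cut level shared by severity / interference / frequency /
#: amount proportion scores (>= moderate / somewhat / occasionally)
CUT_LEVEL = 2

#: level for the complementary "high end" look (>= severe / frequently)
HIGH_END_LEVEL = 3


class NotAsked:
    """Marker: the attribute question does not exist for this term."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_ASKED"


NOT_ASKED = NotAsked()


def round_half_up_percent(value: float, digits: int = 1) -> float:
    """Proportion -> percent rounded half-up to ``digits`` decimals.

    Reproduces panel figures such as 1/9 -> 11.1 and 2/9 -> 22.2.
    """
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProportionScore:
    """A count ratio; undefined when the denominator is zero."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= max(self.denominator, 0):
            raise ValueError(
                f"invalid proportion {self.numerator}/{self.denominator}"
            )

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float | None:
        if not self.defined:
            return None
        return self.numerator / self.denominator

    @property
    def percent(self) -> float | None:
        if not self.defined:
            return None
        return round_half_up_percent(self.value)

    def __repr__(self) -> str:
        shown = "undefined" if not self.defined else f"{self.value:.4f}"
        return f"ProportionScore({self.numerator}/{self.denominator}={shown})"


def _term_frame(pooled: PooledResponses, term_id: str) -> pd.DataFrame:
    if term_id not in pooled.library:
        # delegate the KeyError semantics to the library
        pooled.library[term_id]
    return pooled.term_rows(term_id)


def prevalence(
    pooled: PooledResponses, term_id: str, library: TermLibrary | None = None
) -> ProportionScore:
    """Fraction of administrations with any attribute above its null level.

    Denominator: administrations in which the term's items were presented
    (at least one item answered).  A survey with severity 0 but
    interference 2 counts in the numerator — the definition is a
    disjunction over attributes.
    """
    library = library or pooled.library
    rows = _term_frame(pooled, term_id)
    if rows.empty:
        return ProportionScore(0, 0)
    by_admin = rows.groupby("admin_id")["level"].max()
    return ProportionScore(int((by_admin > 0).sum()), int(len(by_admin)))


def attribute_proportion_score(
    pooled: PooledResponses,
    term_id: str,
    attribute: AttributeKind | str,
    cut_level: int = CUT_LEVEL,
) -> ProportionScore | NotAsked:
    """Among symptomatic responses, the share at/above the cut level.

    Numerator: responses with level >= ``cut_level``; denominator:
    responses with level > 0.  Returns :data:`NOT_ASKED` when the term has
    no such attribute question, and raises on ``presence`` (prevalence is
    the right metric there).
    """
    attribute = AttributeKind(attribute)
    if attribute is AttributeKind.PRESENCE:
        raise ValueError("presence has no proportion score; use prevalence()")
    term = pooled.library[term_id]
    if attribute not in term.attributes:
        return NOT_ASKED
    rows = _term_frame(pooled, term_id)
    levels = rows.loc[rows["attribute"] == attribute.value, "level"]
    denominator = int((levels > 0).sum())
    numerator = int((levels >= cut_level).sum())
    return ProportionScore(numerator, denominator)


def high_end_proportion(
    pooled: PooledResponses,
    term_id: str,
    attribute: AttributeKind | str,
    level: int = HIGH_END_LEVEL,
) -> ProportionScore | NotAsked:
    """Share of symptomatic responses at/above an arbitrary level.

    Same denominator as :func:`attribute_proportion_score`; at
    ``level == CUT_LEVEL`` the two coincide.
    """
    return attribute_proportion_score(pooled, term_id, attribute, cut_level=level)


def impact_proportion_score(panel: pd.DataFrame, term_id: str) -> ProportionScore:
    """Physician impact score: ratings >= moderate over *all* ratings.

    Unlike the patient attribute scores, the denominator is every
    respondent who rated the term, not the symptomatic subset; with a
    9-member panel every defined value is a multiple of 1/9.
    """
    ratings = panel.loc[panel["term_id"] == term_id, "impact"]
    ratings = ratings.dropna()
    return ProportionScore(
        int((ratings >= CUT_LEVEL).sum()), int(len(ratings))
    )


@dataclass(frozen=True)
class ScoreTable:
    """Tidy per-term score table.

    One row per (term, metric) actually asked; columns term_id, metric,
    numerator, denominator, value.  Undefined (0/0) scores keep their row
    with value NaN; metrics a term does not carry have no row at all, so
    "not asked" is never conflated with zero.
    """

    frame: pd.DataFrame

    _COLUMNS = ("term_id", "metric", "numerator", "denominator", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self._COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")

    def has_metric(self, term_id: str, metric: str) -> bool:
        f = self.frame
        return bool(
            ((f["term_id"] == term_id) & (f["metric"] == metric)).any()
        )

    def get(self, term_id: str, metric: str) -> ProportionScore | NotAsked:
        f = self.frame
        rows = f.loc[(f["term_id"] == term_id) & (f["metric"] == metric)]
        if rows.empty:
            return NOT_ASKED
        row = rows.iloc[0]
        if pd.isna(row["numerator"]) or pd.isna(row["denominator"]):
            # fixture tables may carry values without count provenance
            return _ValueOnlyScore(row["value"])
        return ProportionScore(int(row["numerator"]), int(row["denominator"]))

    def value(self, term_id: str, metric: str) -> float | None:
        score = self.get(term_id, metric)
        if score is NOT_ASKED:
            return None
        v = score.value
        return None if v is None or pd.isna(v) else float(v)

    def metrics_for(self, term_id: str) -> tuple[str, ...]:
        f = self.frame
        return tuple(f.loc[f["term_id"] == term_id, "metric"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.frame.to_json(path, orient="records", indent=2)

    @classmethod
    def from_values(
        cls, values: dict[str, dict[str, float | None]]
    ) -> "ScoreTable":
        """Build a table from {term_id: {metric: value}} without counts.

        Used for fixtures where only the score values are known; ``None``
        marks a defined-but-undefined (0/0) entry.
        """
        rows = []
        for term_id, metrics in values.items():
            for metric, value in metrics.items():
                rows.append(
                    {
                        "term_id": term_id,
                        "metric": metric,
                        "numerator": np.nan,
                        "denominator": np.nan,
                        "value": np.nan if value is None else float(value),
                    }
                )
        return cls(pd.DataFrame(rows, columns=list(cls._COLUMNS)))


class _ValueOnlyScore:
    """Score carrying a value but no count provenance (fixture tables)."""

    def __init__(self, value: float):
        self._value = value

    @property
    def defined(self) -> bool:
        return not pd.isna(self._value)

    @property
    def value(self) -> float | None:
        return None if pd.isna(self._value) else float(self._value)

    @property
    def percent(self) -> float | None:
        v = self.value
        return None if v is None else round_half_up_percent(v)

    def __repr__(self) -> str:
        return f"ValueOnlyScore({self._value})"


def _score_row(term_id: str, metric: str, score: ProportionScore) -> dict:
    return {
        "term_id": term_id,
        "metric": metric,
        "numerator": score.numerator,
        "denominator": score.denominator,
        "value": np.nan if score.value is None else score.value,
    }


def score_table(
    pooled: PooledResponses, library: TermLibrary | None = None
) -> ScoreTable:
    """Assemble prevalence plus all asked attribute proportion scores.

    Exactly one prevalence row per library term, plus one row per ordinal
    attribute the term carries; library (file) order is preserved.
    """
    library = library or pooled.library
    rows = []
    for term in library:
        rows.append(
            _score_row(term.term_id, "prevalence", prevalence(pooled, term.term_id))
        )
        for kind in ORDINAL_KINDS:
            if kind in term.attributes:
                score = attribute_proportion_score(pooled, term.term_id, kind)
                rows.append(_score_row(term.term_id, kind.value, score))
    return ScoreTable(pd.DataFrame(rows, columns=list(ScoreTable._COLUMNS)))


def impact_table(panel: pd.DataFrame, terms: Iterable[str]) -> ScoreTable:
    """Impact proportion scores for ``terms`` as a one-metric ScoreTable."""
    rows = [
        _score_row(t, "impact", impact_proportion_score(panel, t))
        for t in terms
    ]
    return ScoreTable(pd.DataFrame(rows, columns=list(ScoreTable._COLUMNS)))
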