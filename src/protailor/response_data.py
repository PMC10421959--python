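"""Ingestion, validation and timepoint pooling of patient survey responses.

Responses live in long format: one row per (patient, timepoint, term,
attribute) with an ordinal level.  A *survey administration* is the set of
rows one patient contributed at one timepoint.  Attrition is handled by
counting only administered surveys in downstream denominators — patients
who stopped before a later timepoint simply contribute nothing there.
An unanswered item within an administered survey is represented by the
absence of its row; it is excluded from numerators and denominators of any
score that uses it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .term_library import AttributeKind, TermLibrary

__all__ = [
    "TIMEPOINTS",
    "BEST_RESPONSE_CATEGORIES",
    "ResponseValidationError",
    "ResponseFormatError",
    "EmptyDatasetError",
    "ResponseDataset",
    "PooledResponses",
    "CohortSummary",
    "read_responses",
    "write_responses",
    "pool_timepoints",
    "read_patients",
    "cohort_summary",
]

#: the study design's three administrations, in chronological order
TIMEPOINTS = ("baseline", "mid_cycle_1", "mid_cycle_2")

#: RECIST best-response categories (closed set)
BEST_RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")

_RESPONSE_COLUMNS = ("patient_id", "timepoint", "term_id", "attribute", "level")


class ResponseFormatError(ValueError):
    """File does not have the expected columns."""


class ResponseValidationError(ValueError):
    """Row content violates the library contract or level ranges."""


class EmptyDatasetError(ValueError):
    """An operation that needs data received none."""


@dataclass(frozen=True)
class ResponseDataset:
    """Validated long-format survey responses bound to a term library.

    ``frame`` has columns patient_id, timepoint, term_id, attribute, level.
    """

    frame: pd.DataFrame
    library: TermLibrary
    timepoints: tuple[str, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        _validate_frame(self.frame, self.library, self.timepoints)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def administrations(self) -> pd.DataFrame:
        """One row per (patient_id, timepoint) survey administration."""
        return (
            self.frame[["patient_id", "timepoint"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def administration_counts(self) -> dict[str, int]:
        """Number of administered surveys per timepoint (attrition report)."""
        admins = self.administrations
        counts = admins["timepoint"].value_counts()
        return {tp: int(counts.get(tp, 0)) for tp in self.timepoints}

    @property
    def n_administrations(self) -> int:
        return len(self.administrations)


def _validate_frame(
    frame: pd.DataFrame, library: TermLibrary, timepoints: Sequence[str]
) -> None:
    missing = [c for c in _RESPONSE_COLUMNS if c not in frame.columns]
    if missing:
        raise ResponseFormatError(f"missing columns: {missing}")
    if frame.empty:
        return
    bad_tp = frame.loc[~frame["timepoint"].isin(timepoints)]
    if not bad_tp.empty:
        raise ResponseValidationError(
            f"row {bad_tp.index[0]}: unknown timepoint "
            f"{bad_tp['timepoint'].iloc[0]!r}"
        )
    valid_attrs = {k.value for k in AttributeKind}
    bad_attr = frame.loc[~frame["attribute"].isin(valid_attrs)]
    if not bad_attr.empty:
        raise ResponseValidationError(
            f"row {bad_attr.index[0]}: unknown attribute "
            f"{bad_attr['attribute'].iloc[0]!r}"
        )
    for row_idx, term_id, attr, level in frame[
        ["term_id", "attribute", "level"]
    ].itertuples(index=True, name=None):
        if term_id not in library:
            raise ResponseValidationError(
                f"row {row_idx}: term {term_id!r} not in library"
            )
        kind = AttributeKind(attr)
        if kind not in library[term_id].attributes:
            raise ResponseValidationError(
                f"row {row_idx}: attribute {attr!r} not asked for term "
                f"{term_id!r}"
            )
        if not (0 <= int(level) <= kind.max_level):
            raise ResponseValidationError(
                f"row {row_idx}: level {level} out of range for {attr!r}"
            )
    dup = frame.duplicated(
        subset=["patient_id", "timepoint", "term_id", "attribute"]
    )
    if dup.any():
        raise ResponseValidationError(
            f"row {frame.index[dup.argmax()]}: duplicate "
            "(patient, timepoint, term, attribute) key"
        )


def read_responses(
    source, library: TermLibrary, timepoints: Sequence[str] = TIMEPOINTS
) -> ResponseDataset:
    """Read and validate a long-format response CSV."""
    try:
        frame = pd.read_csv(
            source, dtype={"patient_id": str, "timepoint": str, "term_id": str,
                           "attribute": str}
        )
    except pd.errors.EmptyDataError as exc:
        raise ResponseFormatError("response file is empty") from exc
    missing = [c for c in _RESPONSE_COLUMNS if c not in frame.columns]
    if missing:
        raise ResponseFormatError(f"missing columns: {missing}")
    frame["level"] = pd.to_numeric(frame["level"], errors="raise").astype(int)
    return ResponseDataset(
        frame=frame.reset_index(drop=True),
        library=library,
        timepoints=tuple(timepoints),
    )


def write_responses(dataset: ResponseDataset, path) -> None:
    dataset.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class PooledResponses:
    """All administrations' records concatenated across timepoints.

    ``frame`` carries an ``admin_id`` key (patient_id|timepoint) so that
    score denominators can count survey administrations, not patients.
    """

    frame: pd.DataFrame
    library: TermLibrary
    n_surveys: int

    def term_rows(self, term_id: str) -> pd.DataFrame:
        return self.frame.loc[self.frame["term_id"] == term_id]


def pool_timepoints(
    dataset: ResponseDataset, complete_case: bool = False
) -> PooledResponses:
    """Pool responses across timepoints into one response table.

    Each administration contributes one row per answered item; record
    count is preserved exactly.  With ``complete_case=True`` only patients
    who completed every timepoint are kept (non-default alternative to
    attrition-adjusted denominators).
    """
    frame = dataset.frame
    if frame.empty:
        raise EmptyDatasetError("cannot pool an empty dataset")
    if complete_case:
        per_patient = (
            frame[["patient_id", "timepoint"]]
            .drop_duplicates()
            .groupby("patient_id")["timepoint"]
            .nunique()
        )
        keep = per_patient[per_patient == len(dataset.timepoints)].index
        frame = frame.loc[frame["patient_id"].isin(keep)]
        if frame.empty:
            raise EmptyDatasetError("no complete-case patients")
    pooled = frame.copy()
    pooled["admin_id"] = (
        pooled["patient_id"].astype(str) + "|" + pooled["timepoint"].astype(str)
    )
    n_surveys = pooled["admin_id"].nunique()
    return PooledResponses(
        frame=pooled.reset_index(drop=True),
        library=dataset.library,
        n_surveys=int(n_surveys),
    )


# -- patient characteristics -------------------------------------------------

_PATIENT_COLUMNS = ("patient_id", "best_response")


@dataclass(frozen=True)
class CohortSummary:
    """Counts per best-response category plus the overall response rate."""

    n: int
    best_response_counts: dict[str, int]
    orr: float  # (CR + PR) / n, as a proportion

    @property
    def orr_percent(self) -> float:
        from .scoring import round_half_up_percent

        return round_half_up_percent(self.orr)


def read_patients(source) -> pd.DataFrame:
    frame = pd.read_csv(source, dtype=str)
    missing = [c for c in _PATIENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ResponseFormatError(f"missing columns: {missing}")
    return frame


def cohort_summary(patients: pd.DataFrame) -> CohortSummary:
    """Summarise a patient table; ORR = (CR + PR) / total.

    The best-response column must only contain the closed RECIST set
    CR/PR/SD/PD/NE.
    """
    if "best_response" not in patients.columns:
        raise ResponseFormatError("missing column best_response")
    values = patients["best_response"]
    bad = values.loc[~values.isin(BEST_RESPONSE_CATEGORIES)]
    if not bad.empty:
        raise ResponseValidationError(
            f"unknown best-response category {bad.iloc[0]!r}"
        )
    counts = {c: int((values == c).sum()) for c in BEST_RESPONSE_CATEGORIES}
    n = int(len(values))
    if n == 0:
        raise EmptyDatasetError("patient table is empty")
    orr = (counts["CR"] + counts["PR"]) / n
    return CohortSummary(n=n, best_response_counts=counts, orr=orr)
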