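"""Domain reliability: Cronbach's alpha and leave-one-term-out pruning.

Each organ-system domain is treated as a small scale whose items are the
domain's terms.  A per-term composite item score (default: the maximum
level over the term's answered attribute items within one survey
administration) enters Cronbach's alpha.  For each term, alpha is
recomputed with that term excluded; the term whose removal changes the
domain's reliability least is considered low-yield and is a candidate for
removal.  Domains with two or fewer remaining terms are never pruned:
removing an item there would change the scale qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .response_data import PooledResponses
from .term_library import TermLibrary, UnknownDomainError

__all__ = [
    "ALPHA_ZERO_TOL",
    "CompositeRule",
    "ItemScoreMatrix",
    "TermReliability",
    "ReliabilityResult",
    "composite_item_scores",
    "cronbach_alpha",
    "loo_percent_change",
    "select_reliability_removals",
    "reliability_table",
]

#: |alpha_full| below this is treated as zero: percent change undefined
ALPHA_ZERO_TOL = 1e-8

CompositeRule = Literal["max", "severity", "mean"]

#: rows = survey administrations, columns = one domain's terms
ItemScoreMatrix = pd.DataFrame


def composite_item_scores(
    pooled: PooledResponses,
    library: TermLibrary,
    domain: str,
    terms: Sequence[str] | None = None,
    rule: CompositeRule = "max",
) -> ItemScoreMatrix:
    """Per-administration composite scores for one domain's terms.

    ``rule='max'`` takes the maximum level across the term's answered
    attribute items (presence-only terms contribute their 0/1), matching
    the "any attribute" disjunction used for prevalence.  ``'severity'``
    uses the severity item alone; ``'mean'`` averages answered items.
    An administration that answered none of a term's items gets a missing
    cell.
    """
    domain_all = library.domain_terms(domain)  # raises UnknownDomainError
    if terms is None:
        use = list(domain_all)
    else:
        use = [t for t in sorted(terms)]
        stray = set(use) - set(domain_all)
        if stray:
            raise UnknownDomainError(
                f"terms {sorted(stray)} are not in domain {domain!r}"
            )
    if not use:
        raise UnknownDomainError(f"domain {domain!r} has no terms to score")
    frame = pooled.frame
    rows = frame.loc[frame["term_id"].isin(use)]
    if rule == "severity":
        rows = rows.loc[rows["attribute"].isin(["severity", "presence"])]
    agg = "mean" if rule == "mean" else "max"
    matrix = rows.pivot_table(
        index="admin_id", columns="term_id", values="level", aggfunc=agg
    )
    # keep requested column order; reinstate all-missing columns
    matrix = matrix.reindex(columns=use)
    matrix.columns.name = None
    return matrix.astype(float)


def _as_complete_array(matrix: ItemScoreMatrix) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    complete = arr[~np.isnan(arr).any(axis=1)]
    return complete


def cronbach_alpha(matrix: ItemScoreMatrix | np.ndarray) -> float | None:
    """Cronbach's alpha with listwise deletion and n-1 variances.

    alpha = k/(k-1) * (1 - sum(item variances) / var(row sums)).
    Returns ``None`` (undefined) with fewer than 2 columns, fewer than 2
    complete rows, or a degenerate total score (zero variance).
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        return None
    complete = _as_complete_array(arr)
    if complete.shape[0] < 2:
        return None
    k = complete.shape[1]
    item_var = complete.var(axis=0, ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        return None
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


@dataclass(frozen=True)
class TermReliability:
    """Leave-one-out reliability figures for one term."""

    term_id: str
    alpha_without: float | None  # alpha_2
    delta: float | None          # alpha_2 - alpha_1
    percent_change: float | None  # delta / alpha_1 * 100


@dataclass(frozen=True)
class ReliabilityResult:
    """Domain alpha plus per-term leave-one-out changes.

    ``eligible`` is True only when the domain had more than 2 terms, so
    each leave-one-out alpha is itself defined on >= 2 items.
    """

    domain: str
    alpha_full: float | None
    terms: tuple[TermReliability, ...]
    eligible: bool

    def percent_changes(self) -> dict[str, float | None]:
        return {t.term_id: t.percent_change for t in self.terms}


def loo_percent_change(
    matrix: ItemScoreMatrix, domain: str = ""
) -> ReliabilityResult:
    """Recompute alpha with each term independently excluded.

    delta = alpha_without - alpha_full; percent change = delta/alpha_full
    (as a percent).  With fewer than 3 columns the domain is ineligible
    and no per-term figures are produced.  Listwise deletion is applied
    once on the full domain so every leave-one-out alpha sees the same
    rows.
    """
    columns = list(matrix.columns)
    if len(columns) < 3:
        return ReliabilityResult(
            domain=domain,
            alpha_full=cronbach_alpha(matrix),
            terms=(),
            eligible=False,
        )
    complete = matrix.dropna(axis=0, how="any")
    alpha_full = cronbach_alpha(complete)
    terms = []
    for col in columns:
        alpha_without = cronbach_alpha(complete.drop(columns=[col]))
        if alpha_full is None or alpha_without is None:
            delta = pct = None
        else:
            delta = alpha_without - alpha_full
            if abs(alpha_full) < ALPHA_ZERO_TOL:
                pct = None
            else:
                pct = delta / alpha_full * 100.0
        terms.append(
            TermReliability(
                term_id=col,
                alpha_without=alpha_without,
                delta=delta,
                percent_change=pct,
            )
        )
    return ReliabilityResult(
        domain=domain,
        alpha_full=alpha_full,
        terms=tuple(terms),
        eligible=True,
    )


def select_reliability_removals(
    results: Mapping[str, ReliabilityResult],
    policy: Literal["absolute", "signed"] = "absolute",
) -> dict[str, str]:
    """Pick the one removable term per eligible domain.

    Default policy removes the term with the smallest *absolute* percent
    change in domain reliability (minimal effect on the scale);
    ``'signed'`` removes the signed minimum instead.  Ties break
    lexicographically on term_id.  Domains that are ineligible, have an
    undefined alpha, or only undefined percent changes are skipped.
    """
    removals: dict[str, str] = {}
    for domain in sorted(results):
        result = results[domain]
        if not result.eligible:
            continue
        candidates = [
            t for t in result.terms if t.percent_change is not None
        ]
        if not candidates:
            continue
        if policy == "absolute":
            key = lambda t: (abs(t.percent_change), t.term_id)
        elif policy == "signed":
            key = lambda t: (t.percent_change, t.term_id)
        else:
            raise ValueError(f"unknown policy {policy!r}")
        removals[domain] = min(candidates, key=key).term_id
    return removals


def reliability_table(results: Mapping[str, ReliabilityResult]) -> pd.DataFrame:
    """Flatten results for CSV export."""
    rows = []
    for domain in sorted(results):
        result = results[domain]
        for t in result.terms:
            rows.append(
                {
                    "domain": domain,
                    "term_id": t.term_id,
                    "alpha_full": result.alpha_full,
                    "alpha_without": t.alpha_without,
                    "delta": t.delta,
                    "percent_change": t.percent_change,
                    "eligible": result.eligible,
                }
            )
        if not result.terms:
            rows.append(
                {
                    "domain": domain,
                    "term_id": None,
                    "alpha_full": result.alpha_full,
                    "alpha_without": None,
                    "delta": None,
                    "percent_change": None,
                    "eligible": result.eligible,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "domain",
            "term_id",
            "alpha_full",
            "alpha_without",
            "delta",
            "percent_change",
            "eligible",
        ],
    )
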