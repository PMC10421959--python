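"""The elimination pipeline: threshold filters, reliability pruning,
physician refinement, and an auditable ledger.

Seven steps run in a fixed order:

1. prevalence < 5%  -> eliminate ("not administered" terms also drop here)
2. severity proportion score < 25%      (terms without a severity
   question are retained and flagged carried-forward)
3. interference proportion score < 25%  (carry-forward likewise)
4. frequency proportion score < 25%     (carry-forward likewise)
5. amount proportion score < 25%        (carry-forward likewise)
6. one term with the smallest leave-one-out change in domain reliability
   removed per domain with more than 2 remaining terms
7. physician impact proportion score < 25%, then reintroduction of
   configured terms that were eliminated at any earlier step

Scores for steps 1-5 are computed once from the pooled data; only the
reliability step is recomputed on the then-current working set.  A term
exactly at a threshold is retained (elimination is strict ``<``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

from .reliability import (
    CompositeRule,
    composite_item_scores,
    loo_percent_change,
    select_reliability_removals,
)
from .response_data import PooledResponses, ResponseDataset, pool_timepoints
from .scoring import (
    NOT_ASKED,
    ScoreTable,
    impact_table,
    score_table,
)
from .term_library import ORDINAL_KINDS, TermLibrary, UnknownTermError

__all__ = [
    "TailoringConfig",
    "LedgerStep",
    "EliminationLedger",
    "TailoredSurvey",
    "LedgerIntegrityError",
    "apply_threshold_filter",
    "run_patient_steps",
    "run_patient_steps_from_scores",
    "run_physician_step",
    "run_pipeline",
    "build_report",
]

#: pipeline step names in execution order
PATIENT_STEPS = ("prevalence", "severity", "interference", "frequency", "amount")


class LedgerIntegrityError(RuntimeError):
    """The ledger's conservation invariant failed."""


@dataclass(frozen=True)
class TailoringConfig:
    """Thresholds and policies for one tailoring run.

    Defaults: prevalence eliminates below 5%; every proportion-score step
    (patient attributes and physician impact) eliminates below 25%.
    """

    prevalence_threshold: float = 0.05
    proportion_score_threshold: float = 0.25
    impact_threshold: float = 0.25
    reintroduction_terms: tuple[str, ...] = ()
    reliability_policy: str = "absolute"  # or "signed"
    composite_rule: CompositeRule = "max"
    complete_case: bool = False

    def __post_init__(self) -> None:
        for name in (
            "prevalence_threshold",
            "proportion_score_threshold",
            "impact_threshold",
        ):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {value}")

    @classmethod
    def from_yaml(cls, source) -> "TailoringConfig":
        with open(source) as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ValueError("tailoring config must be a mapping")
        if "reintroduction_terms" in raw:
            raw["reintroduction_terms"] = tuple(raw["reintroduction_terms"])
        return cls(**raw)

    def to_dict(self) -> dict:
        data = asdict(self)
        data["reintroduction_terms"] = list(self.reintroduction_terms)
        return data


@dataclass(frozen=True)
class LedgerStep:
    """One pipeline step: what was removed, kept, or added back, and why."""

    name: str
    metric: str
    threshold: float | None
    eliminated: dict[str, float | None]  # term -> score at elimination
    carried_forward: tuple[str, ...]
    reintroduced: tuple[str, ...]
    survivors: tuple[str, ...]

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)


@dataclass
class EliminationLedger:
    """Ordered record of every elimination/reintroduction decision."""

    library_size: int
    steps: list[LedgerStep] = field(default_factory=list)

    def record(self, step: LedgerStep) -> None:
        already = self.eliminated_terms()
        overlap = set(step.eliminated) & already
        if overlap:
            raise LedgerIntegrityError(
                f"terms eliminated twice: {sorted(overlap)}"
            )
        bad_reintro = set(step.reintroduced) - already
        if bad_reintro:
            raise LedgerIntegrityError(
                f"reintroduced terms never eliminated: {sorted(bad_reintro)}"
            )
        self.steps.append(step)

    def eliminated_terms(self) -> set[str]:
        out: set[str] = set()
        for step in self.steps:
            out |= set(step.eliminated)
        return out

    def reintroduced_terms(self) -> set[str]:
        out: set[str] = set()
        for step in self.steps:
            out |= set(step.reintroduced)
        return out

    @property
    def final_survivors(self) -> tuple[str, ...]:
        if not self.steps:
            raise LedgerIntegrityError("empty ledger")
        return self.steps[-1].survivors

    def check_conservation(self) -> None:
        """|library| - total eliminated + reintroduced == |final|."""
        n_elim = sum(len(s.eliminated) for s in self.steps)
        n_reintro = sum(len(s.reintroduced) for s in self.steps)
        expected = self.library_size - n_elim + n_reintro
        if expected != len(self.final_survivors):
            raise LedgerIntegrityError(
                f"conservation failed: {self.library_size} - {n_elim} + "
                f"{n_reintro} != {len(self.final_survivors)}"
            )

    def survivor_counts(self) -> dict[str, int]:
        return {s.name: s.n_survivors for s in self.steps}

    def to_dict(self) -> dict:
        return {
            "library_size": self.library_size,
            "steps": [
                {
                    "name": s.name,
                    "metric": s.metric,
                    "threshold": s.threshold,
                    "eliminated": {
                        t: (None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v))
                        for t, v in s.eliminated.items()
                    },
                    "carried_forward": list(s.carried_forward),
                    "reintroduced": list(s.reintroduced),
                    "survivors": list(s.survivors),
                    "n_survivors": s.n_survivors,
                }
                for s in self.steps
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2)

    def to_markdown(self) -> str:
        lines = [
            "# Elimination ledger",
            "",
            f"Library size: {self.library_size}",
            "",
        ]
        for step in self.steps:
            thr = "-" if step.threshold is None else f"{step.threshold:g}"
            lines.append(f"## Step: {step.name} (metric={step.metric}, threshold={thr})")
            if step.eliminated:
                lines.append("Eliminated:")
                for term in sorted(step.eliminated):
                    value = step.eliminated[term]
                    shown = "undefined" if value is None else f"{value:.3f}"
                    lines.append(f"- {term} ({shown})")
            else:
                lines.append("Eliminated: none")
            if step.carried_forward:
                lines.append(
                    "Carried forward (attribute not asked): "
                    + ", ".join(sorted(step.carried_forward))
                )
            if step.reintroduced:
                lines.append("Reintroduced: " + ", ".join(sorted(step.reintroduced)))
            lines.append(f"Survivors: {step.n_survivors}")
            lines.append("")
        return "\n".join(lines)


def apply_threshold_filter(
    scores: ScoreTable,
    working: Sequence[str],
    metric: str,
    threshold: float,
    library: TermLibrary,
    carry_forward: bool = True,
) -> tuple[dict[str, float | None], list[str], list[str]]:
    """Split ``working`` into eliminated / retained / carried-forward.

    A term is eliminated iff its score is defined and strictly below
    ``threshold``; a term exactly at the threshold passes.  Terms lacking
    the metric's attribute question are retained and flagged
    carried-forward (when ``carry_forward`` is set).  For the prevalence
    metric an *undefined* score means the term was never administered and
    the term is eliminated with a ``None`` score; for attribute metrics an
    undefined score joins the carried-forward set.
    """
    eliminated: dict[str, float | None] = {}
    retained: list[str] = []
    carried: list[str] = []
    for term_id in working:
        if term_id not in library:
            raise UnknownTermError(term_id)
        score = scores.get(term_id, metric)
        if score is NOT_ASKED:
            if metric == "prevalence":
                raise ValueError(
                    f"score table has no prevalence row for {term_id!r}"
                )
            if not carry_forward:
                raise ValueError(
                    f"term {term_id!r} lacks metric {metric!r} and "
                    "carry-forward is disabled"
                )
            retained.append(term_id)
            carried.append(term_id)
            continue
        value = score.value
        if value is None:
            if metric == "prevalence":
                eliminated[term_id] = None  # never administered
            else:
                retained.append(term_id)
                carried.append(term_id)
            continue
        if value < threshold:
            eliminated[term_id] = float(value)
        else:
            retained.append(term_id)
    return eliminated, retained, carried


def _reliability_step(
    pooled: PooledResponses,
    library: TermLibrary,
    working: Sequence[str],
    config: TailoringConfig,
) -> tuple[dict[str, float | None], dict]:
    """Compute leave-one-out removals on the current working set."""
    by_domain: dict[str, list[str]] = {}
    for term_id in working:
        by_domain.setdefault(library.domain_of(term_id), []).append(term_id)
    results = {}
    for domain, terms in by_domain.items():
        if len(terms) < 2:
            continue
        matrix = composite_item_scores(
            pooled, library, domain, terms=terms, rule=config.composite_rule
        )
        results[domain] = loo_percent_change(matrix, domain=domain)
    removals = select_reliability_removals(
        results, policy=config.reliability_policy
    )
    eliminated = {}
    for domain, term_id in sorted(removals.items()):
        pct = dict(results[domain].percent_changes())[term_id]
        eliminated[term_id] = pct
    return eliminated, results


def run_patient_steps(
    dataset: ResponseDataset,
    library: TermLibrary | None = None,
    config: TailoringConfig | None = None,
) -> tuple[EliminationLedger, tuple[str, ...], ScoreTable, dict]:
    """Steps 1-6 from patient data.

    Returns the ledger so far, the surviving working set, the score table
    the filters used, and the per-domain reliability results.
    """
    library = library or dataset.library
    config = config or TailoringConfig()
    pooled = pool_timepoints(dataset, complete_case=config.complete_case)
    scores = score_table(pooled, library)
    ledger, working = _threshold_steps(scores, library, config)
    eliminated, results = _reliability_step(pooled, library, working, config)
    working = tuple(t for t in working if t not in eliminated)
    ledger.record(
        LedgerStep(
            name="reliability",
            metric="loo_percent_change",
            threshold=None,
            eliminated=eliminated,
            carried_forward=(),
            reintroduced=(),
            survivors=working,
        )
    )
    return ledger, working, scores, results


def _threshold_steps(
    scores: ScoreTable, library: TermLibrary, config: TailoringConfig
) -> tuple[EliminationLedger, tuple[str, ...]]:
    ledger = EliminationLedger(library_size=len(library))
    working: tuple[str, ...] = library.term_ids
    for metric in PATIENT_STEPS:
        threshold = (
            config.prevalence_threshold
            if metric == "prevalence"
            else config.proportion_score_threshold
        )
        eliminated, retained, carried = apply_threshold_filter(
            scores, working, metric, threshold, library
        )
        working = tuple(retained)
        ledger.record(
            LedgerStep(
                name=metric,
                metric=metric,
                threshold=threshold,
                eliminated=eliminated,
                carried_forward=tuple(carried),
                reintroduced=(),
                survivors=working,
            )
        )
    return ledger, working


def run_patient_steps_from_scores(
    scores: ScoreTable,
    library: TermLibrary,
    config: TailoringConfig | None = None,
    reliability_removals: Mapping[str, float | None] | Sequence[str] | None = None,
) -> tuple[EliminationLedger, tuple[str, ...]]:
    """Replay steps 1-6 from a precomputed score table.

    ``reliability_removals`` supplies the step-6 removals explicitly
    (term -> percent change, or just a term sequence), for replaying a
    recorded analysis whose raw responses are unavailable.  Each removal
    must be in the working set, at most one per domain, and only from
    domains with more than 2 remaining terms.
    """
    config = config or TailoringConfig()
    ledger, working = _threshold_steps(scores, library, config)
    if reliability_removals is None:
        removals: dict[str, float | None] = {}
    elif isinstance(reliability_removals, Mapping):
        removals = dict(reliability_removals)
    else:
        removals = {t: None for t in reliability_removals}
    by_domain: dict[str, list[str]] = {}
    for term_id in working:
        by_domain.setdefault(library.domain_of(term_id), []).append(term_id)
    seen_domains: set[str] = set()
    for term_id in removals:
        if term_id not in working:
            raise LedgerIntegrityError(
                f"reliability removal {term_id!r} is not in the working set"
            )
        domain = library.domain_of(term_id)
        if domain in seen_domains:
            raise LedgerIntegrityError(
                f"two reliability removals from domain {domain!r}"
            )
        if len(by_domain[domain]) <= 2:
            raise LedgerIntegrityError(
                f"domain {domain!r} has <=2 terms; nothing may be removed"
            )
        seen_domains.add(domain)
    working = tuple(t for t in working if t not in removals)
    ledger.record(
        LedgerStep(
            name="reliability",
            metric="loo_percent_change",
            threshold=None,
            eliminated=removals,
            carried_forward=(),
            reintroduced=(),
            survivors=working,
        )
    )
    return ledger, working


def run_physician_step(
    working: Sequence[str],
    impact_scores: ScoreTable,
    config: TailoringConfig,
    ledger: EliminationLedger,
    library: TermLibrary,
) -> tuple[str, ...]:
    """Step 7: impact-threshold elimination then reintroduction.

    Terms with a defined impact proportion score strictly below the
    threshold are removed; unrated terms are retained and flagged.  The
    configured reintroduction terms must exist in the library and must
    have been eliminated at some earlier step; they come back with their
    full attribute sets.  The final set is sorted by term_id.
    """
    eliminated: dict[str, float | None] = {}
    retained: list[str] = []
    carried: list[str] = []
    for term_id in working:
        score = impact_scores.get(term_id, "impact")
        if score is NOT_ASKED or score.value is None:
            retained.append(term_id)
            carried.append(term_id)
            continue
        if score.value < config.impact_threshold:
            eliminated[term_id] = float(score.value)
        else:
            retained.append(term_id)
    for term_id in config.reintroduction_terms:
        if term_id not in library:
            raise UnknownTermError(term_id)
    previously_eliminated = ledger.eliminated_terms() | set(eliminated)
    never_eliminated = set(config.reintroduction_terms) - previously_eliminated
    if never_eliminated:
        raise LedgerIntegrityError(
            "cannot reintroduce terms never eliminated: "
            f"{sorted(never_eliminated)}"
        )
    final = tuple(sorted(set(retained) | set(config.reintroduction_terms)))
    ledger.record(
        LedgerStep(
            name="impact",
            metric="impact",
            threshold=config.impact_threshold,
            eliminated=eliminated,
            carried_forward=tuple(carried),
            reintroduced=tuple(sorted(config.reintroduction_terms)),
            survivors=final,
        )
    )
    return final


@dataclass(frozen=True)
class TailoredSurvey:
    """The final tailored survey: terms, their attribute sets, and size."""

    terms: tuple[str, ...]
    attributes: dict[str, tuple[str, ...]]
    max_item_count: int
    domain_count: int

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "attributes": {t: list(a) for t, a in self.attributes.items()},
            "max_item_count": self.max_item_count,
            "domain_count": self.domain_count,
        }


def build_report(
    ledger: EliminationLedger,
    final: Sequence[str],
    library: TermLibrary,
) -> tuple[TailoredSurvey, str]:
    """Assemble the tailored survey and a human-readable report.

    Refuses to render (raises :class:`LedgerIntegrityError`) if the
    ledger's conservation invariant does not hold.
    """
    ledger.check_conservation()
    if tuple(sorted(final)) != tuple(sorted(ledger.final_survivors)):
        raise LedgerIntegrityError("final set does not match ledger survivors")
    superscript = {
        "frequency": "F",
        "interference": "I",
        "presence": "P",
        "severity": "S",
        "amount": "A",
    }
    attributes = {}
    for term_id in sorted(final):
        kinds = sorted(k.value for k in library[term_id].attributes)
        attributes[term_id] = tuple(kinds)
    survey = TailoredSurvey(
        terms=tuple(sorted(final)),
        attributes=attributes,
        max_item_count=library.item_count(final),
        domain_count=len({library.domain_of(t) for t in final}),
    )
    lines = [ledger.to_markdown(), "# Final tailored survey", ""]
    lines.append(
        f"{len(survey.terms)} terms, {survey.domain_count} domains, "
        f"maximum {survey.max_item_count} items"
    )
    lines.append("")
    for term_id in survey.terms:
        marks = "".join(
            sorted(superscript[a] for a in survey.attributes[term_id])
        )
        lines.append(f"- {library[term_id].display_name} [{marks}]")
    return survey, "\n".join(lines)


def run_pipeline(
    dataset: ResponseDataset,
    panel,
    library: TermLibrary | None = None,
    config: TailoringConfig | None = None,
):
    """Full steps 1-7 plus report.

    Returns (ledger, survey, report_markdown, score_table, reliability
    results).
    """
    library = library or dataset.library
    config = config or TailoringConfig()
    ledger, working, scores, rel = run_patient_steps(dataset, library, config)
    impacts = impact_table(panel, working)
    final = run_physician_step(working, impacts, config, ledger, library)
    survey, report = build_report(ledger, final, library)
    return ledger, survey, report, scores, rel
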