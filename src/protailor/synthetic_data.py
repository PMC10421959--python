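"""Latent-factor simulator for ordinal PRO survey responses.

The generator emulates the structure the tailoring pipeline assumes: a
cohort answering the full item library at up to three timepoints with
attrition, ordinal attribute responses, and within-domain correlation
strong enough to make the reliability step meaningful.

Model.  For patient *i* at an administered timepoint, each organ-system
domain draws a latent factor ``z ~ N(0,1)``.  A term *t* with loading
``lambda_t`` draws ``u_t = lambda_t * z + sqrt(1 - lambda_t^2) * eps``
(``eps ~ N(0,1)``), so ``u_t`` is standard normal with a Gaussian-copula
correlation ``lambda_s * lambda_t`` between terms of a domain.  The term
is symptomatic iff ``Phi(u_t) > 1 - pi_t``: the marginal prevalence is
``pi_t`` *exactly* by construction.  Given symptomatic, the conditional
uniform ``v = (Phi(u_t) - (1 - pi_t)) / pi_t`` is mapped through each
attribute's conditional level distribution (levels 1-4), making a term's
attributes comonotone by default; presence-only terms answer 1.
Non-symptomatic terms answer 0 on every item.

Because marginals are exact, closed-form expected scores exist for every
term (:func:`analytic_marginals`), and the composite score entering
Cronbach's alpha is a known monotone transform of ``u_t``, so population
domain covariance matrices — and hence population alpha and its
leave-one-out changes — are computable by bivariate-normal quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import multivariate_normal

from .response_data import TIMEPOINTS, ResponseDataset
from .scoring import CUT_LEVEL, ScoreTable
from .term_library import (
    AttributeKind,
    ORDINAL_KINDS,
    TermLibrary,
    load_full_library,
)

__all__ = [
    "GeneratorConfigError",
    "TermParams",
    "GeneratorConfig",
    "PanelConfig",
    "simulate_survey_data",
    "analytic_marginals",
    "simulate_physician_panel",
    "composite_level_pmf",
    "population_domain_cov",
    "population_alpha",
    "population_loo_percent_change",
    "tune_loading_for_null_removal",
    "study_like_fixture",
    "StudyLikeFixture",
]


class GeneratorConfigError(ValueError):
    """Invalid simulation parameters."""


def _check_dist(dist: Sequence[float], name: str) -> tuple[float, ...]:
    arr = np.asarray(dist, dtype=float)
    if arr.shape != (4,):
        raise GeneratorConfigError(
            f"{name}: conditional distribution needs 4 probabilities "
            "(levels 1-4)"
        )
    if (arr < 0).any() or not np.isclose(arr.sum(), 1.0, atol=1e-9):
        raise GeneratorConfigError(f"{name}: probabilities must be >=0 and sum to 1")
    return tuple(float(x) for x in arr)


@dataclass(frozen=True)
class TermParams:
    """Marginal parameters of one term.

    ``prevalence`` is the marginal symptomatic probability; for each
    ordinal attribute the term carries, ``attribute_dists`` gives the
    conditional level distribution over levels 1-4 given symptomatic;
    ``loading`` is the term's loading on its domain factor.
    """

    prevalence: float
    attribute_dists: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    loading: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise GeneratorConfigError(
                f"prevalence must be in [0,1], got {self.prevalence}"
            )
        if not 0.0 <= self.loading < 1.0:
            raise GeneratorConfigError(
                f"loading must be in [0,1), got {self.loading}"
            )
        checked = {
            k: _check_dist(v, k) for k, v in dict(self.attribute_dists).items()
        }
        object.__setattr__(self, "attribute_dists", checked)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level simulation parameters.

    ``retention`` gives the per-timepoint probability that a patient
    completes that survey (independent Bernoulli); the study-like pattern
    (219/191/118 expected administrations from 219 patients) is
    ``(1.0, 191/219, 118/219)``.
    """

    n_patients: int
    terms: Mapping[str, TermParams]
    retention: tuple[float, ...] = (1.0, 191 / 219, 118 / 219)
    coupling: str = "comonotone"  # or "independent"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise GeneratorConfigError("n_patients must be >= 1")
        if not all(0.0 <= r <= 1.0 for r in self.retention):
            raise GeneratorConfigError("retention probabilities must be in [0,1]")
        if self.coupling not in ("comonotone", "independent"):
            raise GeneratorConfigError(f"unknown coupling {self.coupling!r}")
        object.__setattr__(self, "terms", dict(self.terms))
        object.__setattr__(self, "retention", tuple(self.retention))

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "retention": list(self.retention),
            "coupling": self.coupling,
            "seed": self.seed,
            "terms": {
                t: {
                    "prevalence": p.prevalence,
                    "loading": p.loading,
                    "attribute_dists": {
                        k: list(v) for k, v in p.attribute_dists.items()
                    },
                }
                for t, p in self.terms.items()
            },
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "GeneratorConfig":
        terms = {
            t: TermParams(
                prevalence=spec["prevalence"],
                attribute_dists={
                    k: tuple(v) for k, v in spec.get("attribute_dists", {}).items()
                },
                loading=spec.get("loading", 0.0),
            )
            for t, spec in raw["terms"].items()
        }
        return cls(
            n_patients=int(raw["n_patients"]),
            terms=terms,
            retention=tuple(raw.get("retention", (1.0, 191 / 219, 118 / 219))),
            coupling=raw.get("coupling", "comonotone"),
            seed=int(raw.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, dict):
            raise GeneratorConfigError("generator config must be a mapping")
        return cls.from_dict(raw)


@dataclass(frozen=True)
class PanelConfig:
    """Physician panel simulation: per-term impact level distributions
    over the 5 ordinal impact levels (0 = none .. 4)."""

    n_respondents: int
    impact_dists: Mapping[str, tuple[float, ...]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise GeneratorConfigError("n_respondents must be >= 1")
        checked = {}
        for term, dist in dict(self.impact_dists).items():
            arr = np.asarray(dist, dtype=float)
            if arr.shape != (5,):
                raise GeneratorConfigError(
                    f"{term}: impact distribution needs 5 probabilities"
                )
            if (arr < 0).any() or not np.isclose(arr.sum(), 1.0, atol=1e-9):
                raise GeneratorConfigError(
                    f"{term}: probabilities must be >=0 and sum to 1"
                )
            checked[term] = tuple(float(x) for x in arr)
        object.__setattr__(self, "impact_dists", checked)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _levels_from_uniform(dist: tuple[float, ...], v: np.ndarray) -> np.ndarray:
    """Map conditional uniforms to levels 1-4 through the inverse CDF."""
    cdf = np.cumsum(dist)
    return np.searchsorted(cdf, v, side="left").clip(max=3) + 1


def simulate_survey_data(
    config: GeneratorConfig,
    library: TermLibrary | None = None,
    seed: int | None = None,
    timepoints: Sequence[str] = TIMEPOINTS,
) -> ResponseDataset:
    """Draw one complete long-format response dataset.

    Every term in ``config.terms`` must exist in the library; every
    administered survey answers every item of those terms (item-level
    missingness is not simulated).  Identical (config, seed) pairs give
    identical datasets.
    """
    library = library or load_full_library()
    for term_id in config.terms:
        library[term_id]  # raises UnknownTermError
    if len(config.retention) != len(timepoints):
        raise GeneratorConfigError(
            "retention must give one probability per timepoint"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # administrations: independent Bernoulli retention per timepoint
    n = config.n_patients
    width = max(4, len(str(n)))
    patient_ids = np.array([f"P{i + 1:0{width}d}" for i in range(n)])
    admin_patient: list[np.ndarray] = []
    admin_tp: list[np.ndarray] = []
    for tp, r in zip(timepoints, config.retention):
        kept = rng.random(n) < r
        admin_patient.append(patient_ids[kept])
        admin_tp.append(np.repeat(tp, kept.sum()))
    patients = np.concatenate(admin_patient)
    tps = np.concatenate(admin_tp)
    n_admin = len(patients)

    by_domain: dict[str, list[str]] = {}
    for term_id in config.terms:
        by_domain.setdefault(library.domain_of(term_id), []).append(term_id)

    out_patient: list[np.ndarray] = []
    out_tp: list[np.ndarray] = []
    out_term: list[np.ndarray] = []
    out_attr: list[np.ndarray] = []
    out_level: list[np.ndarray] = []

    for domain in sorted(by_domain):
        term_ids = sorted(by_domain[domain])
        z = rng.standard_normal(n_admin)
        for term_id in term_ids:
            params = config.terms[term_id]
            lam = params.loading
            eps = rng.standard_normal(n_admin)
            u = lam * z + np.sqrt(1.0 - lam * lam) * eps
            pu = ndtr(u)
            symptomatic = pu > 1.0 - params.prevalence
            if params.prevalence > 0:
                v = (pu - (1.0 - params.prevalence)) / params.prevalence
                v = np.clip(v, 1e-12, 1.0 - 1e-12)
            else:
                v = np.zeros(n_admin)
            term = library[term_id]
            for kind in sorted(term.attributes, key=lambda k: k.value):
                levels = np.zeros(n_admin, dtype=int)
                if kind is AttributeKind.PRESENCE:
                    levels[symptomatic] = 1
                else:
                    dist = params.attribute_dists.get(kind.value)
                    if dist is None:
                        raise GeneratorConfigError(
                            f"{term_id}: missing conditional distribution "
                            f"for {kind.value!r}"
                        )
                    if config.coupling == "independent":
                        vv = rng.random(n_admin)
                    else:
                        vv = v
                    levels[symptomatic] = _levels_from_uniform(
                        dist, vv[symptomatic]
                    )
                out_patient.append(patients)
                out_tp.append(tps)
                out_term.append(np.repeat(term_id, n_admin))
                out_attr.append(np.repeat(kind.value, n_admin))
                out_level.append(levels)

    frame = pd.DataFrame(
        {
            "patient_id": np.concatenate(out_patient),
            "timepoint": np.concatenate(out_tp),
            "term_id": np.concatenate(out_term),
            "attribute": np.concatenate(out_attr),
            "level": np.concatenate(out_level),
        }
    )
    frame = frame.sort_values(
        ["patient_id", "timepoint", "term_id", "attribute"], kind="mergesort"
    ).reset_index(drop=True)
    return ResponseDataset(
        frame=frame, library=library, timepoints=tuple(timepoints)
    )


def simulate_physician_panel(
    config: PanelConfig,
    terms: Iterable[str],
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one ordinal impact rating per respondent per term."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    term_list = sorted(terms)
    rows = []
    for term_id in term_list:
        dist = config.impact_dists.get(term_id)
        if dist is None:
            raise GeneratorConfigError(
                f"no impact distribution for term {term_id!r}"
            )
        levels = rng.choice(5, size=config.n_respondents, p=dist)
        for r, level in enumerate(levels):
            rows.append(
                {
                    "respondent_id": f"R{r + 1:02d}",
                    "term_id": term_id,
                    "impact": int(level),
                }
            )
    frame = pd.DataFrame(rows, columns=["respondent_id", "term_id", "impact"])
    return frame.sort_values(
        ["term_id", "respondent_id"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# closed-form marginals and population reliability
# ---------------------------------------------------------------------------

def analytic_marginals(
    config: GeneratorConfig, library: TermLibrary | None = None
) -> ScoreTable:
    """Expected score table implied by the config, in closed form.

    Expected prevalence is ``pi_t``; each attribute's expected proportion
    score is the conditional mass at/above the cut level.  An attribute
    score with ``pi_t == 0`` is undefined (0/0), mirroring the sample
    statistic.
    """
    library = library or load_full_library()
    values: dict[str, dict[str, float | None]] = {}
    for term_id, params in config.terms.items():
        term = library[term_id]
        cells: dict[str, float | None] = {"prevalence": params.prevalence}
        for kind in ORDINAL_KINDS:
            if kind in term.attributes:
                if params.prevalence == 0:
                    cells[kind.value] = None
                else:
                    dist = params.attribute_dists[kind.value]
                    cells[kind.value] = float(sum(dist[CUT_LEVEL - 1:]))
        values[term_id] = cells
    return ScoreTable.from_values(values)


def composite_level_pmf(
    params: TermParams, term_attributes: frozenset[AttributeKind]
) -> np.ndarray:
    """Distribution of the max-rule composite score (levels 0..4).

    With comonotone attributes the composite given symptomatic is
    ``max_j F_j^{-1}(v)`` for one uniform ``v``, so
    ``P(comp >= a | symptomatic) = 1 - min_j F_j(a - 1)``.
    Presence-only terms have composite in {0, 1}.
    """
    pi = params.prevalence
    pmf = np.zeros(5)
    pmf[0] = 1.0 - pi
    if pi == 0:
        return pmf
    if term_attributes == frozenset({AttributeKind.PRESENCE}):
        pmf[1] = pi
        return pmf
    cdfs = []
    for kind in term_attributes:
        dist = params.attribute_dists[kind.value]
        cdfs.append(np.concatenate([[0.0], np.cumsum(dist)]))  # F(0..4)
    cdfs = np.array(cdfs)
    surv = 1.0 - cdfs.min(axis=0)  # P(comp >= a | sympt) at a-1 index shift
    # surv[a-1] corresponds to P(comp >= a | sympt) for a = 1..4
    cond = np.zeros(5)
    for a in range(1, 5):
        upper = surv[a] if a < 4 else 0.0
        cond[a] = surv[a - 1] - upper
    pmf[1:] = pi * cond[1:]
    return pmf


def _survival_thresholds(pmf: np.ndarray) -> np.ndarray:
    """Latent thresholds c_a with P(u >= c_a) = P(comp >= a), a = 1..4."""
    surv = pmf[::-1].cumsum()[::-1]  # P(comp >= a) for a = 0..4
    c = np.full(4, np.inf)
    for a in range(1, 5):
        s = surv[a]
        if s <= 0:
            c[a - 1] = np.inf
        elif s >= 1:
            c[a - 1] = -np.inf
        else:
            c[a - 1] = ndtri(1.0 - s)
    return c


def _bvn_survival(x: float, y: float, rho: float) -> float:
    """P(U1 > x, U2 > y) for standard bivariate normal with corr rho."""
    if np.isinf(x) or np.isinf(y):
        if x == np.inf or y == np.inf:
            return 0.0
    px = 1.0 - ndtr(x) if not np.isinf(x) else (1.0 if x == -np.inf else 0.0)
    py = 1.0 - ndtr(y) if not np.isinf(y) else (1.0 if y == -np.inf else 0.0)
    if x == -np.inf:
        return py
    if y == -np.inf:
        return px
    cdf = multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
    ).cdf([x, y])
    return float(1.0 - (1.0 - px) - (1.0 - py) + cdf)


def population_domain_cov(
    config: GeneratorConfig,
    library: TermLibrary,
    term_ids: Sequence[str],
) -> np.ndarray:
    """Population covariance matrix of composite scores for ``term_ids``.

    Uses ``E[X] = sum_a P(X >= a)`` and ``E[X_s X_t] = sum_a sum_b
    P(X_s >= a, X_t >= b)`` with the joint survival evaluated under the
    Gaussian copula correlation ``lambda_s * lambda_t``.
    """
    k = len(term_ids)
    pmfs, thresholds, means, loadings = [], [], [], []
    for term_id in term_ids:
        params = config.terms[term_id]
        pmf = composite_level_pmf(params, library[term_id].attributes)
        pmfs.append(pmf)
        thresholds.append(_survival_thresholds(pmf))
        levels = np.arange(5)
        means.append(float((pmf * levels).sum()))
        loadings.append(params.loading)
    cov = np.zeros((k, k))
    for i in range(k):
        pmf = pmfs[i]
        second = float((pmf * np.arange(5) ** 2).sum())
        cov[i, i] = second - means[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            rho = loadings[i] * loadings[j]
            exy = 0.0
            for a in range(4):
                for b in range(4):
                    exy += _bvn_survival(
                        thresholds[i][a], thresholds[j][b], rho
                    )
            c = exy - means[i] * means[j]
            cov[i, j] = cov[j, i] = c
    return cov


def population_alpha(cov: np.ndarray) -> float:
    k = cov.shape[0]
    total = cov.sum()
    return float(k / (k - 1) * (1.0 - np.trace(cov) / total))


def population_loo_percent_change(cov: np.ndarray) -> np.ndarray:
    """Population leave-one-out percent changes for a covariance matrix."""
    k = cov.shape[0]
    alpha_full = population_alpha(cov)
    out = np.empty(k)
    for i in range(k):
        keep = [j for j in range(k) if j != i]
        sub = cov[np.ix_(keep, keep)]
        out[i] = (population_alpha(sub) - alpha_full) / alpha_full * 100.0
    return out


def tune_loading_for_null_removal(
    config: GeneratorConfig,
    library: TermLibrary,
    domain_terms: Sequence[str],
    target: str,
    lo: float = 0.0,
    hi: float = 0.9,
) -> float:
    """Loading for ``target`` making its removal reliability-neutral.

    Removing an item uncorrelated with its domain raises alpha; removing
    one as correlated as its neighbours lowers it.  In between there is a
    loading at which removing the target leaves the domain's population
    alpha unchanged — the fixed point the reliability step is designed to
    find.  Solved by bisection on the population covariance.
    """
    idx = list(domain_terms).index(target)
    k = len(domain_terms)
    pmfs, thresholds, means, loadings = [], [], [], []
    for term_id in domain_terms:
        params = config.terms[term_id]
        pmf = composite_level_pmf(params, library[term_id].attributes)
        pmfs.append(pmf)
        thresholds.append(_survival_thresholds(pmf))
        means.append(float((pmf * np.arange(5)).sum()))
        loadings.append(params.loading)
    base = population_domain_cov(config, library, domain_terms)
    keep = [j for j in range(k) if j != idx]

    def delta(mu: float) -> float:
        cov = base.copy()
        for j in keep:
            rho = mu * loadings[j]
            exy = sum(
                _bvn_survival(thresholds[idx][a], thresholds[j][b], rho)
                for a in range(4)
                for b in range(4)
            )
            c = exy - means[idx] * means[j]
            cov[idx, j] = cov[j, idx] = c
        return population_alpha(cov[np.ix_(keep, keep)]) - population_alpha(cov)

    f_lo, f_hi = delta(lo), delta(hi)
    if f_lo * f_hi > 0:
        # no sign change: fall back to the end closer to neutrality
        return lo if abs(f_lo) < abs(f_hi) else hi
    return float(brentq(delta, lo, hi, xtol=1e-4))


# ---------------------------------------------------------------------------
# study-like fixture
# ---------------------------------------------------------------------------

#: conditional level distributions used by the study-like fixture: the
#: "low" profile fails the 25% cut with a wide margin, the "high" profile
#: passes it with a wide margin
_LOW_DIST = (0.92, 0.05, 0.02, 0.01)   # score 0.08
_HIGH_DIST = (0.45, 0.30, 0.15, 0.10)  # score 0.55

_PREV_LOW = 0.015   # eliminated at the 5% prevalence step
_PREV_HIGH = 0.30   # comfortably retained

_IMPACT_LOW = (0.60, 0.39, 0.01, 0.0, 0.0)   # P(>= moderate) = 0.01
_IMPACT_HIGH = (0.0, 0.01, 0.60, 0.30, 0.09)  # P(>= moderate) = 0.99

_DEFAULT_LOADING = 0.7
#: presence-only composites are binary and attenuate copula correlation
#: more than 5-level composites, so they get a stronger loading to keep
#: their leave-one-out effect comparable
_PRESENCE_LOADING = 0.85


@dataclass(frozen=True)
class StudyLikeFixture:
    """A packaged configuration whose analytic marginals drive the
    pipeline to the published elimination ledger."""

    config: GeneratorConfig
    panel_config: PanelConfig
    library: TermLibrary


def _base_loading(library: TermLibrary, term_id: str) -> float:
    return (
        _PRESENCE_LOADING if library[term_id].presence_only else _DEFAULT_LOADING
    )


def _study_like_margins() -> dict[str, dict]:
    """Per-term margin assignments replaying the published ledger."""
    from . import study

    library = load_full_library()
    severity_low = set(study.SEVERITY_ELIMINATED)
    # published low interference/frequency values, whether or not the term
    # was still in play when that step ran
    interference_low = set(study.INTERFERENCE_ELIMINATED) | set(
        study.INTERFERENCE_PUBLISHED_OTHER
    )
    frequency_low = {"urinary_urgency", "nosebleed"}
    amount_low = set(study.AMOUNT_ELIMINATED)
    prevalence_low = set(study.PREVALENCE_ELIMINATED)

    margins: dict[str, dict] = {}
    for term in library:
        dists: dict[str, tuple[float, ...]] = {}
        for kind in ORDINAL_KINDS:
            if kind not in term.attributes:
                continue
            low = {
                "severity": term.term_id in severity_low,
                "interference": term.term_id in interference_low,
                "frequency": term.term_id in frequency_low,
                "amount": term.term_id in amount_low,
            }[kind.value]
            dists[kind.value] = _LOW_DIST if low else _HIGH_DIST
        margins[term.term_id] = {
            "prevalence": _PREV_LOW if term.term_id in prevalence_low else _PREV_HIGH,
            "attribute_dists": dists,
        }
    return margins


@lru_cache(maxsize=1)
def _tuned_loadings() -> dict[str, float]:
    """Loadings for the designated reliability-removal terms.

    Each is solved so that, within the working set the reliability step
    will see, removing the designated term leaves the population domain
    alpha unchanged while removing any other term changes it materially.
    """
    from . import study

    library = load_full_library()
    margins = _study_like_margins()
    base_terms = {
        t: TermParams(loading=_base_loading(library, t), **spec)
        for t, spec in margins.items()
    }
    cfg = GeneratorConfig(n_patients=10, terms=base_terms)
    # working set when the reliability step runs: survivors of steps 1-5
    scores = analytic_marginals(cfg, library)
    from .tailoring import TailoringConfig, _threshold_steps

    _, working = _threshold_steps(scores, library, TailoringConfig())
    by_domain: dict[str, list[str]] = {}
    for term_id in working:
        by_domain.setdefault(library.domain_of(term_id), []).append(term_id)
    tuned: dict[str, float] = {}
    for target in study.RELIABILITY_REMOVED:
        domain = library.domain_of(target)
        terms = sorted(by_domain[domain])
        tuned[target] = tune_loading_for_null_removal(
            cfg, library, terms, target
        )
    return tuned


def study_like_fixture(
    n_patients: int = 219, seed: int = 0
) -> StudyLikeFixture:
    """Generator + panel configuration emulating the development study.

    The marginal parameters are synthetic: they are chosen so each term
    sits on the published side of each elimination threshold with a wide
    margin (the study's exact per-term values are not reproducible
    without its raw data), so at sufficient sample size the pipeline's
    ledger reproduces the published per-step elimination lists.
    """
    from . import study

    library = load_full_library()
    margins = _study_like_margins()
    tuned = _tuned_loadings()
    terms = {
        t: TermParams(
            loading=tuned.get(t, _base_loading(library, t)), **spec
        )
        for t, spec in margins.items()
    }
    config = GeneratorConfig(n_patients=n_patients, terms=terms, seed=seed)
    impact_low = set(study.IMPACT_ELIMINATED)
    panel = PanelConfig(
        n_respondents=study.PANEL_SIZE,
        impact_dists={
            t: (_IMPACT_LOW if t in impact_low else _IMPACT_HIGH)
            for t in library.term_ids
        },
        seed=seed,
    )
    return StudyLikeFixture(config=config, panel_config=panel, library=library)
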