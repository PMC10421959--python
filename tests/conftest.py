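import numpy as np
import pandas as pd
import pytest

from protailor import study
from protailor.response_data import PooledResponses, pool_timepoints
from protailor.scoring import impact_table
from protailor.synthetic_data import (
    simulate_physician_panel,
    simulate_survey_data,
    study_like_fixture,
)
from protailor.term_library import (
    AttributeKind,
    Term,
    TermLibrary,
    load_full_library,
)


@pytest.fixture(scope="session")
def full_library():
    return load_full_library()


@pytest.fixture(scope="session")
def tiny_library():
    """Two domains, four terms: one per attribute pattern of interest."""
    S = AttributeKind.SEVERITY
    I = AttributeKind.INTERFERENCE
    P = AttributeKind.PRESENCE
    F = AttributeKind.FREQUENCY
    return TermLibrary(
        [
            Term("ache", "Ache", "dom_a", frozenset({S, I, F})),
            Term("itch", "Itch", "dom_a", frozenset({S})),
            Term("spots", "Spots", "dom_a", frozenset({P})),
            Term("worry", "Worry", "dom_b", frozenset({S, I})),
        ]
    )


def make_pooled(library, rows):
    """Build a PooledResponses from (admin, term, attribute, level) tuples."""
    frame = pd.DataFrame(
        rows, columns=["admin_id", "term_id", "attribute", "level"]
    )
    frame.insert(0, "patient_id", frame["admin_id"])
    frame.insert(1, "timepoint", "baseline")
    return PooledResponses(
        frame=frame,
        library=library,
        n_surveys=frame["admin_id"].nunique(),
    )


@pytest.fixture(scope="session")
def study_sim():
    """One large study-like cohort shared across simulation-facing tests.

    n_patients=800 gives ~1900 pooled administrations: large enough for
    the generator's analytic marginals to pin every term to the intended
    side of each elimination threshold.
    """
    fixture = study_like_fixture(n_patients=800, seed=20260926 % 2**31)
    dataset = simulate_survey_data(fixture.config, fixture.library, seed=101)
    panel = simulate_physician_panel(
        fixture.panel_config, fixture.library.term_ids, seed=102
    )
    return fixture, dataset, panel


@pytest.fixture(scope="session")
def study_sim_pooled(study_sim):
    _, dataset, _ = study_sim
    return pool_timepoints(dataset)
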