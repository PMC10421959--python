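import pytest
from hypothesis import given, settings, strategies as st

from protailor import study
from protailor.scoring import ScoreTable, impact_table
from protailor.tailoring import (
    EliminationLedger,
    LedgerIntegrityError,
    LedgerStep,
    TailoringConfig,
    apply_threshold_filter,
    build_report,
    run_patient_steps_from_scores,
    run_physician_step,
)
from protailor.term_library import UnknownTermError


@pytest.fixture(scope="module")
def reference_scores(full_library):
    return study.reference_score_table(full_library)


def replay(full_library, config=None):
    config = config or TailoringConfig(
        reintroduction_terms=study.REINTRODUCED
    )
    ledger, working = run_patient_steps_from_scores(
        study.reference_score_table(full_library),
        full_library,
        config,
        reliability_removals=study.RELIABILITY_REMOVED,
    )
    final = run_physician_step(
        working,
        study.reference_impact_table(full_library),
        config,
        ledger,
        full_library,
    )
    return ledger, final


class TestThresholdFilter:
    def test_nothing_eliminated_when_all_pass(self, tiny_library):
        scores = ScoreTable.from_values(
            {"ache": {"severity": 0.5}, "itch": {"severity": 0.9}}
        )
        eliminated, retained, carried = apply_threshold_filter(
            scores, ["ache", "itch"], "severity", 0.25, tiny_library
        )
        assert eliminated == {}
        assert retained == ["ache", "itch"]

    def test_exactly_at_threshold_is_retained(self, tiny_library):
        scores = ScoreTable.from_values({"ache": {"severity": 0.25}})
        eliminated, retained, _ = apply_threshold_filter(
            scores, ["ache"], "severity", 0.25, tiny_library
        )
        assert eliminated == {} and retained == ["ache"]

    def test_term_without_metric_is_carried_forward(self, tiny_library):
        # presence-only 'spots' has no severity question
        scores = ScoreTable.from_values(
            {"spots": {"prevalence": 0.5}, "itch": {"severity": 0.1}}
        )
        eliminated, retained, carried = apply_threshold_filter(
            scores, ["spots", "itch"], "severity", 0.25, tiny_library
        )
        assert "spots" in retained and "spots" in carried
        assert eliminated == {"itch": 0.1}

    def test_undefined_attribute_score_carried_forward(self, tiny_library):
        scores = ScoreTable.from_values({"itch": {"severity": None}})
        eliminated, retained, carried = apply_threshold_filter(
            scores, ["itch"], "severity", 0.25, tiny_library
        )
        assert eliminated == {} and carried == ["itch"]

    def test_undefined_prevalence_means_never_administered(self, tiny_library):
        scores = ScoreTable.from_values({"itch": {"prevalence": None}})
        eliminated, retained, _ = apply_threshold_filter(
            scores, ["itch"], "prevalence", 0.05, tiny_library
        )
        assert eliminated == {"itch": None} and retained == []

    def test_printed_prevalence_fixture_eliminates_18_terms(
        self, full_library, reference_scores
    ):
        eliminated, retained, _ = apply_threshold_filter(
            reference_scores,
            list(full_library.term_ids),
            "prevalence",
            0.05,
            full_library,
        )
        assert set(eliminated) == set(study.PREVALENCE_ELIMINATED)
        assert len(retained) == 62

    @settings(deadline=None, max_examples=40)
    @given(
        thresholds=st.tuples(
            st.floats(0.01, 0.99), st.floats(0.01, 0.99)
        ).map(sorted)
    )
    def test_raising_threshold_never_shrinks_elimination(
        self, full_library, reference_scores, thresholds
    ):
        low, high = thresholds
        elim_low, _, _ = apply_threshold_filter(
            reference_scores, list(full_library.term_ids), "severity",
            low, full_library,
        )
        elim_high, _, _ = apply_threshold_filter(
            reference_scores, list(full_library.term_ids), "severity",
            high, full_library,
        )
        assert set(elim_low) <= set(elim_high)


class TestLedgerReplay:
    def test_reference_survivor_counts(self, full_library):
        ledger, final = replay(full_library)
        assert ledger.survivor_counts() == study.EXPECTED_SURVIVOR_COUNTS

    def test_per_step_eliminations_match_reference_lists(self, full_library):
        ledger, _ = replay(full_library)
        by_name = {s.name: s for s in ledger.steps}
        assert set(by_name["prevalence"].eliminated) == set(
            study.PREVALENCE_ELIMINATED
        )
        assert set(by_name["severity"].eliminated) == set(
            study.SEVERITY_ELIMINATED
        )
        assert set(by_name["interference"].eliminated) == set(
            study.INTERFERENCE_ELIMINATED
        )
        assert by_name["frequency"].eliminated == {}
        assert set(by_name["amount"].eliminated) == {"hair_loss"}
        assert set(by_name["reliability"].eliminated) == set(
            study.RELIABILITY_REMOVED
        )
        assert set(by_name["impact"].eliminated) == set(study.IMPACT_ELIMINATED)
        assert by_name["impact"].reintroduced == tuple(
            sorted(study.REINTRODUCED)
        )

    def test_frequency_step_eliminates_no_new_terms(self, full_library):
        # both sub-threshold frequency terms were removed at earlier steps
        ledger, _ = replay(full_library)
        by_name = {s.name: s for s in ledger.steps}
        assert by_name["frequency"].n_survivors == by_name[
            "interference"
        ].n_survivors

    def test_final_survey_30_terms_58_items_11_domains(self, full_library):
        ledger, final = replay(full_library)
        survey, report = build_report(ledger, final, full_library)
        assert survey.terms == study.FINAL_TERMS
        assert survey.max_item_count == 58
        assert survey.domain_count == 11
        assert "Final tailored survey" in report

    def test_carry_forward_flags_only_terms_lacking_the_attribute(
        self, full_library
    ):
        ledger, _ = replay(full_library)
        for step in ledger.steps:
            if step.name in ("reliability", "impact"):
                continue
            for term_id in step.carried_forward:
                assert step.metric not in [
                    k.value for k in full_library[term_id].attributes
                ]

    def test_zero_thresholds_eliminate_nothing(self, full_library):
        config = TailoringConfig(
            prevalence_threshold=1e-9,
            proportion_score_threshold=1e-9,
            impact_threshold=1e-9,
        )
        ledger, working = run_patient_steps_from_scores(
            study.reference_score_table(full_library), full_library, config
        )
        assert len(working) == 80


class TestPhysicianStep:
    def test_all_passing_with_no_reintroduction_is_identity(
        self, full_library
    ):
        config = TailoringConfig()
        ledger = EliminationLedger(library_size=len(full_library))
        working = ("nausea", "fatigue")
        impacts = ScoreTable.from_values(
            {"nausea": {"impact": 0.5}, "fatigue": {"impact": 0.9}}
        )
        final = run_physician_step(
            working, impacts, config, ledger, full_library
        )
        assert final == ("fatigue", "nausea")

    def test_reference_13_removed_6_reintroduced_30_final(self, full_library):
        _, final = replay(full_library)
        assert len(final) == 30
        assert set(study.REINTRODUCED) <= set(final)

    def test_reintroducing_never_eliminated_term_errors(self, full_library):
        config = TailoringConfig(reintroduction_terms=("nausea",))
        ledger = EliminationLedger(library_size=len(full_library))
        impacts = ScoreTable.from_values({"fatigue": {"impact": 0.9}})
        with pytest.raises(LedgerIntegrityError):
            run_physician_step(
                ("fatigue",), impacts, config, ledger, full_library
            )

    def test_reintroducing_unknown_term_errors(self, full_library):
        config = TailoringConfig(reintroduction_terms=("not_a_term",))
        ledger = EliminationLedger(library_size=len(full_library))
        impacts = ScoreTable.from_values({"fatigue": {"impact": 0.9}})
        with pytest.raises(UnknownTermError):
            run_physician_step(
                ("fatigue",), impacts, config, ledger, full_library
            )


class TestLedgerIntegrity:
    def test_conservation_holds_on_reference_replay(self, full_library):
        ledger, _ = replay(full_library)
        ledger.check_conservation()  # must not raise
        n_elim = sum(len(s.eliminated) for s in ledger.steps)
        n_reintro = sum(len(s.reintroduced) for s in ledger.steps)
        assert 80 - n_elim + n_reintro == 30

    def test_no_term_eliminated_twice(self, full_library):
        ledger, _ = replay(full_library)
        seen = set()
        for step in ledger.steps:
            assert not (set(step.eliminated) & seen)
            seen |= set(step.eliminated)

    def test_broken_conservation_refuses_to_render(self, full_library):
        ledger = EliminationLedger(library_size=80)
        ledger.record(
            LedgerStep(
                name="prevalence",
                metric="prevalence",
                threshold=0.05,
                eliminated={"hives": 0.01},
                carried_forward=(),
                reintroduced=(),
                survivors=("nausea",),  # wrong count on purpose
            )
        )
        with pytest.raises(LedgerIntegrityError):
            build_report(ledger, ("nausea",), full_library)

    def test_replay_is_deterministic(self, full_library):
        first = replay(full_library)[0].to_dict()
        second = replay(full_library)[0].to_dict()
        assert first == second

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_conservation_on_random_score_tables(self, full_library, seed):
        """Whatever the scores, the ledger's bookkeeping must balance."""
        import numpy as np

        rng = np.random.default_rng(seed)
        values = {}
        for term in full_library:
            cells = {"prevalence": float(rng.random())}
            for kind in term.attributes:
                if kind.value != "presence":
                    cells[kind.value] = float(rng.random())
            values[term.term_id] = cells
        scores = ScoreTable.from_values(values)
        config = TailoringConfig()
        ledger, working = run_patient_steps_from_scores(
            scores, full_library, config
        )
        impacts = ScoreTable.from_values(
            {t: {"impact": float(rng.random())} for t in working}
        )
        final = run_physician_step(
            working, impacts, config, ledger, full_library
        )
        ledger.check_conservation()
        assert len(ledger.eliminated_terms()) == 80 - len(final)
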