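import io

import numpy as np
import pandas as pd
import pytest

from protailor.reliability import cronbach_alpha, composite_item_scores
from protailor.response_data import pool_timepoints, write_responses
from protailor.scoring import impact_proportion_score, prevalence
from protailor.synthetic_data import (
    GeneratorConfig,
    GeneratorConfigError,
    PanelConfig,
    TermParams,
    analytic_marginals,
    composite_level_pmf,
    population_alpha,
    population_domain_cov,
    population_loo_percent_change,
    simulate_physician_panel,
    simulate_survey_data,
    study_like_fixture,
)
from protailor.term_library import AttributeKind


def one_domain_config(n_patients, loading, prevalence_=0.5):
    terms = {
        t: TermParams(
            prevalence=prevalence_,
            attribute_dists={"severity": (0.4, 0.3, 0.2, 0.1)},
            loading=loading,
        )
        for t in ("acne", "itching", "skin_dryness", "hand_foot_syndrome")
    }
    return GeneratorConfig(
        n_patients=n_patients, terms=terms, retention=(1.0, 1.0, 1.0)
    )


class TestConfigValidation:
    def test_invalid_probabilities_rejected(self):
        with pytest.raises(GeneratorConfigError):
            TermParams(prevalence=1.2)
        with pytest.raises(GeneratorConfigError):
            TermParams(
                prevalence=0.5, attribute_dists={"severity": (0.5, 0.5, 0.5, 0.5)}
            )
        with pytest.raises(GeneratorConfigError):
            TermParams(prevalence=0.5, loading=1.0)

    def test_panel_distribution_must_normalize(self):
        with pytest.raises(GeneratorConfigError):
            PanelConfig(n_respondents=9, impact_dists={"x": (1, 1, 0, 0, 0)})

    def test_yaml_round_trip(self, tmp_path):
        config = one_domain_config(10, 0.5)
        path = tmp_path / "gen.yaml"
        config.to_yaml(path)
        again = GeneratorConfig.from_yaml(path)
        assert again.to_dict() == config.to_dict()


class TestSimulateSurveyData:
    def test_seeded_determinism_byte_identical(self, full_library, tmp_path):
        config = one_domain_config(30, 0.6)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_responses(simulate_survey_data(config, full_library, seed=9), a)
        write_responses(simulate_survey_data(config, full_library, seed=9), b)
        assert a.read_bytes() == b.read_bytes()
        c = tmp_path / "c.csv"
        write_responses(simulate_survey_data(config, full_library, seed=10), c)
        assert a.read_bytes() != c.read_bytes()

    def test_zero_prevalence_means_all_null_responses(self, full_library):
        config = one_domain_config(25, 0.6, prevalence_=0.0)
        ds = simulate_survey_data(config, full_library, seed=1)
        assert (ds.frame["level"] == 0).all()
        pooled = pool_timepoints(ds)
        assert prevalence(pooled, "acne").value == 0.0

    def test_marginal_prevalence_recovered_within_3_se(self, full_library):
        config = one_domain_config(700, 0.6)  # ~2100 pooled surveys
        ds = simulate_survey_data(config, full_library, seed=2)
        pooled = pool_timepoints(ds)
        for term in config.terms:
            score = prevalence(pooled, term)
            se = np.sqrt(0.25 / score.denominator)
            assert abs(score.value - 0.5) < 3 * se

    def test_expected_attrition_pattern(self, full_library):
        fixture = study_like_fixture(n_patients=219, seed=0)
        ds = simulate_survey_data(fixture.config, full_library, seed=3)
        counts = ds.administration_counts()
        assert counts["baseline"] == 219
        # binomial(219, 191/219) and binomial(219, 118/219): +-3 SD bands
        assert 175 <= counts["mid_cycle_1"] <= 207
        assert 96 <= counts["mid_cycle_2"] <= 140

    def test_zero_loading_gives_near_zero_alpha(self, full_library):
        config = one_domain_config(700, 0.0)
        ds = simulate_survey_data(config, full_library, seed=4)
        pooled = pool_timepoints(ds)
        matrix = composite_item_scores(
            pooled, full_library, "cutaneous", terms=sorted(config.terms)
        )
        alpha = cronbach_alpha(matrix)
        assert abs(alpha) < 0.1

    def test_alpha_increases_with_domain_loading(self, full_library):
        alphas = []
        for loading in (0.0, 0.45, 0.8):
            config = one_domain_config(400, loading)
            ds = simulate_survey_data(config, full_library, seed=5)
            pooled = pool_timepoints(ds)
            matrix = composite_item_scores(
                pooled, full_library, "cutaneous", terms=sorted(config.terms)
            )
            alphas.append(cronbach_alpha(matrix))
        assert alphas[0] < alphas[1] < alphas[2]


class TestAnalyticMarginals:
    def test_attribute_score_is_mass_above_cut(self):
        config = GeneratorConfig(
            n_patients=5,
            terms={
                "itching": TermParams(
                    prevalence=0.3,
                    attribute_dists={"severity": (0.6, 0.3, 0.1, 0.0)},
                )
            },
        )
        table = analytic_marginals(config)
        assert table.value("itching", "prevalence") == pytest.approx(0.3)
        assert table.value("itching", "severity") == pytest.approx(0.4)

    def test_sub_threshold_prevalence_flagged_for_elimination(self):
        config = GeneratorConfig(
            n_patients=5,
            terms={"rash": TermParams(prevalence=0.04)},
        )
        assert analytic_marginals(config).value("rash", "prevalence") < 0.05

    def test_composite_pmf_sums_to_one_and_matches_simulation(
        self, full_library
    ):
        params = TermParams(
            prevalence=0.4,
            attribute_dists={
                "severity": (0.5, 0.3, 0.15, 0.05),
                "interference": (0.7, 0.2, 0.08, 0.02),
            },
            loading=0.0,
        )
        pmf = composite_level_pmf(
            params, full_library["mouth_throat_sores"].attributes
        )
        assert pmf.sum() == pytest.approx(1.0)
        config = GeneratorConfig(
            n_patients=4000,
            terms={"mouth_throat_sores": params},
            retention=(1.0, 0.0, 0.0),
        )
        ds = simulate_survey_data(config, full_library, seed=6)
        pooled = pool_timepoints(ds)
        matrix = composite_item_scores(
            pooled, full_library, "oral", terms=["mouth_throat_sores"]
        )
        observed = (
            matrix["mouth_throat_sores"].value_counts(normalize=True).sort_index()
        )
        for level, p in enumerate(pmf):
            obs = float(observed.get(float(level), 0.0))
            se = np.sqrt(max(p * (1 - p), 1e-6) / 4000)
            assert abs(obs - p) < 4 * se


class TestPopulationReliability:
    def test_population_alpha_matches_large_simulation(self, full_library):
        config = one_domain_config(3000, 0.7)
        terms = sorted(config.terms)
        cov = population_domain_cov(config, full_library, terms)
        expected = population_alpha(cov)
        ds = simulate_survey_data(config, full_library, seed=8)
        pooled = pool_timepoints(ds)
        matrix = composite_item_scores(
            pooled, full_library, "cutaneous", terms=terms
        )
        assert cronbach_alpha(matrix) == pytest.approx(expected, abs=0.03)

    def test_tuned_fixture_population_argmin_is_designated_term(
        self, full_library
    ):
        from protailor import study
        from protailor.tailoring import TailoringConfig, _threshold_steps

        fixture = study_like_fixture()
        scores = analytic_marginals(fixture.config, full_library)
        _, working = _threshold_steps(
            scores, full_library, TailoringConfig()
        )
        by_domain = {}
        for t in working:
            by_domain.setdefault(full_library.domain_of(t), []).append(t)
        for target in study.RELIABILITY_REMOVED:
            domain = full_library.domain_of(target)
            terms = sorted(by_domain[domain])
            cov = population_domain_cov(fixture.config, full_library, terms)
            pcs = population_loo_percent_change(cov)
            assert terms[int(np.argmin(np.abs(pcs)))] == target


class TestPhysicianPanel:
    def test_degenerate_none_distribution_scores_zero(self):
        config = PanelConfig(
            n_respondents=9, impact_dists={"x": (1.0, 0, 0, 0, 0)}
        )
        panel = simulate_physician_panel(config, ["x"], seed=0)
        assert impact_proportion_score(panel, "x").value == 0.0

    def test_nine_respondents_give_ninth_multiples(self):
        config = PanelConfig(
            n_respondents=9, impact_dists={"x": (0.2, 0.2, 0.3, 0.2, 0.1)}
        )
        panel = simulate_physician_panel(config, ["x"], seed=1)
        value = impact_proportion_score(panel, "x").value
        assert value * 9 == pytest.approx(round(value * 9))

    def test_long_run_mean_matches_binomial_expectation(self):
        config = PanelConfig(
            n_respondents=9, impact_dists={"x": (0.0, 8 / 9, 1 / 9, 0.0, 0.0)}
        )
        values = []
        for seed in range(300):
            panel = simulate_physician_panel(config, ["x"], seed=seed)
            values.append(impact_proportion_score(panel, "x").value)
        se = np.sqrt((1 / 9) * (8 / 9) / (9 * 300))
        assert abs(np.mean(values) - 1 / 9) < 3 * se

    def test_seeded_determinism(self):
        config = PanelConfig(
            n_respondents=9, impact_dists={"x": (0.2, 0.2, 0.3, 0.2, 0.1)}
        )
        a = simulate_physician_panel(config, ["x"], seed=3)
        b = simulate_physician_panel(config, ["x"], seed=3)
        pd.testing.assert_frame_equal(a, b)
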