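"""Screening overlay: schedules, tests, adherence, surveillance, full arms."""

import numpy as np
import pytest

from crcscreen import config
from crcscreen.natural_history import sample_latent_histories, simulate_cohort_no_screening
from crcscreen.screening import (
    AdherenceScenario,
    ConfigurationError,
    Strategy,
    TestPerformance,
    adherence_decision,
    colonoscopy_exam,
    fit_test,
    load_scenarios,
    load_strategies,
    null_scenario,
    run_strategy_arm,
    schedule_offers,
    surveillance_policy,
)


class TestSchedules:
    def test_biennial_fit_yields_sixteen_offers(self, strategies):
        offers = schedule_offers(strategies["FIT2y45"], config.MALE)
        assert len(offers) == 16
        assert offers[0][0] == 45.0 and offers[-1][0] == 75.0
        assert all(test == "fit" and mod == "fit_biennial" for _, test, mod in offers)

    def test_colonoscopy_only_strategy(self, strategies):
        offers = schedule_offers(strategies["COL10y45-3X"], config.FEMALE)
        assert [age for age, _, _ in offers] == [45.0, 55.0, 65.0]
        assert all(test == "colonoscopy" for _, test, _ in offers)

    def test_current_strategy_by_sex(self, strategies):
        male = schedule_offers(strategies["current"], config.MALE)
        assert [(a, t) for a, t, _ in male] == [(50.0, "colonoscopy"), (60.0, "colonoscopy")]
        female = schedule_offers(strategies["current"], config.FEMALE)
        fits = [a for a, t, _ in female if t == "fit"]
        cols = [a for a, t, _ in female if t == "colonoscopy"]
        assert fits == [50.0, 51.0, 52.0, 53.0, 54.0]
        assert cols == [55.0, 65.0]

    def test_fixture_file_contains_all_five_strategies(self, strategies):
        assert set(strategies) == {
            "current", "FIT1y45+COL10y50", "FIT1y45+COL10y50-3X", "FIT2y45",
            "COL10y45-3X",
        }

    def test_malformed_strategy_rejected(self):
        with pytest.raises(ConfigurationError, match="interval"):
            Strategy(
                name="bad", label="bad",
                blocks={"male": [{"test": "fit", "start": 45, "stop": 50, "interval": 0}],
                        "female": []},
            )
        with pytest.raises(ConfigurationError, match="ages"):
            Strategy(
                name="bad", label="bad",
                blocks={"male": [{"test": "colonoscopy", "ages": [15]}], "female": []},
            )


class TestFitTest:
    def test_false_positive_rate_is_one_minus_specificity(self, perf):
        rng = np.random.default_rng(3)
        n = 20_000
        hits = sum(fit_test([], perf, rng) for _ in range(n))
        p = 1 - perf.fit_specificity
        assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_cancer_detected_with_cancer_sensitivity(self, perf):
        rng = np.random.default_rng(5)
        n = 20_000
        hits = sum(fit_test(["non_aa", "cancer"], perf, rng) for _ in range(n))
        p = perf.fit_sens["cancer"]
        assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_most_advanced_state_governs(self, perf):
        rng = np.random.default_rng(7)
        n = 20_000
        hits = sum(fit_test(["non_crsp", "aa"], perf, rng) for _ in range(n))
        p = perf.fit_sens["aa"]
        assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_perfect_specificity_never_fires_on_clean_colon(self):
        perfect = TestPerformance(
            fit_sens=dict(config.FIT_SENSITIVITY), fit_specificity=1.0,
            col_sens=dict(config.COL_SENSITIVITY), col_specificity=1.0,
            complication_prob=0.0,
        )
        rng = np.random.default_rng(9)
        assert not any(fit_test([], perfect, rng) for _ in range(5000))


class TestColonoscopy:
    def test_advanced_adenoma_detection_rate(self, perf):
        rng = np.random.default_rng(11)
        n = 20_000
        hits = sum(bool(colonoscopy_exam(["aa"], perf, rng)[0]) for _ in range(n))
        p = perf.col_sens["aa"]
        assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_clean_colon_never_yields_findings(self, perf):
        rng = np.random.default_rng(13)
        for _ in range(2000):
            detected, cancer, _ = colonoscopy_exam([], perf, rng)
            assert not detected and not cancer

    def test_perfect_sensitivity_detects_everything(self):
        perfect = TestPerformance(
            fit_sens=dict(config.FIT_SENSITIVITY), fit_specificity=0.95,
            col_sens={k: 1.0 for k in config.COL_SENSITIVITY}, col_specificity=1.0,
            complication_prob=0.0,
        )
        rng = np.random.default_rng(15)
        states = ["non_aa", "aa", "crsp", "cancer"]
        detected, cancer, _ = colonoscopy_exam(states, perfect, rng)
        assert detected == [0, 1, 2, 3] and cancer


class TestAdherence:
    def test_perfect_scenario_attends_everything(self, scenarios):
        rng = np.random.default_rng(17)
        assert all(
            adherence_decision("fit_annual", config.MALE, scenarios[1], rng)
            for _ in range(100)
        )

    def test_current_biennial_fit_rate_for_men(self, scenarios):
        rng = np.random.default_rng(19)
        n = 20_000
        hits = sum(
            adherence_decision("fit_biennial", config.MALE, scenarios[2], rng)
            for _ in range(n)
        )
        assert abs(hits / n - 0.16) < 3 * np.sqrt(0.16 * 0.84 / n)

    def test_persistent_mode_reuses_first_decision(self, scenarios):
        scenario = AdherenceScenario(
            scenario_id=9, label="t", fit_annual={"male": 0.5, "female": 0.5},
            fit_biennial={"male": 0.5, "female": 0.5}, fit_positive_col=0.5,
            screening_col={"male": 0.5, "female": 0.5}, surveillance_col=0.5,
            mode="persistent",
        )
        rng = np.random.default_rng(21)
        cache = {}
        first = adherence_decision("fit_annual", config.MALE, scenario, rng, cache)
        assert all(
            adherence_decision("fit_annual", config.MALE, scenario, rng, cache) == first
            for _ in range(50)
        )

    def test_rates_must_be_probabilities(self):
        with pytest.raises(ConfigurationError):
            AdherenceScenario(
                scenario_id=9, label="t", fit_annual={"male": 1.5, "female": 0.5},
                fit_biennial={"male": 0.5, "female": 0.5}, fit_positive_col=0.5,
                screening_col={"male": 0.5, "female": 0.5}, surveillance_col=0.5,
            )


class TestSurveillancePolicy:
    @pytest.mark.parametrize(
        "n_adv, n_removed, expected",
        [
            (1, 1, 3.0),  # advanced lesion removed
            (0, 3, 3.0),  # three or more lesions
            (0, 2, 5.0),  # one or two non-advanced
            (0, 1, 5.0),
            (0, 0, None),  # clean exam: back to routine
        ],
    )
    def test_interval_table(self, n_adv, n_removed, expected):
        assert surveillance_policy(n_adv, n_removed) == expected


class TestStrategyArms:
    def test_zero_participation_equals_no_screening_exactly(
        self, central, life_table, perf, strategies
    ):
        n = 10_000
        latent = sample_latent_histories(n, central, life_table, seed=23)
        _, base = run_strategy_arm(
            n, central, None, null_scenario(), perf, life_table, seed=23, latent=latent
        )
        _, null = run_strategy_arm(
            n, central, strategies["COL10y45-3X"], null_scenario(), perf, life_table,
            seed=23, latent=latent,
        )
        for key in ("incidence", "mortality", "n_eligible"):
            assert null[key] == base[key]
        assert null["colonoscopies"] == 0.0
        # and both agree with the vectorised no-screening summary
        _, vec = simulate_cohort_no_screening(
            n, central, life_table, seed=23, histories=False
        )
        assert base["incidence"] == vec["incidence"]
        assert base["mortality"] == vec["mortality"]

    def test_perfect_adherence_colonoscopy_cuts_incidence(
        self, central, life_table, perf, strategies, scenarios
    ):
        n = 20_000
        latent = sample_latent_histories(n, central, life_table, seed=29)
        _, base = run_strategy_arm(
            n, central, None, scenarios[1], perf, life_table, seed=29, latent=latent
        )
        _, col = run_strategy_arm(
            n, central, strategies["COL10y45-3X"], scenarios[1], perf, life_table,
            seed=29, latent=latent,
        )
        assert col["incidence"] < base["incidence"]
        assert col["mortality"] < base["mortality"]

    def test_colonoscopy_count_decomposition(
        self, central, life_table, perf, strategies, scenarios
    ):
        n = 10_000
        _, s = run_strategy_arm(
            n, central, strategies["current"], scenarios[2], perf, life_table, seed=31
        )
        total = (
            s["colonoscopies_screening"]
            + s["colonoscopies_followup"]
            + s["colonoscopies_surveillance"]
        )
        assert total == pytest.approx(s["colonoscopies"], abs=1e-9)

    def test_fit_positivity_on_lesion_free_tests(
        self, central, life_table, perf, strategies, scenarios
    ):
        n = 20_000
        _, s = run_strategy_arm(
            n, central, strategies["FIT2y45"], scenarios[1], perf, life_table, seed=37
        )
        tests = s["fit_tests_lesion_free"]
        pos = s["fit_positives_lesion_free"]
        p = 1 - perf.fit_specificity
        se = np.sqrt(p * (1 - p) / tests)
        assert abs(pos / tests - p) < 2.58 * se  # 99% binomial CI

    def test_screening_histories_record_events(
        self, central, life_table, perf, strategies, scenarios
    ):
        histories, _ = run_strategy_arm(
            2000, central, strategies["COL10y45-3X"], scenarios[1], perf, life_table,
            seed=41,
        )
        some_cols = [h for h in histories if h.colonoscopies]
        assert some_cols
        for h in some_cols[:200]:
            ages = [c[0] for c in h.colonoscopies]
            assert ages == sorted(ages)
            assert all(a <= h.death_age for a in ages)
            if h.dx_age is not None:
                assert all(a <= h.dx_age for a in ages)

    def test_determinism_same_seed(self, central, life_table, perf, strategies, scenarios):
        args = (3000, central, strategies["current"], scenarios[2], perf, life_table)
        _, a = run_strategy_arm(*args, seed=43)
        _, b = run_strategy_arm(*args, seed=43)
        assert a == b
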