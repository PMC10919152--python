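"""Natural-history engine: onsets, progression, diagnosis, death, cohorts."""

import numpy as np
import pytest

from crcscreen import config
from crcscreen.natural_history import (
    LifeHistory,
    diagnose_symptomatic,
    progress_lesion,
    sample_deaths,
    sample_latent_histories,
    sample_lesion_onsets,
    simulate_cohort_no_screening,
)


class TestLesionOnsets:
    def test_zero_scale_means_no_lesions(self, central, life_table):
        p = central.replace(onset_rate_scale=0.0)
        cohort = sample_latent_histories(2000, p, life_table, seed=1)
        assert cohort.n_lesions == 0
        _, summary = simulate_cohort_no_screening(
            2000, p, life_table, seed=1, histories=False
        )
        assert summary["incidence"] == 0.0
        assert summary["mortality"] == 0.0

    def test_pure_adenoma_fraction(self, central, life_table):
        p = central.replace(adenoma_fraction=1.0)
        cohort = sample_latent_histories(2000, p, life_table, seed=2)
        assert (cohort.pathway == config.ADENOMA).all()

    def test_mean_onsets_match_nhpp_intensity_integral(self, central, life_table):
        # oracle: E[onsets] = scale * E[frailty] * sum(band hazard * width),
        # with E[frailty] = 1 by construction of the log-normal
        n = 50_000
        cohort = sample_latent_histories(n, central, life_table, seed=3)
        expected = central.onset_rate_scale * float(
            np.sum(config.BASE_ONSET_HAZARD * np.diff(config.ONSET_AGE_BANDS))
        )
        counts = np.diff(cohort.offsets)
        se = counts.std() / np.sqrt(n)
        assert abs(counts.mean() - expected) < 3 * se

    def test_scalar_sampler_agrees_with_intensity(self, central):
        rng = np.random.default_rng(5)
        totals = [
            len(sample_lesion_onsets(1.0, central, config.MALE, rng))
            for _ in range(4000)
        ]
        expected = central.onset_rate_scale * float(
            np.sum(config.BASE_ONSET_HAZARD * np.diff(config.ONSET_AGE_BANDS))
        )
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) < 3 * se
        with pytest.raises(ValueError):
            sample_lesion_onsets(0.0, central, config.MALE, rng)


class TestProgression:
    def test_dwell_means_match_configuration(self, central):
        rng = np.random.default_rng(7)
        for pathway, mean1 in (
            (config.ADENOMA, central.mean_dwell_nonadv_to_adv_adenoma),
            (config.SERRATED, central.mean_dwell_noncr_to_cr_sp),
        ):
            dwells = []
            for _ in range(10_000):
                t_adv, _ = progress_lesion(50.0, pathway, central, rng)
                if np.isfinite(t_adv):
                    dwells.append(t_adv - 50.0)
            dwells = np.asarray(dwells)
            # exponential: SE of the mean = mean / sqrt(n)
            assert abs(dwells.mean() - mean1) < 3 * mean1 / np.sqrt(len(dwells))
            frac = len(dwells) / 10_000
            assert frac == pytest.approx(config.PROGRESS_PROB_NONADV[pathway], abs=0.02)

    def test_serrated_dwell_slower_than_adenoma(self, central):
        assert (
            central.mean_dwell_noncr_to_cr_sp
            >= central.mean_dwell_nonadv_to_adv_adenoma
        )
        assert central.mean_dwell_cr_sp_to_crc >= central.mean_dwell_adv_adenoma_to_crc

    def test_zero_progression_probability_blocks_lesion(self, central, monkeypatch):
        monkeypatch.setattr(
            config, "PROGRESS_PROB_NONADV", {config.ADENOMA: 0.0, config.SERRATED: 0.0}
        )
        rng = np.random.default_rng(11)
        for _ in range(200):
            assert progress_lesion(40.0, config.ADENOMA, central, rng) == (
                np.inf,
                np.inf,
            )


class TestSymptomaticDiagnosis:
    def test_diagnosis_always_after_onset(self, central):
        rng = np.random.default_rng(13)
        ages = [diagnose_symptomatic(60.0, central, rng)[0] for _ in range(1000)]
        assert all(a > 60.0 for a in ages)
        near_zero = central.replace(mean_sojourn=1e-9)
        age, _ = diagnose_symptomatic(60.0, near_zero, rng)
        assert age == pytest.approx(60.0, abs=1e-6)

    def test_stage_frequencies_match_distribution(self, central):
        rng = np.random.default_rng(17)
        stages = np.array(
            [diagnose_symptomatic(60.0, central, rng)[1] for _ in range(20_000)]
        )
        for k in range(4):
            p = central.stage_dist_symptomatic[k]
            freq = (stages == k + 1).mean()
            se = np.sqrt(p * (1 - p) / len(stages))
            assert abs(freq - p) < 3 * se


class TestDeaths:
    def test_survival_matches_life_table_product_limit(self, life_table):
        n = 50_000
        rng = np.random.default_rng(19)
        sex = np.zeros(n, dtype=np.int8)  # all male
        deaths = sample_deaths(n, sex, life_table, rng)
        male = life_table[life_table.sex == "male"].sort_values("age")
        for age in (50, 70, 85):
            qx = male[(male.age >= 20) & (male.age < age)].qx.to_numpy()
            survival = float(np.prod(1 - qx))
            empirical = float((deaths >= age).mean())
            se = np.sqrt(survival * (1 - survival) / n)
            assert abs(empirical - survival) < 3 * se

    def test_life_table_gap_detected(self, life_table):
        broken = life_table[life_table.age != 47]
        with pytest.raises(ValueError, match="gap"):
            from crcscreen.config import load_life_table
            import io

            buf = io.StringIO()
            broken.to_csv(buf, index=False)
            buf.seek(0)
            load_life_table(buf)

    def test_stage4_shortens_survival(self, central, life_table):
        # stage-specific excess hazards are ordered, so mean survival falls
        h = central.survival_hazard_by_stage
        assert h[0] < h[1] < h[2] < h[3]
        rng = np.random.default_rng(23)
        u = rng.random(50_000)
        surv1 = -np.log(u) / h[0]
        surv4 = -np.log(u) / h[3]
        assert surv4.mean() < surv1.mean()


class TestCohortSummaries:
    def test_full_determinism(self, central, life_table):
        _, a = simulate_cohort_no_screening(5000, central, life_table, 31, histories=False)
        _, b = simulate_cohort_no_screening(5000, central, life_table, 31, histories=False)
        assert a == b

    def test_incidence_nondecreasing_in_onset_scale(self, central, life_table):
        incidences = []
        for scale in (0.5, 1.0, 2.0):
            p = central.replace(onset_rate_scale=scale)
            _, s = simulate_cohort_no_screening(
                20_000, p, life_table, seed=37, histories=False
            )
            incidences.append(s["incidence"])
        assert incidences[0] < incidences[1] < incidences[2]

    def test_mortality_never_exceeds_incidence(self, central, life_table):
        for seed in (1, 2, 3):
            _, s = simulate_cohort_no_screening(
                10_000, central, life_table, seed, histories=False
            )
            assert s["mortality"] <= s["incidence"]

    def test_monte_carlo_error_shrinks_with_n(self, central, life_table):
        def spread(n, seeds):
            vals = [
                simulate_cohort_no_screening(
                    n, central, life_table, seed, histories=False
                )[1]["incidence"]
                for seed in seeds
            ]
            return np.std(vals)

        small = spread(2_000, range(40, 52))
        large = spread(8_000, range(60, 72))
        # SE should halve when n quadruples (allow slack for 12 replicates)
        assert large < small

    def test_histories_are_well_formed(self, central, life_table):
        histories, _ = simulate_cohort_no_screening(3000, central, life_table, seed=41)
        assert len(histories) == 3000
        for h in histories:
            assert config.START_AGE <= h.death_age <= config.END_AGE
            if h.death_cause == "crc":
                assert h.dx_age is not None and h.dx_age <= h.death_age
            if h.dx_age is not None:
                assert h.dx_stage in (1, 2, 3, 4)

    def test_life_history_validators(self):
        with pytest.raises(ValueError, match="diagnosis"):
            LifeHistory(person=0, sex=0, death_age=80.0, death_cause="crc")
        with pytest.raises(ValueError, match="stage"):
            LifeHistory(
                person=0, sex=0, death_age=80.0, death_cause="crc",
                dx_age=70.0, dx_stage=7,
            )
        with pytest.raises(ValueError, match="after death"):
            LifeHistory(
                person=0, sex=0, death_age=60.0, death_cause="other",
                dx_age=70.0, dx_stage=2,
            )
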