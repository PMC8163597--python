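"""Synthetic cohort generator: determinism, calibration, generative contracts."""

import dataclasses

import numpy as np
import pytest

from clinconsist.consistency import student_year_table
from clinconsist.errors import ConfigError, UndefinedStatisticError
from clinconsist.records import frame_to_observations, restorations_table, write_frame
from clinconsist.synthetic import (
    SimulationConfig,
    difficult_fraction,
    expected_consistency,
    invert_consistency_target,
    simulate_cohorts,
    simulate_frame,
    simulate_restorations,
    summarize_generated,
)


class TestConfigValidation:
    def test_empty_years_rejected(self):
        with pytest.raises(ConfigError, match="years"):
            SimulationConfig(years=())

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="quadrant_probs"):
            SimulationConfig(quadrant_probs=(0.5, 0.5, 0.5, 0.5))

    def test_targets_must_be_probabilities(self):
        with pytest.raises(ConfigError, match="targets"):
            SimulationConfig(year_consistency_targets={3: 1.2, 4: 0.6, 5: 0.7})

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = SimulationConfig(n_students_per_cohort=5, seed=3,
                               restorations_per_year={3: 10.0, 4: 12.0, 5: 10.0})
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SimulationConfig.from_yaml(path) == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            SimulationConfig.from_dict({"n_student": 4})


class TestDeterminism:
    def test_same_seed_identical_datasets(self):
        cfg = SimulationConfig(n_students_per_cohort=4, seed=13)
        assert simulate_frame(cfg).equals(simulate_frame(cfg))
        assert simulate_cohorts(cfg) == simulate_cohorts(cfg)

    def test_same_seed_byte_identical_csv(self, tmp_path):
        cfg = SimulationConfig(n_students_per_cohort=4, seed=13)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_frame(simulate_frame(cfg), p1)
        write_frame(simulate_frame(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_frame(SimulationConfig(n_students_per_cohort=4, seed=1))
        b = simulate_frame(SimulationConfig(n_students_per_cohort=4, seed=2))
        assert not a.equals(b)


def test_zero_students_yield_empty_dataset():
    assert simulate_cohorts(SimulationConfig(n_students_per_cohort=0)) == []


def test_generated_data_pass_records_validation():
    frame = simulate_frame(SimulationConfig(n_students_per_cohort=3, seed=2))
    observations = frame_to_observations(frame)  # raises on any invalid row
    assert len(observations) == len(frame)
    restorations_table(frame, validate=True)  # raises on any context conflict


def test_monotone_generative_contract():
    """Raising every latent year effect (same seed, same noise) never lowers
    any restoration's minimum stage DI."""
    base_cfg = SimulationConfig(n_students_per_cohort=6, seed=17)
    effects = base_cfg.resolved_year_effects()
    low = dataclasses.replace(base_cfg, year_latent_effects=effects)
    high = dataclasses.replace(base_cfg,
                               year_latent_effects={y: m + 0.5 for y, m in effects.items()})
    min_low = simulate_restorations(low)["min_di"]
    min_high = simulate_restorations(high)["min_di"]
    assert (min_high >= min_low).all()
    assert min_high.mean() > min_low.mean()


def test_observation_and_restoration_paths_agree():
    """simulate_frame and simulate_restorations are two views of one draw."""
    cfg = SimulationConfig(n_students_per_cohort=4, seed=23)
    via_obs = restorations_table(simulate_frame(cfg), validate=False)
    direct = simulate_restorations(cfg)
    assert via_obs.equals(direct)


class TestSummarizeGenerated:
    def test_staff_per_student_near_target(self):
        cfg = SimulationConfig(seed=29)  # 140 students
        summary = summarize_generated(simulate_frame(cfg))
        assert summary["staff_per_student_mean"] == pytest.approx(10.0, abs=1.0)
        assert summary["volume_median_by_year"][4] == pytest.approx(24, abs=3)

    def test_single_student_single_restoration_volumes(self):
        from clinconsist.records import Observation, SurfaceClass, ToothSite
        obs = [Observation(student_id="s1", cohort_id="C1", year_of_study=5,
                           staff_id="st1", patient_id="p1", restoration_id="r1",
                           stage_id=f"s{i}", di=5, site=ToothSite(1, 6),
                           surface=SurfaceClass.OCCLUSAL_SURFACE) for i in (1, 2)]
        summary = summarize_generated(obs)
        assert summary["n_students"] == 1
        assert summary["n_restorations"] == 1
        assert summary["volume_median_by_year"] == {5: 1.0}
        assert summary["staff_per_student_mean"] == 1.0

    def test_degenerate_case_mix(self):
        cfg = SimulationConfig(
            n_students_per_cohort=5, seed=31,
            surface_probs={"approximal_anterior": 0.0, "approximal_posterior": 0.0,
                           "incisal_edge": 0.0, "smooth_surface": 0.0,
                           "occlusal_surface": 1.0})
        summary = summarize_generated(simulate_frame(cfg))
        assert summary["surface_fractions"] == {"occlusal_surface": 1.0}

    def test_empty_input_is_an_error(self):
        with pytest.raises(UndefinedStatisticError):
            summarize_generated([])


def test_difficulty_zero_when_no_clause_can_fire():
    """No approximal surfaces, no upper-posterior teeth, no staff tags ->
    zero difficult restorations downstream."""
    from clinconsist.difficulty import difficult_mask
    cfg = SimulationConfig(
        n_students_per_cohort=5, seed=37, staff_flag_rate=0.0,
        surface_probs={"approximal_anterior": 0.0, "approximal_posterior": 0.0,
                       "incisal_edge": 0.3, "smooth_surface": 0.4, "occlusal_surface": 0.3},
        quadrant_probs=(0.0, 0.0, 0.5, 0.5))
    rest = simulate_restorations(cfg)
    assert difficult_mask(rest).sum() == 0
    assert difficult_fraction(cfg) == 0.0


class TestCalibration:
    def test_inversion_round_trip(self):
        kwargs = dict(stages=4, shift_sd=0.3, noise_sd=1.0, penalty=0.3, p_difficult=0.6)
        for target in (0.2, 0.46, 0.6, 0.76, 0.9):
            mu = invert_consistency_target(target, **kwargs)
            assert expected_consistency(mu, **kwargs) == pytest.approx(target, abs=1e-8)

    def test_year_means_track_targets(self):
        """Simulated per-year mean consistencies land near the configured
        targets (SE of the mean is ~0.018 at 140 students)."""
        cfg = SimulationConfig(seed=41)
        table = student_year_table(simulate_restorations(cfg), 5)
        for year, target in cfg.year_consistency_targets.items():
            got = table.loc[table["year_of_study"] == year, "consistency"].mean()
            assert got == pytest.approx(target, abs=0.06)

    def test_strong_growth_shows_in_consistency(self):
        cfg = SimulationConfig(n_students_per_cohort=20, seed=43)
        table = student_year_table(simulate_restorations(cfg), 5)
        means = table.groupby("year_of_study")["consistency"].mean()
        assert means[3] < means[4] < means[5]
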