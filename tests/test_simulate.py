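import math

import numpy as np
import pytest

from ecoconverge import (
    build_study,
    cp_trend_score,
    default_config,
    make_fixture_study,
    simulate_survey,
    simulate_timeseries,
    yoy_changes,
)
from ecoconverge.simulate import SeriesSpec, SimulationConfig, SurveySpec

YEARS = range(2010, 2021)


class TestSimulateTimeseries:
    def test_noise_free_growth_is_exact(self):
        s = simulate_timeseries(2.0, 0.0, YEARS, seed=0)
        assert yoy_changes(s) == pytest.approx([2.0] * 10, abs=1e-9)

    def test_seed_determinism(self):
        a = simulate_timeseries(-3.0, 0.1, YEARS, seed=7)
        b = simulate_timeseries(-3.0, 0.1, YEARS, seed=7)
        c = simulate_timeseries(-3.0, 0.1, YEARS, seed=8)
        assert a.observations == b.observations
        assert a.observations != c.observations

    def test_gap_years_removed(self):
        s = simulate_timeseries(1.0, 0.0, YEARS, gaps=(2013, 2015), seed=0)
        assert 2013 not in s.years and 2015 not in s.years
        assert s.years[0] == 2010 and s.years[-1] == 2020

    def test_gap_endpoints_rejected(self):
        with pytest.raises(ValueError, match="endpoint"):
            simulate_timeseries(1.0, 0.0, YEARS, gaps=(2010,), seed=0)

    def test_values_stay_positive(self):
        s = simulate_timeseries(-50.0, 0.5, YEARS, seed=1)
        assert all(v > 0 for v in s.values)

    def test_monte_carlo_mean_matches_lognormal_expectation(self):
        # E[YoY%] = 100 * ((1 + g) * exp(sd^2 / 2) - 1)
        trend, sd = -20.0, 0.05
        expected = 100.0 * ((1 + trend / 100.0) * math.exp(sd**2 / 2) - 1)
        rng = np.random.default_rng(2024)
        means = [
            np.mean(yoy_changes(simulate_timeseries(trend, sd, YEARS, seed=rng)))
            for _ in range(500)
        ]
        assert abs(float(np.mean(means)) - expected) < 1.0


class TestSimulateSurvey:
    def test_zero_dispersion_recovers_exactly(self):
        s = simulate_survey(-1, 0.0, 50, scale_points=5, seed=0)
        assert set(s.responses) == {-1}
        assert cp_trend_score(s).score == -1

    def test_seed_determinism(self):
        a = simulate_survey(1, 1.0, 100, scale_points=7, seed=5)
        b = simulate_survey(1, 1.0, 100, scale_points=7, seed=5)
        assert a.responses == b.responses

    def test_clamped_to_scale_range(self):
        s = simulate_survey(3, 2.0, 500, scale_points=7, seed=3)
        assert all(-3 <= r <= 3 for r in s.responses)

    def test_recovery_rate_at_reference_sample_size(self):
        # smallest community sample: n = 252 on a 7-point scale
        hits = sum(
            cp_trend_score(
                simulate_survey(-1, 1.0, 252, scale_points=7, seed=seed)
            ).score
            == -1
            for seed in range(200)
        )
        assert hits >= 190  # >= 95% of 200 seeds

    def test_bias_shifts_responses(self):
        s = simulate_survey(0, 0.0, 20, scale_points=5, seed=0, bias=1.0)
        assert set(s.responses) == {1}


class TestStudyGeneration:
    def test_noise_free_ground_truth_recovered(self):
        from ecoconverge.io import score_cp_frame, score_ns_frame
        from ecoconverge import build_matrix

        cfg = default_config(seed=11)
        series, samples, truth = build_study(cfg)
        _, ns_scores = score_ns_frame(series, cfg.thresholds)
        _, cp_scores = score_cp_frame(samples)
        matrix = build_matrix(ns_scores, cp_scores)
        assert len(matrix.complete_cells) == len(truth)
        for cell in matrix.cells:
            row = truth[
                (truth.site == cell.site)
                & (truth.habitat == cell.habitat)
                & (truth.direction == cell.direction)
            ].iloc[0]
            assert cell.ns_score == row.true_ns_score
            assert cell.cp_score == row.true_cp_score
            assert cell.d == row.true_d

    def test_spec_order_invariance(self):
        cfg = default_config(seed=4, noise_sd=0.05, dispersion=1.0, n=50)
        reversed_cfg = SimulationConfig(
            series=tuple(reversed(cfg.series)),
            surveys=tuple(reversed(cfg.surveys)),
            seed=cfg.seed,
        )
        series_a, samples_a, _ = build_study(cfg)
        series_b, samples_b, _ = build_study(reversed_cfg)
        key = lambda s: s.key
        assert sorted(series_a, key=key) == sorted(series_b, key=key)
        assert sorted(samples_a, key=key) == sorted(samples_b, key=key)

    def test_fixture_files_byte_identical_for_fixed_seed(self, tmp_path):
        cfg = default_config(seed=9, noise_sd=0.02, dispersion=0.5, n=40)
        paths_a = make_fixture_study(cfg, tmp_path / "a")
        paths_b = make_fixture_study(cfg, tmp_path / "b")
        for role in paths_a:
            assert paths_a[role].read_bytes() == paths_b[role].read_bytes()

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SeriesSpec("s", "fisheries", trend_pct=1.0, n_years=1)
        with pytest.raises(ValueError):
            SurveySpec("s", "fisheries", "past", true_score=3, scale_points=5)
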