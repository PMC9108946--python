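import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecoconverge import (
    DEFAULT_THRESHOLDS,
    EcosystemSeries,
    categorize_rate,
    interpolate_series,
    score_scenarios,
    suggest_cutoffs,
    summarize_yoy,
    two_point_rate,
    yoy_changes,
)
from ecoconverge.ns_scoring import RateSummary, rate_for_series


def series(obs, habitat="fisheries", scenario="present"):
    return EcosystemSeries("s1", habitat, tuple(obs), scenario)


def growth_series(rate_pct, n_years=11, start=100.0, start_year=2010):
    """Exact multiplicative growth: every YoY change equals rate_pct."""
    g = 1.0 + rate_pct / 100.0
    return series(
        [(start_year + t, start * g**t) for t in range(n_years)]
    )


class TestEcosystemSeries:
    def test_rejects_short_unsorted_or_negative(self):
        with pytest.raises(ValueError, match="at least 2"):
            series([(2010, 1.0)])
        with pytest.raises(ValueError, match="strictly increasing"):
            series([(2011, 1.0), (2010, 2.0)])
        with pytest.raises(ValueError, match="negative"):
            series([(2010, 1.0), (2011, -2.0)])


class TestYoyChanges:
    @pytest.mark.parametrize(
        "obs, expected",
        [
            ([(2010, 100), (2011, 110), (2012, 99)], [10.0, -10.0]),
            ([(2010, 7), (2011, 7), (2012, 7), (2013, 7)], [0.0, 0.0, 0.0]),
        ],
    )
    def test_definition(self, obs, expected):
        assert yoy_changes(series(obs)) == pytest.approx(expected)

    def test_exact_growth_factor(self):
        changes = yoy_changes(growth_series(2.0))
        assert changes == pytest.approx([2.0] * 10, abs=1e-9)

    def test_gap_years_require_interpolation_first(self):
        with pytest.raises(ValueError, match="interpolate"):
            yoy_changes(series([(2010, 1.0), (2012, 2.0)]))

    def test_zero_base_year_named(self):
        with pytest.raises(ZeroDivisionError, match="2011"):
            yoy_changes(series([(2010, 5.0), (2011, 0.0), (2012, 5.0)]))


class TestSummarizeYoy:
    def test_mean_and_median(self):
        assert summarize_yoy([10, -10]) == 0.0
        # endpoints echo the reported +25% .. -50% cross-site spread
        assert summarize_yoy([25, -50, 2, 2, 2], "median") == 2.0

    def test_large_sample_mean_recovers_location(self):
        rng = np.random.default_rng(42)
        draws = rng.normal(3.0, 1.0, size=1000)
        assert abs(summarize_yoy(list(draws)) - 3.0) < 0.1

    def test_empty_and_bad_method(self):
        with pytest.raises(ValueError):
            summarize_yoy([])
        with pytest.raises(ValueError):
            summarize_yoy([1.0], "mode")


class TestTwoPointRate:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((100, 90, 2007, 2017, "linear"), -1.0),
            ((100, 100, 2003, 2016, "linear"), 0.0),
            ((100, 100, 2003, 2016, "compound"), 0.0),
            ((100, 90, 2007, 2017, "compound"), math.log(0.9) / 10 * 100),
        ],
    )
    def test_closed_forms(self, args, expected):
        assert two_point_rate(*args) == pytest.approx(expected, abs=1e-12)

    def test_hazards(self):
        with pytest.raises(ZeroDivisionError):
            two_point_rate(0.0, 10, 2000, 2010)
        with pytest.raises(ValueError, match="compound|log"):
            two_point_rate(10, 0.0, 2000, 2010, "compound")
        with pytest.raises(ValueError):
            two_point_rate(10, 10, 2010, 2010)

    @given(
        a1=st.floats(50, 200),
        ratio=st.floats(0.9905, 1.0095),
        dt=st.integers(1, 15),
    )
    def test_linear_compound_first_order_agreement(self, a1, ratio, dt):
        a2 = a1 * ratio
        lin = two_point_rate(a1, a2, 2000, 2000 + dt, "linear")
        comp = two_point_rate(a1, a2, 2000, 2000 + dt, "compound")
        assert abs(lin - comp) < 0.01


class TestInterpolateSeries:
    @pytest.mark.parametrize(
        "obs, expected",
        [
            ([(2000, 10), (2002, 20)], [(2000, 10.0), (2001, 15.0), (2002, 20.0)]),
            (
                [(2000, 8), (2004, 0)],
                [(2000, 8.0), (2001, 6.0), (2002, 4.0), (2003, 2.0), (2004, 0.0)],
            ),
        ],
    )
    def test_linear_fill(self, obs, expected):
        assert interpolate_series(series(obs)).observations == tuple(expected)

    def test_identity_on_complete_series(self):
        s = series([(2000, 1.0), (2001, 2.0), (2002, 3.0)])
        assert interpolate_series(s) is s

    @given(
        st.lists(
            st.tuples(st.integers(1990, 2020), st.floats(0.1, 1e4)),
            min_size=2, max_size=8,
            unique_by=lambda t: t[0],
        )
    )
    def test_idempotent_and_preserves_observations(self, obs):
        s = series(sorted(obs))
        full = interpolate_series(s)
        assert interpolate_series(full).observations == full.observations
        observed = dict(s.observations)
        for y, v in full.observations:
            if y in observed:
                assert v == observed[y]


class TestCategorizeRate:
    @pytest.mark.parametrize(
        "rate, sector, expected",
        [
            (0.3, "mangrove", 1),
            (-13.45, "mangrove", -2),  # steepest observed mangrove decline
            (0.0, "fisheries", 0),
            (0.0, "mangrove", 0),
            (0.0, "coral", 0),
            (0.0, "seagrass", 0),
            # boundary convention: the outer value belongs to the milder band
            (10.0, "fisheries", 0),
            (10.000001, "fisheries", 1),
            (20.0, "fisheries", 1),
            (20.000001, "fisheries", 2),
            (-10.0, "fisheries", 0),
            (-20.0, "fisheries", -1),
            (-20.000001, "fisheries", -2),
            (5.0, "seagrass", 1),
            (5.1, "seagrass", 2),
        ],
    )
    def test_bands(self, rate, sector, expected):
        assert categorize_rate(rate, sector) == expected

    def test_unknown_sector(self):
        with pytest.raises(KeyError, match="kelp"):
            categorize_rate(1.0, "kelp")

    @given(
        r1=st.floats(-100, 100),
        r2=st.floats(-100, 100),
        sector=st.sampled_from(["fisheries", "mangrove", "coral", "seagrass"]),
    )
    def test_monotone_in_rate(self, r1, r2, sector):
        lo, hi = sorted((r1, r2))
        assert categorize_rate(lo, sector) <= categorize_rate(hi, sector)

    @given(
        rate=st.floats(-100, 100),
        sector=st.sampled_from(["fisheries", "mangrove", "coral", "seagrass"]),
    )
    def test_antisymmetric_off_boundaries(self, rate, sector):
        t = DEFAULT_THRESHOLDS[sector]
        if abs(rate) in (t.inner, t.outer):
            return
        assert categorize_rate(-rate, sector) == -categorize_rate(rate, sector)


class TestRateForSeries:
    @given(rate=st.floats(-50, 200))
    def test_noise_free_growth_recovered_exactly(self, rate):
        summary = rate_for_series(growth_series(rate))
        assert summary.method == "yoy_mean"
        assert summary.rate_pct_per_year == pytest.approx(rate, abs=1e-9)

    def test_two_snapshot_series_uses_linear_rate(self):
        s = series([(2007, 100.0), (2017, 90.0)], habitat="mangrove")
        summary = rate_for_series(s)
        assert summary.method == "two_point_linear"
        assert summary.rate_pct_per_year == pytest.approx(-1.0)
        assert summary.n_intervals == 1


def rate_summaries(rates):
    return [
        RateSummary("s%d" % i, "fisheries", "present", r, "yoy_mean", 10)
        for i, r in enumerate(rates)
    ]


class TestSuggestCutoffs:
    def test_sd_18_reproduces_fisheries_pairing(self):
        # sample SD exactly 18, median +2 (the reported cross-site stats)
        out = suggest_cutoffs(rate_summaries([-16.0, 2.0, 20.0]))
        assert out.sd == pytest.approx(18.0)
        assert out.median == pytest.approx(2.0)
        assert (out.proposal.inner, out.proposal.outer) == (10.0, 20.0)
        assert out.proposal.provenance == "median_derived"
        assert out.heuristic

    def test_degenerate_dispersion_rejected(self):
        out = suggest_cutoffs(rate_summaries([3.0, 3.0, 3.0]))
        assert out.proposal is None
        assert any("degenerate" in w for w in out.warnings)

    def test_diagnostics(self):
        out = suggest_cutoffs(rate_summaries([25.0, -50.0, 2.0]))
        assert out.median == 2.0
        assert out.minimum == -50.0
        assert out.maximum == 25.0
        assert out.n == 3

    def test_needs_two_rates(self):
        with pytest.raises(ValueError):
            suggest_cutoffs(rate_summaries([1.0]))


class TestScoreScenarios:
    @staticmethod
    def scenarios(rates):
        return {
            f"rcp{i}": EcosystemSeries(
                "s1", "fisheries",
                tuple(
                    (2030 + t, 100.0 * (1 + r / 100.0) ** t) for t in range(11)
                ),
                scenario=f"rcp{i}",
            )
            for i, r in enumerate(rates)
        }

    def test_mild_scenarios_agree_on_slight_change(self):
        out = score_scenarios(self.scenarios([-5.0, 1.0]), "fisheries")
        assert set(out.scores.values()) == {0}
        assert out.agreement and out.consensus_score == 0

    def test_single_scenario_vacuously_agrees(self):
        out = score_scenarios(self.scenarios([3.0]), "fisheries")
        assert out.agreement

    def test_disagreement_flagged(self):
        out = score_scenarios(self.scenarios([15.0, -15.0]), "fisheries")
        assert sorted(out.scores.values()) == [-1, 1]
        assert not out.agreement
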