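"""Area -> V/V0 -> initial slope -> Pf/Ps chain and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aqpkit.osmotic import BathCondition, analytic_initial_slope_water
from aqpkit.permeability import (
    SwellingTimeCourse,
    compare_groups,
    estimate_cohort,
    estimate_pf,
    estimate_ps,
    inhibition_percent,
    initial_slope,
    relative_volume,
)
from aqpkit.simulate import SwellingSimParams, gen_swelling_cohort

PF = 2e-2
BATH = BathCondition(70.0)


def _tc(areas, times=None, bath=BATH):
    areas = np.asarray(areas, dtype=float)
    if times is None:
        times = np.arange(areas.size, dtype=float)
    return SwellingTimeCourse("oo-1", "g", times, areas, bath)


def _noise_free_cohort(**kw):
    params = SwellingSimParams(pf_cv=0.0, area_noise_cv=0.0, n_oocytes=1, **kw)
    return gen_swelling_cohort(params)


class TestRelativeVolume:
    @pytest.mark.parametrize(
        "ratio, expected",
        [(1.0, 1.0), (1.21, 1.331), (4.0, 8.0)],
    )
    def test_three_halves_power(self, ratio, expected):
        tc = _tc([2.0, 2.0 * ratio, 2.0 * ratio])
        assert relative_volume(tc)[1] == pytest.approx(expected, rel=1e-12)

    def test_first_element_exactly_one(self):
        tc = _tc([3.1, 3.3, 3.5])
        assert relative_volume(tc)[0] == 1.0

    def test_nonpositive_area_rejected_with_index(self):
        with pytest.raises(ValueError, match="index 2"):
            _tc([1.0, 1.1, -0.5, 1.2])

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, scale):
        """Doubling (or any rescaling of) all areas leaves V/V0 unchanged."""
        base = np.array([1.0, 1.02, 1.05, 1.09, 1.14]) * 1e-2
        vv_a = relative_volume(_tc(base))
        vv_b = relative_volume(_tc(base * scale))
        assert np.allclose(vv_a, vv_b, rtol=1e-12)


class TestInitialSlope:
    def test_constant_series(self):
        fit = initial_slope(np.ones(10), np.arange(10.0), window=5.0)
        assert fit.slope == 0.0
        assert fit.r_squared == 1.0

    def test_exact_line(self):
        t = np.arange(0.0, 21.0)
        fit = initial_slope(1.0 + 1e-3 * t, t, window=20.0)
        assert fit.slope == pytest.approx(1e-3, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_window_restricts_points(self):
        t = np.arange(0.0, 61.0)
        y = 1.0 + 1e-3 * t
        y[21:] = 5.0  # garbage outside the window must not matter
        fit = initial_slope(y, t, window=20.0)
        assert fit.n_points == 21
        assert fit.slope == pytest.approx(1e-3, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="window"):
            initial_slope([1.0, 1.1, 1.2], [0.0, 5.0, 10.0], window=1.0)

    def test_simulated_slope_near_analytic_over_10s(self, geom):
        tc = _noise_free_cohort(dt=1.0)[0]
        fit = initial_slope(relative_volume(tc), tc.times, window=10.0)
        assert fit.slope == pytest.approx(2.34e-3, rel=0.03)


class TestCoefficients:
    def test_pf_formula_anchor(self, geom):
        # slope 1e-3 1/s against a 130-mOsm gradient -> 8.55e-3 cm/s
        est = estimate_pf(1e-3, geom, 200.0, 70.0)
        assert est.coefficient == pytest.approx(8.547e-3, rel=1e-3)
        assert float(f"{est.coefficient:.3g}") == 8.55e-3

    def test_zero_slope_zero_pf(self, geom):
        assert estimate_pf(0.0, geom, 200.0, 70.0).coefficient == 0.0

    def test_zero_gradient_rejected(self, geom):
        with pytest.raises(ValueError, match="gradient"):
            estimate_pf(1e-3, geom, 200.0, 200.0)
        with pytest.raises(ValueError, match="gradient"):
            estimate_ps(1e-3, geom, 50.0, 50.0)

    def test_ps_formula_anchor(self, geom):
        est = estimate_ps(5e-4, geom, 0.0, 100.0)
        assert est.coefficient == pytest.approx(5.556e-3, rel=1e-3)
        assert est.kind == "solute"

    def test_influx_gives_positive_coefficient(self, geom):
        # gradient magnitude convention: sol_in - sol_out < 0 still yields Ps > 0
        assert estimate_ps(5e-4, geom, 0.0, 100.0).coefficient > 0

    def test_algebraic_round_trip_is_identity(self, geom):
        for pf in (1e-3, 5e-3, 2e-2):
            slope = analytic_initial_slope_water(geom, pf, 200.0, 70.0)
            back = estimate_pf(slope, geom, 200.0, 70.0).coefficient
            assert back == pytest.approx(pf, rel=1e-14)

    def test_pf_recovery_from_simulator_short_window(self, geom):
        """Forward simulate, fit a near-zero window, invert: Pf within 1%."""
        tc = _noise_free_cohort(dt=0.1)[0]
        fit = initial_slope(relative_volume(tc), tc.times, window=2.0)
        est = estimate_pf(fit, geom, 200.0, 70.0)
        assert est.coefficient == pytest.approx(PF, rel=0.01)

    def test_window_bias_decreases_pf_monotonically(self, geom):
        """Internal dilution shrinks the gradient: longer window, lower Pf."""
        tc = _noise_free_cohort(dt=1.0)[0]
        vv0 = relative_volume(tc)
        pfs = [
            estimate_pf(
                initial_slope(vv0, tc.times, w), geom, 200.0, 70.0
            ).coefficient
            for w in (5, 10, 20, 40, 60)
        ]
        assert np.all(np.diff(pfs) < 0)

    def test_low_r_squared_flagged_not_dropped(self, geom):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 21.0)
        y = 1.0 + 1e-4 * t + rng.normal(0, 0.05, t.size)
        est = estimate_pf(initial_slope(y, t, 20.0), geom, 200.0, 70.0)
        assert est.low_quality
        assert np.isfinite(est.coefficient)


class TestInhibition:
    def test_no_change(self):
        assert inhibition_percent(1.0, 1.0) == 0.0

    def test_eighty_percent_block(self):
        assert inhibition_percent(0.2, 1.0) == pytest.approx(80.0)

    def test_stimulation_reported_negative_by_default(self):
        assert inhibition_percent(1.5, 1.0) == pytest.approx(-50.0)
        assert inhibition_percent(1.5, 1.0, clip_negative=True) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            inhibition_percent(0.5, 0.0)


class TestGroupComparison:
    def test_two_identical_groups(self):
        res = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.method == "welch-t"
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.pairwise is None

    def test_three_identical_groups(self):
        vals = [1.0, 2.0, 3.0]
        res = compare_groups({"a": vals, "b": vals, "c": vals})
        assert res.method == "anova-tukey"
        assert res.statistic == 0.0
        assert len(res.pairwise) == 3

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})

    def test_tukey_matches_statsmodels(self):
        """Independent cross-check of the ANOVA branch."""
        import pandas as pd
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(11)
        data = {
            "low": rng.normal(1.0, 0.2, 8),
            "mid": rng.normal(1.5, 0.2, 8),
            "high": rng.normal(2.2, 0.2, 8),
        }
        res = compare_groups(data)
        stacked = pd.DataFrame(
            [(g, v) for g, vals in data.items() for v in vals],
            columns=["group", "value"],
        )
        sm = pairwise_tukeyhsd(stacked["value"], stacked["group"])
        from itertools import combinations

        sm_pairs = list(combinations(sm.groupsunique, 2))
        sm_p = {
            tuple(sorted(pair)): p for pair, p in zip(sm_pairs, sm.pvalues)
        }
        for (a, b), p in res.pairwise:
            assert p == pytest.approx(sm_p[tuple(sorted((a, b)))], abs=1e-6)

    def test_separated_groups_detected_with_high_power(self):
        """Monte-Carlo power oracle: means 1 vs 2, sd 0.1, n=5 -> p < 0.001."""
        hits = 0
        n_sim = 300
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            res = compare_groups(
                {"a": rng.normal(1.0, 0.1, 5), "b": rng.normal(2.0, 0.1, 5)}
            )
            hits += res.p_value < 1e-3
        assert hits / n_sim >= 0.99


class TestCohortPipeline:
    def test_per_oocyte_table_and_summary(self, geom):
        cohort = gen_swelling_cohort(SwellingSimParams(seed=3))
        per = estimate_cohort(cohort, mode="water", window=20.0)
        assert len(per) == 5
        assert set(per["group"]) == {"construct"}
        from aqpkit.permeability import summarize_groups

        summary = summarize_groups(per)
        assert summary.loc[0, "n"] == 5
        assert summary.loc[0, "coef_mean"] > 0

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            estimate_cohort([], mode="osmole")
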