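"""Elastic-point detection, DP/PEEP recommendations."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import two_line_maneuver
from oracles import hinge_oracle

from dptitrate.mechanics import LungParams, PVManeuver, simulate_maneuver
from dptitrate.titration import (
    NoPlasticTransition,
    VentSettings,
    detect_elastic_point,
    elastic_modulus_summary,
    fit_two_segment,
    local_slopes,
    recommend_dp,
    recommend_peep,
    round_to_half,
)


class TestLocalSlopes:
    def test_linear_maneuver_constant_slope(self):
        v = np.arange(8.0)
        m = PVManeuver("t", "inflation", v, 9.0 + 1.2 * v, 1.0)
        _, s = local_slopes(m)
        np.testing.assert_allclose(s, 1.2)
        assert len(s) == 7

    def test_hand_arithmetic(self):
        m = PVManeuver.from_points(
            "t", "inflation", [(0, 10), (1, 11), (2, 14), (3, 18), (4, 23)], 1
        )
        mids, s = local_slopes(m)
        np.testing.assert_allclose(s[:2], [1.0, 3.0])
        np.testing.assert_allclose(mids[:2], [0.5, 1.5])

    def test_model_convexity_gives_nondecreasing_slopes(self):
        p = LungParams(peep=10, e1=0.8, v_el=6, alpha=0.4, sigma=0.0)
        _, s = local_slopes(simulate_maneuver(p))
        assert np.all(np.diff(s) >= -1e-9)


class TestTwoSegmentFit:
    @pytest.mark.parametrize(
        "knot_v,knot_p,s1,s2",
        [(5.0, 16.0, 1.0, 3.0), (3.0, 12.0, 0.5, 2.0), (7.0, 20.0, 1.5, 6.0)],
    )
    def test_exact_recovery_on_two_lines(self, knot_v, knot_p, s1, s2):
        m = two_line_maneuver(knot_v, knot_p, s1, s2)
        ep = fit_two_segment(m)
        assert ep.v_el_hat == pytest.approx(knot_v, abs=1e-9)
        assert ep.p_el_hat == pytest.approx(knot_p, abs=1e-8)
        assert ep.sse == pytest.approx(0.0, abs=1e-10)
        assert ep.e1_hat == pytest.approx(s1, abs=1e-8)
        assert ep.e2_hat == pytest.approx(s2, abs=1e-8)
        assert ep.dp_individual == pytest.approx(s1 * knot_v, abs=1e-8)
        assert ep.ok

    def test_linear_data_flagged_no_transition(self):
        v = np.arange(10.0)
        ep = fit_two_segment(PVManeuver("t", "inflation", v, 10 + 1.2 * v, 1.0))
        assert ep.flag == "no_plastic_transition"
        assert not ep.ok

    def test_too_few_points_rejected(self):
        v = np.arange(5.0)
        with pytest.raises(ValueError):
            fit_two_segment(PVManeuver("t", "inflation", v, 10 + v**1.5, 1.0))

    def test_e1_recovered_within_10pct_on_clean_kinked_curve(self):
        ep = fit_two_segment(two_line_maneuver(6.0, 18.0, 0.8, 2.4, v_max=12))
        assert ep.e1_hat == pytest.approx(0.8, rel=0.1)

    def test_monotone_dp_in_knot_position_for_two_line_curves(self):
        # at fixed elastic slope, later elastic limits mean larger DP
        dps = [
            fit_two_segment(two_line_maneuver(k, 10 + 1.2 * k, 1.2, 4.0, v_max=14)).dp_individual
            for k in (3.0, 5.0, 7.0, 9.0, 11.0)
        ]
        assert all(b - a > 0 for a, b in zip(dps, dps[1:]))

    def test_permutation_safety(self):
        rng = np.random.default_rng(0)
        m = simulate_maneuver(LungParams(peep=10, e1=1.0, v_el=6, alpha=0.3, sigma=0.3), seed=1)
        pts = m.points
        rng.shuffle(pts)
        m2 = PVManeuver.from_points(m.subject_id, m.limb, pts, m.step)
        assert fit_two_segment(m) == fit_two_segment(m2)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 21))
        v = np.arange(float(n))
        p = (
            rng.uniform(5, 15)
            + rng.uniform(0.2, 2.0) * v
            + rng.uniform(0, 0.5) * np.maximum(v - rng.uniform(2, n - 3), 0) ** 2
            + rng.normal(0, rng.uniform(0, 1.0), n)
        )
        m = PVManeuver("t", "inflation", v, p, 1.0)
        ep = fit_two_segment(m)
        k_oracle, sse_oracle = hinge_oracle(v, p)
        assert ep.index == k_oracle
        assert ep.sse == pytest.approx(sse_oracle, rel=1e-9, abs=1e-9)


class TestDetectElasticPoint:
    def test_methods_agree_on_clean_two_line(self, clean_two_line):
        a = detect_elastic_point(clean_two_line, "piecewise")
        b = detect_elastic_point(clean_two_line, "max_acceleration")
        assert a.index == b.index
        assert b.dp_individual == pytest.approx(a.dp_individual, abs=1e-8)

    def test_quadratic_tie_breaks_to_lowest_interior_index(self):
        v = np.arange(11.0)
        m = PVManeuver("t", "inflation", v, 10 + 0.1 * v**2, 1.0)
        ep = detect_elastic_point(m, "max_acceleration")
        assert ep.index == 1

    def test_unknown_method_rejected(self, clean_two_line):
        with pytest.raises(ValueError):
            detect_elastic_point(clean_two_line, "spline")


class TestRecommendations:
    def test_rounding_to_half_cmh2o(self):
        assert round_to_half(11.2) == 11.0
        assert round_to_half(11.25) == 11.5
        assert round_to_half(16.1) == 16.0
        assert round_to_half(13.74) == 13.5

    def test_plain_recommendation_no_warnings(self, clean_two_line):
        # dp 11.2, v_el 1.9 mL at 357 g -> 5.3 mL/kg: below every threshold
        base = fit_two_segment(clean_two_line)
        rec = recommend_dp(
            _with(base, dp_individual=11.2, v_el_hat=1.9),
            VentSettings(peep=12, weight_g=357),
        )
        assert rec.dp == 11.0
        assert rec.warnings == ()

    def test_high_dp_warning(self, clean_two_line):
        ep = _with(fit_two_segment(clean_two_line), dp_individual=16.1)
        rec = recommend_dp(ep, VentSettings(peep=12, weight_g=357))
        assert rec.dp == 16.0
        assert "high_dp" in rec.warnings

    def test_tidal_volume_warning(self, clean_two_line):
        ep = _with(fit_two_segment(clean_two_line), dp_individual=10.0, v_el_hat=3.0)
        rec = recommend_dp(ep, VentSettings(peep=12, weight_g=357))
        assert "tidal_volume_above_6_ml_per_kg" in rec.warnings  # 3/0.357 = 8.4 mL/kg

    def test_degenerate_curve_warning(self, clean_two_line):
        ep = _with(fit_two_segment(clean_two_line), dp_individual=0.0, v_el_hat=0.5)
        rec = recommend_dp(ep, VentSettings(peep=12, weight_g=357))
        assert rec.dp == 0.0
        assert "degenerate_curve" in rec.warnings

    def test_flagged_fit_raises(self):
        v = np.arange(10.0)
        ep = fit_two_segment(PVManeuver("t", "inflation", v, 10 + v, 1.0))
        with pytest.raises(NoPlasticTransition):
            recommend_dp(ep, VentSettings(peep=12, weight_g=357))

    def test_peep_from_two_line_deflation(self):
        m = two_line_maneuver(6.0, 12.0, 0.6, 2.2, v_max=12, limb="deflation")
        rec = recommend_peep(m)
        assert rec.peep == 12.0
        assert rec.warnings == ()

    def test_linear_deflation_falls_back_to_default(self):
        v = np.arange(12.0)
        m = PVManeuver("t", "deflation", v, 4 + 0.8 * v, 1.0)
        rec = recommend_peep(m)
        assert rec.peep == 5.0
        assert "no_transition_default_peep" in rec.warnings

    def test_peep_requires_deflation_limb(self, clean_two_line):
        with pytest.raises(ValueError):
            recommend_peep(clean_two_line)

    def test_modulus_summary_ratio(self, clean_two_line):
        e1, e2, ratio = elastic_modulus_summary(fit_two_segment(clean_two_line))
        assert ratio == pytest.approx(3.0, abs=1e-8)
        flagged = fit_two_segment(
            PVManeuver("t", "inflation", np.arange(10.0), 10 + np.arange(10.0), 1.0)
        )
        _, _, r = elastic_modulus_summary(flagged)
        assert r <= 1 + 1e-6 and not flagged.ok


def _with(ep, **kw):
    """Copy an ElasticPoint with selected fields replaced."""
    import dataclasses

    return dataclasses.replace(ep, **kw)
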