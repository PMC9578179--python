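"""Pressure–volume law, maneuver simulation and cohort generator."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dptitrate.mechanics import (
    ArmSpec,
    CohortConfig,
    LungParams,
    OutcomeSpec,
    PVManeuver,
    default_cohort_config,
    draw_outcome,
    lognormal_shape,
    pv_deflation_model,
    pv_inflation_model,
    simulate_cohort,
    simulate_maneuver,
)


class TestPVModel:
    def test_zero_volume_returns_peep(self):
        p = LungParams(peep=7.5, e1=1.1, v_el=6, alpha=0.4)
        assert pv_inflation_model(p, 0.0) == pytest.approx(7.5)

    def test_elastic_endpoint(self):
        p = LungParams(peep=10, e1=1.0, v_el=4, alpha=0.9)
        assert pv_inflation_model(p, 4.0) == pytest.approx(14.0)

    def test_plastic_closed_form(self):
        # peep + e1*v_el + (e1/alpha)*(exp(alpha*(v-v_el)) - 1)
        # = 10 + 4 + 2*(e - 1), evaluated by hand
        p = LungParams(peep=10, e1=1.0, v_el=4, alpha=0.5)
        assert pv_inflation_model(p, 6.0) == pytest.approx(14.0 + 2.0 * (math.e - 1.0))

    def test_alpha_zero_is_linear_extension(self):
        p = LungParams(peep=10, e1=1.2, v_el=4, alpha=0.0)
        assert pv_inflation_model(p, 9.0) == pytest.approx(10 + 1.2 * 9)

    def test_negative_volume_rejected(self):
        p = LungParams(peep=10, e1=1.0, v_el=4)
        with pytest.raises(ValueError):
            pv_inflation_model(p, -0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_slope_nondecreasing_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        p = LungParams(
            peep=rng.uniform(0, 15),
            e1=rng.uniform(0.2, 3.0),
            v_el=rng.uniform(1, 12),
            alpha=rng.uniform(0, 1.5),
        )
        v = np.linspace(0, 14, 600)
        slopes = np.diff(pv_inflation_model(p, v)) / np.diff(v)
        assert np.all(np.diff(slopes) >= -1e-9)

    def test_deflation_below_inflation_and_continuous(self):
        p = LungParams(peep=10, e1=1.2, v_el=6, alpha=0.4, hysteresis=1.5)
        v = np.linspace(0, 14, 100)
        d = pv_deflation_model(p, v)
        assert np.all(d <= pv_inflation_model(p, v) + 1e-12)
        assert d[0] == pytest.approx(10.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LungParams(peep=-1, e1=1, v_el=4)
        with pytest.raises(ValueError):
            LungParams(peep=5, e1=0, v_el=4)
        with pytest.raises(ValueError):
            LungParams(peep=5, e1=1, v_el=4, hysteresis=0.9)


class TestSimulateManeuver:
    def test_noise_free_lies_on_model(self):
        p = LungParams(peep=10, e1=0.9, v_el=7, alpha=0.3, sigma=0.0)
        m = simulate_maneuver(p, v_max=14, step=1)
        assert m.n == 15
        np.testing.assert_allclose(m.p, pv_inflation_model(p, m.v), rtol=0, atol=1e-12)

    def test_noise_free_short_grid_pressures(self):
        p = LungParams(peep=8, e1=1.5, v_el=2.5, alpha=0.4, sigma=0.0)
        m = simulate_maneuver(p, v_max=4, step=1)
        expected = [pv_inflation_model(p, v) for v in (0, 1, 2, 3, 4)]
        np.testing.assert_allclose(m.p, expected)
        assert m.p[0] == pytest.approx(8.0)

    def test_seeded_determinism_bitwise(self):
        p = LungParams(peep=10, e1=1.0, v_el=6, alpha=0.4, sigma=0.3)
        a = simulate_maneuver(p, seed=7)
        b = simulate_maneuver(p, seed=7)
        assert a == b
        c = simulate_maneuver(p, seed=8)
        assert not np.array_equal(a.p, c.p)

    def test_deflation_uses_hysteresis_elastance(self):
        p = LungParams(peep=10, e1=1.2, v_el=6, alpha=0.0, sigma=0.0, hysteresis=1.5)
        m = simulate_maneuver(p, limb="deflation")
        slopes = np.diff(m.p) / np.diff(m.v)
        assert slopes[0] == pytest.approx(1.2 / 1.5)

    def test_non_integer_step_count_rejected(self):
        p = LungParams(peep=10, e1=1.0, v_el=6)
        with pytest.raises(ValueError):
            simulate_maneuver(p, v_max=14, step=3)

    def test_too_short_maneuver_rejected(self):
        p = LungParams(peep=10, e1=1.0, v_el=6)
        with pytest.raises(ValueError):
            simulate_maneuver(p, v_max=2, step=1)


class TestPVManeuverContainer:
    def test_from_points_sorts(self):
        m = PVManeuver.from_points("s", "inflation", [(2, 12), (0, 10), (1, 11), (4, 18), (3, 14)], 1)
        assert list(m.v) == [0, 1, 2, 3, 4]

    def test_rejects_duplicate_volumes(self):
        with pytest.raises(ValueError):
            PVManeuver("s", "inflation", np.array([0, 1, 1, 2, 3.0]),
                       np.arange(5.0), 1.0)

    def test_rejects_nonzero_start(self):
        with pytest.raises(ValueError):
            PVManeuver("s", "inflation", np.array([1, 2, 3, 4, 5.0]), np.arange(5.0), 1.0)


class TestOutcomeCalibration:
    def test_lognormal_median_and_p75(self):
        rng = np.random.default_rng(1)
        spec = ArmSpec(median=270, p25=230, p75=340)
        d = draw_outcome(spec, "lognormal", rng, size=100_000)
        assert np.median(d) == pytest.approx(270, rel=0.02)
        assert np.percentile(d, 75) == pytest.approx(340, rel=0.05)
        # the lower quartile is the distribution's own implied one
        mu, sigma = lognormal_shape(270, 340)
        assert np.percentile(d, 25) == pytest.approx(math.exp(mu - 0.6744897501960817 * sigma),
                                                     rel=0.05)

    def test_degenerate_spread_collapses_to_median(self):
        rng = np.random.default_rng(2)
        spec = ArmSpec(median=42.0, p25=42.0, p75=42.0)
        d = draw_outcome(spec, "lognormal", rng, size=100)
        np.testing.assert_allclose(d, 42.0)
        d = draw_outcome(spec, "normal", rng, size=100)
        np.testing.assert_allclose(d, 42.0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ArmSpec(median=5, p25=6, p75=7)  # median below p25
        with pytest.raises(ValueError):
            OutcomeSpec("x", "lognormal", {"standard": ArmSpec(0.0, 0.0, 1.0),
                                           "individualized": ArmSpec(1, 1, 2)})
        with pytest.raises(ValueError):
            OutcomeSpec("x", "weird", {})


class TestSimulateCohort:
    def test_counts_and_arms(self):
        recs = simulate_cohort(default_cohort_config(seed=3))
        assert len(recs) == 20
        arms = [r.arm for r in recs]
        assert arms.count("standard") == 10 and arms.count("individualized") == 10

    def test_full_determinism(self):
        a = simulate_cohort(default_cohort_config(seed=11))
        b = simulate_cohort(default_cohort_config(seed=11))
        for ra, rb in zip(a, b):
            assert ra.outcomes == rb.outcomes
            assert ra.inflation == rb.inflation
            assert ra.deflation == rb.deflation
            assert ra.ali_ratings == rb.ali_ratings

    def test_cell_fractions_sum_to_100(self):
        for r in simulate_cohort(default_cohort_config(seed=5)):
            total = sum(v for k, v in r.outcomes.items() if k.endswith("_pct"))
            assert total == pytest.approx(100.0)

    def test_ordinal_ratings_within_scale(self):
        for r in simulate_cohort(default_cohort_config(seed=6)):
            for items in r.ali_ratings.values():
                assert set(items) == {
                    "congestion", "hemorrhage", "neutrophil_infiltration", "hyaline_membrane"
                }
                assert all(0 <= s <= 4 and isinstance(s, int) for s in items.values())

    def test_outcome_spec_for_missing_arm_rejected(self):
        spec = OutcomeSpec("x", "normal", {"standard": ArmSpec(1, 0, 2)})
        with pytest.raises(ValueError):
            CohortConfig(outcomes=[spec])
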