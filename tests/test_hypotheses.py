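import numpy as np
import pytest
from scipy.integrate import quad

import gridhex as gx
from gridhex import hexmetrics
from gridhex.hypotheses import (
    AdaptationParams,
    ConjunctiveParams,
    adapted_rate_series,
    assign_hd_preferences,
    hd_factor,
    population_activity,
)


class TestHDFactor:
    def test_zero_concentration_is_flat(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 100)
        assert np.allclose(hd_factor(theta, 0.7, 0.0), 1.0)

    @pytest.mark.parametrize("kappa", [1.0, 4.0, 50.0])
    def test_circular_mean_is_one(self, kappa):
        val, _ = quad(lambda t: hd_factor(t, 0.0, kappa), 0, 2 * np.pi)
        assert val / (2 * np.pi) == pytest.approx(1.0, rel=1e-9)

    def test_tuning_width_large_kappa(self):
        # 1/sqrt(kappa) approximates the angular SD for sharp tuning
        width = np.rad2deg(1 / np.sqrt(50.0))
        assert width == pytest.approx(8.1, abs=0.1)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            hd_factor(0.0, 0.0, -1.0)


class TestAssignHDPreferences:
    def test_zero_fraction(self):
        is_conj, mu = assign_hd_preferences(100, p_c=0.0, seed=0)
        assert not is_conj.any()
        assert np.isnan(mu).all()

    def test_zero_jitter_aligns_to_grid_axes(self):
        _, mu = assign_hd_preferences(500, p_c=1.0, sigma_c=0.0, seed=1)
        k = mu / (np.pi / 3)
        assert np.allclose(k, np.round(k))
        assert set(np.round(k).astype(int)) <= {0, 1, 2, 3, 4, 5}

    def test_one_third_of_1024(self):
        is_conj, _ = assign_hd_preferences(1024, p_c=1.0 / 3.0, seed=2)
        assert is_conj.sum() in (341, 342)

    def test_conjunctive_count_rounds(self):
        is_conj, _ = assign_hd_preferences(10, p_c=0.26, seed=3)
        assert is_conj.sum() == 3


class TestAdaptation:
    def test_zero_weight_is_identity(self, rng):
        raw = rng.uniform(0, 8, 500)
        out = adapted_rate_series(raw, AdaptationParams(tau_r=3.0, w_r=0.0), dt=0.01)
        assert np.allclose(out, raw)

    def test_constant_input_steady_state_half(self):
        raw = np.full(20_000, 6.0)
        out = adapted_rate_series(raw, AdaptationParams(tau_r=1.0, w_r=1.0), dt=0.01)
        assert out[-1] == pytest.approx(3.0, rel=1e-3)

    def test_output_never_exceeds_input(self, rng):
        raw = rng.uniform(0, 8, (1000, 4))
        out = adapted_rate_series(raw, AdaptationParams(tau_r=2.0, w_r=0.8), dt=0.01)
        assert np.all(out <= raw + 1e-12)
        assert np.all(out >= 0)

    def test_monotone_in_weight(self, rng):
        raw = np.abs(np.sin(np.linspace(0, 20, 2000))) * 8
        outs = [
            adapted_rate_series(raw, AdaptationParams(tau_r=3.0, w_r=w), dt=0.01)
            for w in (0.2, 0.5, 1.0)
        ]
        assert np.all(outs[0] >= outs[1] - 1e-12)
        assert np.all(outs[1] >= outs[2] - 1e-12)

    def test_reset_marks_restart_adaptation(self):
        raw = np.full(400, 8.0)
        marks = np.zeros(400, dtype=bool)
        marks[200] = True
        out = adapted_rate_series(
            raw, AdaptationParams(tau_r=0.5, w_r=1.0), dt=0.01, reset_marks=marks
        )
        # right after the reset the rate recovers to the unadapted value
        assert out[200] == pytest.approx(8.0)
        assert out[199] < 6.0

    def test_carry_over_ignores_resets(self):
        raw = np.full(400, 8.0)
        marks = np.zeros(400, dtype=bool)
        marks[200] = True
        params = AdaptationParams(tau_r=0.5, w_r=1.0, carry_over=True)
        out = adapted_rate_series(raw, params, dt=0.01, reset_marks=marks)
        assert out[200] < 6.0

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError):
            adapted_rate_series(np.ones(10), AdaptationParams(tau_r=0.005), dt=0.01)

    def test_coarse_dt_warns(self):
        with pytest.warns(UserWarning):
            adapted_rate_series(np.ones(10), AdaptationParams(tau_r=0.05), dt=0.01)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AdaptationParams(tau_r=-1.0)
        with pytest.raises(ValueError):
            AdaptationParams(w_r=1.5)


class TestPopulationActivity:
    def test_mean_activity_matches_spatial_mean(self, small_population):
        # direction-balanced star walk, no tuning: A0 ~ N * 5*Amax/32
        traj = gx.star_walk(n_angles=360, r_max=300.0, v=10.0, dt=0.1)
        prof = population_activity(traj, small_population)
        expected = small_population.n_cells * 5 * 8.0 / 32
        assert prof.mean_activity.mean() == pytest.approx(expected, rel=0.05)

    def test_numeric_route_matches_analytic(self, small_star, tiny_population):
        pa = population_activity(small_star, tiny_population, method="analytic")
        pn = population_activity(small_star, tiny_population, method="numeric")
        ha = hexmetrics.neural_hexasymmetry(pa)
        hn = hexmetrics.neural_hexasymmetry(pn)
        # midpoint-rule error at dt = 0.05 (0.5 cm substeps)
        assert pa.mean_activity.mean() == pytest.approx(
            pn.mean_activity.mean(), rel=2e-5
        )
        assert ha == pytest.approx(hn, rel=1e-3)

    def test_zero_conjunctive_fraction_equals_plain(self, small_star, tiny_population):
        plain = population_activity(small_star, tiny_population)
        conj = population_activity(
            small_star,
            tiny_population,
            conjunctive=ConjunctiveParams(kappa_c=50.0, p_c=0.0),
            seed=0,
        )
        assert np.allclose(plain.mean_activity, conj.mean_activity)

    def test_conjunctive_orientation_on_grid_axes(self, small_star):
        pop = gx.GridPopulation(phases=gx.sample_phases(128, seed=11))
        prof = population_activity(
            small_star,
            pop,
            conjunctive=ConjunctiveParams(kappa_c=50.0, sigma_c=0.0, p_c=1.0),
            seed=12,
        )
        ori = hexmetrics.apparent_orientation(prof)
        assert min(ori, 60.0 - ori) < 1.0

    def test_adaptation_orientation_shifted_30_degrees(self):
        traj = gx.star_walk(n_angles=120, r_max=300.0, v=10.0, dt=0.05)
        pop = gx.GridPopulation(phases=gx.sample_phases(128, seed=13))
        prof = population_activity(traj, pop, adaptation=AdaptationParams())
        assert hexmetrics.apparent_orientation(prof) == pytest.approx(30.0, abs=1.0)

    def test_adaptation_reduces_activity(self, tiny_population):
        traj = gx.star_walk(n_angles=24, r_max=60.0, v=10.0, dt=0.05)
        plain = population_activity(traj, tiny_population, method="numeric")
        adapted = population_activity(
            traj, tiny_population, adaptation=AdaptationParams(tau_r=3.0, w_r=1.0)
        )
        assert np.all(adapted.mean_activity <= plain.mean_activity + 1e-9)

    def test_wide_tuning_kills_hexasymmetry(self, small_star):
        # kappa_c -> 0 approaches flat tuning and H -> 0
        pop = gx.GridPopulation(phases=gx.sample_phases(256, seed=14))
        hs = []
        for kappa in (50.0, 1.0, 1e-6):
            prof = population_activity(
                small_star,
                pop,
                conjunctive=ConjunctiveParams(kappa_c=kappa, sigma_c=0.0, p_c=1.0),
                hd_assignment=assign_hd_preferences(256, 1.0, 0.0, seed=15),
            )
            hs.append(hexmetrics.neural_hexasymmetry(prof))
        assert hs[0] > hs[1] > hs[2]
        assert hs[2] < 0.05 * hs[0]

    def test_adaptation_drive_variants_differ(self):
        traj = gx.star_walk(n_angles=12, r_max=60.0, v=10.0, dt=0.05)
        pop = gx.GridPopulation(phases=np.zeros((1, 2)))
        out = {}
        for drive in ("adapted", "raw"):
            prof = population_activity(
                traj, pop, adaptation=AdaptationParams(drive=drive)
            )
            out[drive] = prof.mean_activity.mean()
        assert out["adapted"] != pytest.approx(out["raw"], rel=1e-3)
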