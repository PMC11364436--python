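import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gridhex.hexmetrics import (
    DirectionalProfile,
    apparent_orientation,
    circular_linear_hexasymmetry,
    glm_binning_hexasymmetry,
    glm_hexasymmetry,
    hypothesis_test,
    neural_hexasymmetry,
    path_contribution,
    path_hexasymmetry,
)

DENSE = np.deg2rad(np.arange(0.0, 360.0, 0.5))


def sinusoid_profile(c=4.0, phi0_deg=12.0, offset=10.0, directions=DENSE):
    act = offset + 2 * c * np.cos(6 * (directions - np.deg2rad(phi0_deg)))
    return DirectionalProfile(directions=directions, mean_activity=act)


class TestNeuralHexasymmetry:
    def test_constant_profile_has_no_hexasymmetry(self):
        prof = DirectionalProfile(DENSE, np.full_like(DENSE, 3.0))
        assert neural_hexasymmetry(prof) < 1e-12

    def test_pure_sixth_harmonic_gives_half_amplitude(self):
        prof = DirectionalProfile(DENSE, 5.0 * (1 + np.cos(6 * DENSE)))
        assert neural_hexasymmetry(prof) == pytest.approx(2.5, rel=1e-12)

    def test_single_direction_returns_activity(self):
        prof = DirectionalProfile(np.array([0.7]), np.array([4.2]))
        assert neural_hexasymmetry(prof) == pytest.approx(4.2)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            DirectionalProfile(np.array([]), np.array([]))

    @given(
        act=hnp.arrays(
            float,
            st.integers(3, 60),
            elements=st.floats(0.0, 100.0),
        ),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=60, deadline=None)
    def test_h_bounded_by_mean_activity(self, act, seed):
        # triangle inequality for nonnegative activities
        rng = np.random.default_rng(seed)
        th = rng.uniform(0, 2 * np.pi, act.size)
        prof = DirectionalProfile(th, act)
        assert neural_hexasymmetry(prof) <= act.mean() + 1e-9

    def test_invariant_under_joint_rotation(self):
        prof = sinusoid_profile()
        rot = np.deg2rad(17.0)
        rotated = DirectionalProfile(
            prof.directions + rot,
            10.0 + 8.0 * np.cos(6 * (prof.directions + rot - np.deg2rad(12.0) - rot)),
        )
        assert neural_hexasymmetry(rotated) == pytest.approx(
            neural_hexasymmetry(prof), rel=1e-9
        )


class TestPathHexasymmetry:
    def test_uniform_directions(self):
        assert path_hexasymmetry(np.deg2rad(np.arange(360.0))) < 1e-10

    def test_single_direction(self):
        assert path_hexasymmetry(np.full(10, 1.1)) == pytest.approx(1.0)

    def test_sixty_degree_multiples(self):
        assert path_hexasymmetry(np.deg2rad(np.arange(0, 360, 60))) == pytest.approx(1.0)

    def test_contribution(self):
        prof = DirectionalProfile(np.full(5, 0.3), np.full(5, 7.0))
        assert path_contribution(prof) == pytest.approx(7.0)
        uniform = DirectionalProfile(DENSE, np.full_like(DENSE, 7.0))
        assert path_contribution(uniform) < 1e-9


class TestApparentOrientation:
    def test_recovers_phase(self):
        prof = sinusoid_profile(phi0_deg=23.0)
        assert apparent_orientation(prof) == pytest.approx(23.0, abs=1e-6)

    def test_undefined_for_flat_profile(self):
        prof = DirectionalProfile(DENSE, np.full_like(DENSE, 1.0))
        with pytest.raises(ValueError):
            apparent_orientation(prof)


class TestHypothesisTest:
    def test_identical_samples_give_p_one(self):
        x = np.arange(10.0)
        res = hypothesis_test(x, x)
        assert res.p == 1.0

    def test_separated_groups_significant(self):
        res = hypothesis_test(np.arange(20.0) + 100.0, np.arange(20.0))
        assert res.U == 0.0
        assert res.p < 1e-6

    def test_u_bounds(self, rng):
        a, b = rng.normal(size=(2, 15))
        res = hypothesis_test(a, b)
        assert 0 <= res.U <= 15 * 15

    def test_null_behavior(self):
        # same distribution: p rarely below 0.05
        rng = np.random.default_rng(77)
        rejections = sum(
            hypothesis_test(rng.normal(size=30), rng.normal(size=30)).p < 0.05
            for _ in range(100)
        )
        assert rejections < 15

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hypothesis_test([1.0], [2.0, 3.0])


class TestGLMMetrics:
    def test_recovers_orientation_and_amplitude(self):
        prof = sinusoid_profile(c=3.0, phi0_deg=17.0)
        fit = glm_hexasymmetry(prof)
        assert np.rad2deg(fit.phi) % 60 == pytest.approx(17.0, abs=1e-6)
        assert fit.H == pytest.approx(3.0, rel=1e-9)

    def test_zero_modulation_scatters_around_zero(self):
        rng = np.random.default_rng(5)
        hs = []
        for _ in range(50):
            prof = DirectionalProfile(
                rng.uniform(0, 2 * np.pi, 400), rng.uniform(9, 11, 400)
            )
            hs.append(glm_hexasymmetry(prof).H)
        assert abs(np.mean(hs)) < 0.05
        assert min(hs) < 0 < max(hs)

    def test_mismatched_halves_give_negative_h(self):
        # first half oriented at 0 deg, second half in antiphase (30 deg)
        th = DENSE
        half = len(th) // 2
        act = np.concatenate(
            [
                10 + 4 * np.cos(6 * th[:half]),
                10 + 4 * np.cos(6 * (th[half:] - np.deg2rad(30.0))),
            ]
        )
        fit = glm_hexasymmetry(DirectionalProfile(th, act))
        assert fit.H < 0

    def test_rank_deficient_design_rejected(self):
        prof = DirectionalProfile(np.full(10, 0.5), np.arange(10.0))
        with pytest.raises(ValueError):
            glm_hexasymmetry(prof)

    def test_binning_signs(self):
        assert glm_binning_hexasymmetry(sinusoid_profile(c=3.0, phi0_deg=0.0)).H > 0
        # anti-aligned: peaks at 30 deg relative to the first-half estimate
        th = DENSE
        half = len(th) // 2
        act = np.concatenate(
            [
                10 + 4 * np.cos(6 * th[:half]),
                10 - 4 * np.cos(6 * th[half:]),
            ]
        )
        assert glm_binning_hexasymmetry(DirectionalProfile(th, act)).H < 0
        flat = DirectionalProfile(DENSE, np.full_like(DENSE, 2.0))
        assert abs(glm_binning_hexasymmetry(flat).H) < 1e-9


class TestCircularLinear:
    def test_half_amplitude_on_dense_directions(self):
        fit = circular_linear_hexasymmetry(sinusoid_profile(c=3.0), seed=0)
        assert fit.H == pytest.approx(3.0, rel=1e-6)

    def test_agrees_with_harmonic_metric_on_pure_signal(self):
        prof = sinusoid_profile(c=2.0, phi0_deg=41.0)
        fit = circular_linear_hexasymmetry(prof, seed=1)
        assert fit.H == pytest.approx(neural_hexasymmetry(prof), rel=1e-6)

    def test_strong_signal_gives_large_z(self):
        # directions in random temporal order, as on a random walk: circular
        # shifts then decorrelate activity from direction
        rng = np.random.default_rng(31)
        th = rng.uniform(0, 2 * np.pi, 2000)
        prof = DirectionalProfile(th, 10.0 + 6.0 * np.cos(6 * th))
        fit = circular_linear_hexasymmetry(prof, seed=2)
        assert fit.z > 5.0

    def test_no_modulation_gives_small_mean_z(self):
        rng = np.random.default_rng(9)
        zs = []
        for s in range(30):
            prof = DirectionalProfile(
                rng.uniform(0, 2 * np.pi, 300), rng.uniform(9, 11, 300)
            )
            zs.append(circular_linear_hexasymmetry(prof, n_surrogates=50, seed=s).z)
        assert abs(np.mean(zs)) < 0.5

    def test_few_surrogates_warn(self):
        with pytest.warns(UserWarning):
            circular_linear_hexasymmetry(sinusoid_profile(), n_surrogates=5, seed=0)
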