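import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from echoray import (
    AttenuationVolume,
    Ray,
    acoustic_impedance,
    attenuation_ratio,
    diffuse_reflection,
    gradient_reflection,
    specular_reflection,
    transmittance,
)
from echoray.errors import DomainError

finite_pos = st.floats(min_value=1e-6, max_value=1e9, allow_nan=False, allow_infinity=False)


class TestImpedance:
    def test_zero_density_gives_zero(self):
        assert acoustic_impedance(0.0, 1540.0) == 0.0

    def test_soft_tissue_value(self):
        assert acoustic_impedance(1000.0, 1540.0) == pytest.approx(1.54e6)

    @given(rho=finite_pos, v=finite_pos)
    @settings(derandomize=True, max_examples=50)
    def test_homogeneity_in_density(self, rho, v):
        assert acoustic_impedance(2 * rho, v) == pytest.approx(2 * acoustic_impedance(rho, v))

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            acoustic_impedance(-1.0, 1540.0)


class TestSpecularReflection:
    def test_matched_impedance_reflects_nothing(self):
        assert specular_reflection(1.5e6, 1.5e6) == 0.0

    def test_three_to_one_mismatch(self):
        # ((3-1)/(3+1))^2 = 0.25
        assert specular_reflection(1.0, 3.0) == pytest.approx(0.25)

    @given(q1=finite_pos, q2=finite_pos)
    @settings(derandomize=True, max_examples=100)
    def test_symmetric_and_in_range(self, q1, q2):
        k = specular_reflection(q1, q2)
        assert k == specular_reflection(q2, q1)
        assert 0 <= k < 1

    def test_zero_sum_rejected(self):
        with pytest.raises(DomainError):
            specular_reflection(0.0, 0.0)


class TestDiffuseReflection:
    def test_normal_incidence_reduces_to_specular(self):
        for n in (0.0, 1.0, 3.5):
            assert diffuse_reflection(1.0, 3.0, 0.0, n) == pytest.approx(
                specular_reflection(1.0, 3.0)
            )

    def test_grazing_incidence_reflects_nothing(self):
        assert diffuse_reflection(1.0, 3.0, np.pi / 2, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_sixty_degree_quadratic_lobe(self):
        # cos^2(pi/3) * 0.25 = 0.0625
        assert diffuse_reflection(1.0, 3.0, np.pi / 3, 2.0) == pytest.approx(0.0625)

    @given(
        theta=st.floats(min_value=0.0, max_value=np.pi / 2 - 1e-6),
        dtheta=st.floats(min_value=0.0, max_value=0.5),
        n=st.floats(min_value=0.0, max_value=5.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_nonincreasing_in_angle(self, theta, dtheta, n):
        hi = min(theta + dtheta, np.pi / 2)
        assert diffuse_reflection(1.0, 4.0, theta, n) >= diffuse_reflection(1.0, 4.0, hi, n) - 1e-12

    def test_angle_outside_quadrant_rejected(self):
        with pytest.raises(DomainError):
            diffuse_reflection(1.0, 3.0, -0.1, 1.0)


class TestGradientReflection:
    def test_uniform_volume_reflects_nothing(self, uniform_volume):
        assert gradient_reflection(uniform_volume, (4.0, 4.0, 8.0), (0, 0, 1.0)) == 0.0

    def test_direction_orthogonal_to_interface_normal(self, ramp_volume):
        # gradient points along +z; a beam along x sees no reflection
        assert gradient_reflection(ramp_volume, (4.0, 4.0, 10.0), (1.0, 0, 0)) == 0.0

    def test_back_facing_interface_clamped_to_zero(self, ramp_volume):
        assert gradient_reflection(ramp_volume, (4.0, 4.0, 10.0), (0, 0, -1.0)) == 0.0

    def test_aligned_gradient_at_max_strength(self):
        # |grad| = max_delta and d parallel to grad with n=1 -> 1 * (1/2)^1 = 0.5
        # ramp 0..10 over 1 mm: |grad| = 10/mm equals max_delta = 10
        values = np.tile(np.linspace(0.0, 10.0, 11), (8, 8, 1))
        vol = AttenuationVolume(values, spacing=(1.0, 1.0, 0.1))
        r = gradient_reflection(vol, (4.0, 4.0, 0.5), (0, 0, 1.0), n=1.0)
        assert r == pytest.approx(0.5)

    def test_outside_position_rejected(self, uniform_volume):
        with pytest.raises(DomainError):
            gradient_reflection(uniform_volume, (100.0, 0.0, 0.0), (0, 0, 1.0))


class TestTransmittance:
    def test_homogeneous_region_transmits_fully(self, uniform_volume):
        assert transmittance(uniform_volume, (4.0, 4.0, 8.0)) == 1.0

    def test_half_normalised_gradient(self, ramp_volume):
        # |grad| = 0.5/mm, max_delta = 10 -> t = 1 - (0.5/20)^2
        t = transmittance(ramp_volume, (4.0, 4.0, 10.0))
        assert t == pytest.approx(1.0 - (0.5 / 20.0) ** 2)

    def test_consistency_with_reflection_normaliser(self, ramp_volume):
        # (|grad|/(2 max d))^2 == 1 - t, and equals R for aligned beam at n=1
        pos = (4.0, 4.0, 10.0)
        t = transmittance(ramp_volume, pos)
        r = gradient_reflection(ramp_volume, pos, (0, 0, 1.0), n=1.0)
        # aligned beam: cosine = 1, so R = |grad|/(2 max d) and R^2 = 1 - t
        assert r**2 == pytest.approx(1.0 - t, abs=1e-12)


class TestAttenuationRatio:
    def test_homogeneous_volume_never_attenuates(self, uniform_volume):
        ray = Ray((4.0, 4.0, 0.0), (0, 0, 1.0), 0.25)
        for depth in (0.0, 3.0, 12.0):
            assert attenuation_ratio(uniform_volume, ray, depth) == pytest.approx(1.0)

    def test_zero_depth_is_identity(self, ramp_volume):
        ray = Ray((4.0, 4.0, 0.0), (0, 0, 1.0), 0.25)
        assert attenuation_ratio(ramp_volume, ray, 0.0) == 1.0

    def test_constant_gradient_matches_closed_form(self, ramp_volume):
        # integrand constant: (g/(2 max))^2 with g=0.5, max=10 -> exp(-(1/40)^2 L)
        ray = Ray((4.0, 4.0, 0.0), (0, 0, 1.0), 0.25)
        L = 15.0
        expected = np.exp(-((0.5 / 20.0) ** 2) * L)
        assert attenuation_ratio(ramp_volume, ray, L) == pytest.approx(expected, rel=1e-9)

    def test_matches_hundredfold_finer_integration(self, two_layer_volume):
        coarse = Ray((4.0, 4.0, 0.0), (0, 0, 1.0), 0.5)
        fine = Ray((4.0, 4.0, 0.0), (0, 0, 1.0), 0.005)
        a = attenuation_ratio(two_layer_volume, coarse, 14.0)
        b = attenuation_ratio(two_layer_volume, fine, 14.0)
        assert a == pytest.approx(b, rel=0.01)

    def test_composition_over_consecutive_segments(self, two_layer_volume):
        ray = Ray((4.0, 4.0, 0.0), (0, 0, 1.0), 0.25)
        full = attenuation_ratio(two_layer_volume, ray, 14.0)
        first = attenuation_ratio(two_layer_volume, ray, 6.0)
        cont = Ray((4.0, 4.0, 6.0), (0, 0, 1.0), 0.25)
        second = attenuation_ratio(two_layer_volume, cont, 8.0)
        assert full == pytest.approx(first * second, rel=1e-9)

    @given(d1=st.floats(min_value=0.0, max_value=14.0), d2=st.floats(min_value=0.0, max_value=14.0))
    @settings(
        derandomize=True,
        max_examples=50,
        suppress_health_check=[HealthCheck.function_scoped_fixture],  # volume is read-only
    )
    def test_nonincreasing_in_depth(self, two_layer_volume, d1, d2):
        lo, hi = sorted((d1, d2))
        ray = Ray((4.0, 4.0, 0.0), (0, 0, 1.0), 0.25)
        assert attenuation_ratio(two_layer_volume, ray, lo) >= attenuation_ratio(
            two_layer_volume, ray, hi
        ) - 1e-12

    def test_segment_leaving_volume_names_exit_depth(self, uniform_volume):
        ray = Ray((4.0, 4.0, 0.0), (0, 0, 1.0), 0.25)
        with pytest.raises(DomainError, match="exits the volume"):
            attenuation_ratio(uniform_volume, ray, 100.0)


class TestRangeProperties:
    """Outputs stay in their stated ranges on random noisy volumes."""

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_kernels_in_range_on_random_volumes(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.1, 5.0, size=(10, 10, 10))
        vol = AttenuationVolume(values, spacing=(0.5, 0.5, 0.5))
        pos = rng.uniform(0.5, 4.0, size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        r = gradient_reflection(vol, pos, d, n=1.0)
        t = transmittance(vol, pos)
        assert 0 <= r <= 1
        assert 0 <= t <= 1
        ray = Ray((2.0, 2.0, 0.5), (0, 0, 1.0), 0.2)
        a = attenuation_ratio(vol, ray, 3.5)
        assert 0 < a <= 1
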