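"""Fluence kernel of a cylindrical diffuser in a turbid medium."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from ipdtplan import (
    CylindricalDiffuser,
    OpticalProperties,
    cdf_fluence_rate,
    dose_from_fluence,
    effective_attenuation,
    total_dose,
)


def line_source_fluence(h: float, z: float, length: float, s: float, props) -> float:
    """Independent oracle: fine quadrature of the continuous line-source integral."""
    mu = effective_attenuation(props)
    pref = 3.0 * s * props.musp / (4.0 * np.pi)

    def integrand(x):
        r = np.hypot(x - z, h)
        return np.exp(-mu * r) / r

    val, _ = quad(integrand, -length / 2, length / 2, limit=200)
    return pref * val


class TestEffectiveAttenuation:
    def test_zero_absorption_gives_zero(self):
        assert effective_attenuation(OpticalProperties(mua=0.0, musp=16.0)) == 0.0

    def test_forced_unit_value(self):
        # 3 * (1/3) * (1/3 + 2/3) = 1 exactly
        with pytest.warns(UserWarning):  # musp < 10 mua: diffusion validity warning
            props = OpticalProperties(mua=1 / 3, musp=2 / 3)
        assert effective_attenuation(props) == pytest.approx(1.0, abs=1e-15)

    def test_breast_tumor_value_matches_closed_form(self, breast):
        # frozen from arbitrary-precision evaluation of sqrt(3*0.085*16.085)
        assert effective_attenuation(breast) == pytest.approx(
            2.0252592426649976, rel=1e-14
        )

    @pytest.mark.filterwarnings("ignore::UserWarning")  # scattering-dominance check
    @given(
        mua=st.floats(0.01, 1.0),
        musp=st.floats(10.0, 100.0),
        bump=st.floats(1e-3, 1.0),
    )
    def test_strictly_increasing_in_each_coefficient(self, mua, musp, bump):
        base = effective_attenuation(OpticalProperties(mua, musp))
        assert effective_attenuation(OpticalProperties(mua + bump, musp)) > base
        assert effective_attenuation(OpticalProperties(mua, musp + bump)) > base

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            OpticalProperties(mua=-0.1, musp=16.0)
        with pytest.raises(ValueError):
            OpticalProperties(mua=0.1, musp=0.0)


class TestDiffuserValidation:
    def test_even_point_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            CylindricalDiffuser(center=(0, 0, 0), length=1.0, n_points=100)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            CylindricalDiffuser(center=(0, 0, 0), length=0.0)

    def test_power_beyond_hardware_limit_rejected(self):
        with pytest.raises(ValueError):
            CylindricalDiffuser(center=(0, 0, 0), length=1.0, linear_power=501.0)

    def test_elemental_segment_length(self):
        f = CylindricalDiffuser(center=(0, 0, 0), length=5.0, n_points=101)
        assert f.dx == pytest.approx(0.05)
        assert len(f.source_points()) == 101
        # midpoint source sits exactly at the fiber centre
        assert np.allclose(f.source_points()[50], [0, 0, 0])

    def test_coarse_discretization_warns(self):
        with pytest.warns(UserWarning, match="dx"):
            CylindricalDiffuser(center=(0, 0, 0), length=6.0, n_points=101)


class TestFluenceRate:
    @pytest.mark.parametrize("h", [0.17, 0.5, 1.0, 2.0, 3.0])
    def test_matches_line_integral_quadrature(self, breast, h):
        """For node-scale diffusers the sum tracks the line integral to < 0.5%."""
        fiber = CylindricalDiffuser(center=(0, 0, 0), length=5.0, linear_power=65.0)
        got = cdf_fluence_rate(fiber, np.array([h, 0.0, 0.0]), breast)
        want = line_source_fluence(h, 0.0, fiber.length, fiber.linear_power, breast)
        assert got == pytest.approx(want, rel=5e-3)

    @pytest.mark.parametrize("h", [0.2, 0.5, 2.0])
    def test_sum_is_endpoint_weighted_quadrature(self, breast, h):
        """Sharp oracle: the N-point sum equals the line integral plus the
        half-weight endpoint excess of its l/(N-1) normalization."""
        fiber = CylindricalDiffuser(center=(0, 0, 0), length=0.5, linear_power=65.0)
        mu = effective_attenuation(breast)
        pref = 3.0 * fiber.linear_power * breast.musp / (4.0 * np.pi)
        integral = line_source_fluence(h, 0.0, fiber.length, fiber.linear_power, breast)
        r_end = np.hypot(fiber.length / 2, h)
        excess = pref * fiber.dx * np.exp(-mu * r_end) / r_end
        got = cdf_fluence_rate(fiber, np.array([h, 0.0, 0.0]), breast)
        assert got == pytest.approx(integral + excess, rel=2e-4)
        # the overshoot against the bare integral never exceeds N/(N-1)
        assert 1.0 < got / integral < fiber.n_points / (fiber.n_points - 1)

    def test_far_field_reduces_to_point_source(self, breast):
        """At distances >> length the fiber behaves as a point source of power s*l."""
        fiber = CylindricalDiffuser(center=(0, 0, 0), length=0.5, linear_power=65.0)
        h = 20 * fiber.length
        mu = effective_attenuation(breast)
        point = (
            3.0 * fiber.linear_power * fiber.length * breast.musp
            / (4.0 * np.pi * h)
            * np.exp(-mu * h)
        ) * fiber.n_points / (fiber.n_points - 1)
        got = cdf_fluence_rate(fiber, np.array([h, 0.0, 0.0]), breast)
        assert got == pytest.approx(point, rel=1e-2)

    def test_zero_power_gives_zero(self, breast):
        fiber = CylindricalDiffuser(center=(0, 0, 0), length=1.0, linear_power=0.0)
        assert cdf_fluence_rate(fiber, np.array([0.5, 0, 0]), breast) == 0.0

    @given(scale=st.floats(0.1, 7.0))
    def test_linear_in_power(self, breast, scale):
        fiber = CylindricalDiffuser(center=(0, 0, 0), length=1.0, linear_power=50.0)
        pt = np.array([0.4, 0.1, 0.2])
        base = cdf_fluence_rate(fiber, pt, breast)
        scaled = cdf_fluence_rate(fiber.with_power(50.0 * scale), pt, breast)
        assert scaled == pytest.approx(scale * base, rel=1e-12)

    def test_midplane_reflection_symmetry(self, breast):
        fiber = CylindricalDiffuser(center=(0, 0, 0), length=2.0, linear_power=100.0)
        pts = np.array([[0.3, 0.1, z] for z in (0.25, 0.7, 1.3)])
        mirrored = pts * np.array([1, 1, -1])
        up = cdf_fluence_rate(fiber, pts, breast)
        down = cdf_fluence_rate(fiber, mirrored, breast)
        assert np.allclose(up, down, rtol=1e-12)

    @pytest.mark.parametrize("h", [0.17, 0.5, 2.0])
    def test_point_count_refinement_converged(self, breast, h):
        """With dx <= 0.05 cm the sum no longer depends on N inside the node."""
        pt = np.array([h, 0.0, 0.0])
        coarse = cdf_fluence_rate(
            CylindricalDiffuser((0, 0, 0), length=5.0, linear_power=100.0, n_points=101),
            pt, breast,
        )
        fine = cdf_fluence_rate(
            CylindricalDiffuser((0, 0, 0), length=5.0, linear_power=100.0, n_points=201),
            pt, breast,
        )
        assert abs(coarse - fine) / coarse < 1e-3

    def test_far_field_refinement_drift_bounded_by_normalization(self, breast):
        """Far from a short fiber the value shifts with N only through the
        l/(N-1) endpoint normalization, bounded by 1/(N-1)."""
        pt = np.array([3.0, 0.0, 0.0])
        coarse = cdf_fluence_rate(
            CylindricalDiffuser((0, 0, 0), length=0.5, linear_power=100.0, n_points=101),
            pt, breast,
        )
        fine = cdf_fluence_rate(
            CylindricalDiffuser((0, 0, 0), length=0.5, linear_power=100.0, n_points=201),
            pt, breast,
        )
        assert 0 < (coarse - fine) / coarse < 1.0 / 100.0

    def test_singularity_is_clamped(self, breast):
        fiber = CylindricalDiffuser(center=(0, 0, 0), length=1.0, linear_power=100.0)
        on_source = cdf_fluence_rate(fiber, np.array([0.0, 0.0, 0.0]), breast)
        assert np.isfinite(on_source) and on_source > 0


class TestDose:
    @pytest.mark.parametrize(
        "fluence,time,expected", [(0.0, 150.0, 0.0), (1000 / 3, 150.0, 50.0), (200.0, 150.0, 30.0)]
    )
    def test_fluence_time_product(self, fluence, time, expected):
        assert dose_from_fluence(fluence, time) == pytest.approx(expected)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            dose_from_fluence(100.0, -1.0)

    def test_additive_over_fibers(self, breast):
        fiber = CylindricalDiffuser(center=(0, 0, 0), length=1.0, linear_power=50.0)
        pt = np.array([0.5, 0.0, 0.1])
        single = total_dose([fiber], pt, breast, 150.0)
        doubled = total_dose([fiber, fiber], pt, breast, 150.0)
        assert doubled == pytest.approx(2.0 * single, rel=1e-14)

    def test_fiber_order_commutes(self, breast):
        # swapping the (pose, power) pairs between the two fibers is the same
        # configuration, so the total dose is identical at any point
        a = CylindricalDiffuser(center=(0.3, 0, 0), length=1.0, linear_power=40.0)
        b = CylindricalDiffuser(center=(-0.3, 0, 0), length=1.0, linear_power=90.0)
        pt = np.array([0.1, 0.4, -0.2])
        assert total_dose([a, b], pt, breast, 150.0) == pytest.approx(
            total_dose([b, a], pt, breast, 150.0), rel=1e-14
        )

    def test_all_powers_zero_gives_zero(self, breast):
        fibers = [
            CylindricalDiffuser(center=(0, 0, 0), length=1.0, linear_power=0.0),
            CylindricalDiffuser(center=(0.5, 0, 0), length=0.8, linear_power=0.0),
        ]
        assert total_dose(fibers, np.array([0.2, 0.2, 0.0]), breast, 150.0) == 0.0

    def test_empty_fiber_list_rejected(self, breast):
        with pytest.raises(ValueError):
            total_dose([], np.array([0.1, 0.0, 0.0]), breast, 150.0)
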