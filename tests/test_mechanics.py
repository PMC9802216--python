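"""Ellipse geometry, strain protocol, fiber kinematics, and cell energy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import homeocell as hc
from homeocell.mechanics import (
    CellParams,
    CyclicLoad,
    Microstate,
    area_aspect,
    coeffs_from_geometry,
    cycle_averaged_energy,
    fiber_kinematics,
    geometry_from_coeffs,
    passive_energy,
    substrate_strain,
    suspension_energy,
)


@pytest.fixture
def sfp():
    return hc.SFParams()


@pytest.fixture
def cp():
    return hc.CellParams()


class TestEllipseCoefficients:
    @pytest.mark.parametrize(
        "a1, a2, theta, expected",
        [
            (1.0, 1.0, 0.3, (1.0, 0.0, 1.0)),  # unit circle, any theta
            (2.0, 1.0, 0.0, (0.25, 0.0, 1.0)),
            (2.0, 1.0, np.pi / 2, (1.0, 0.0, 0.25)),  # axes swapped
        ],
    )
    def test_known_coefficients(self, a1, a2, theta, expected):
        assert coeffs_from_geometry(a1, a2, theta) == pytest.approx(expected, abs=1e-12)

    def test_inverse_of_worked_example(self):
        assert geometry_from_coeffs(0.25, 0.0, 1.0) == pytest.approx((2.0, 1.0, 0.0), abs=1e-12)

    def test_circle_tie_break(self):
        a1, a2, theta = geometry_from_coeffs(1.0, 0.0, 1.0)
        assert (a1, a2, theta) == pytest.approx((1.0, 1.0, 0.0))
        assert Microstate(1.0, 0.0, 1.0).is_circular

    def test_degenerate_form_rejected(self):
        with pytest.raises(ValueError):
            geometry_from_coeffs(1.0, 4.0, 1.0)  # 4hl - k^2 < 0
        with pytest.raises(ValueError):
            Microstate(1.0, 4.0, 1.0)

    def test_nonpositive_axes_rejected(self):
        with pytest.raises(ValueError):
            coeffs_from_geometry(0.0, -1.0, 0.0)
        with pytest.raises(ValueError):
            coeffs_from_geometry(1.0, 2.0, 0.0)  # a1 < a2

    @given(
        a2=st.floats(0.3, 3.0),
        ratio=st.floats(1.0 + 1e-6, 4.0),
        theta=st.floats(0.0, np.pi, exclude_max=True),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, a2, ratio, theta):
        a1 = a2 * ratio
        h, k, l = coeffs_from_geometry(a1, a2, theta)
        b1, b2, th = geometry_from_coeffs(h, k, l)
        assert (b1, b2) == pytest.approx((a1, a2), rel=1e-9)
        # orientation defined modulo pi
        assert min(abs(th - theta), np.pi - abs(th - theta)) < 1e-6

    @given(
        a2=st.floats(0.3, 3.0),
        ratio=st.floats(1.0, 4.0),
        theta=st.floats(0.0, np.pi, exclude_max=True),
    )
    @settings(max_examples=100, deadline=None)
    def test_area_identity(self, a2, ratio, theta):
        m = Microstate.from_geometry(a2 * ratio, a2, theta)
        assert m.A_hat * np.sqrt(m.h * m.l - m.k**2 / 4) == pytest.approx(1.0, rel=1e-9)


class TestAreaAspect:
    def test_suspension_circle_area(self):
        m = Microstate.from_geometry(0.96, 0.96, 0.0)
        a_hat, a_s = area_aspect(m)
        assert a_hat == pytest.approx(0.9216, abs=1e-12)
        assert a_s == 1.0

    def test_area_preserving_elongation(self):
        a_hat, a_s = area_aspect(Microstate.from_geometry(2.0, 0.5, 1.0))
        assert (a_hat, a_s) == pytest.approx((1.0, 4.0), rel=1e-12)


class TestSubstrateStrain:
    def test_time_zero(self):
        load = CyclicLoad(eps_amp=0.1, f=1.0, r=0.0, eps_mean=0.02)
        e1, e2, d1, d2 = substrate_strain(0.0, load)
        assert e1 == pytest.approx(0.02)
        assert d1 == pytest.approx(np.pi * load.f * load.eps_amp)
        assert e2 == 0.0 and d2 == 0.0

    def test_quarter_period_peak(self):
        load = CyclicLoad(eps_amp=0.1, f=2.0)
        e1, _, d1, _ = substrate_strain(load.T_p / 4, load)
        assert e1 == pytest.approx(load.eps_mean + load.eps_amp / 2)
        assert d1 == pytest.approx(0.0, abs=1e-12)

    def test_uniaxial_r_zero(self):
        load = CyclicLoad(eps_amp=0.1, f=1.0, r=0.0)
        t = np.linspace(0, 2, 50)
        _, e2, _, d2 = substrate_strain(t, load)
        assert np.all(e2 == 0) and np.all(d2 == 0)

    def test_biaxiality(self):
        load = CyclicLoad(eps_amp=0.1, f=1.0, r=0.5)
        t = np.linspace(0, 1, 17)
        e1, e2, d1, d2 = substrate_strain(t, load)
        assert np.allclose(e2, -0.5 * e1)
        assert np.allclose(d2, -0.5 * d1)

    def test_invalid_load_rejected(self):
        with pytest.raises(ValueError):
            CyclicLoad(eps_amp=-0.1)
        with pytest.raises(ValueError):
            CyclicLoad(r=1.5)


class TestFiberKinematics:
    def test_undeformed_circle_strain_free(self):
        m = Microstate.from_geometry(1.0, 1.0, 0.0)
        load = CyclicLoad(eps_amp=0.1, f=1.0)
        phi = np.linspace(-np.pi / 2, np.pi / 2, 11)
        eps, _ = fiber_kinematics(m, load, 0.0, phi)
        assert np.allclose(eps, 0.0, atol=1e-12)

    def test_major_axis_fiber_stretch(self):
        m = Microstate.from_geometry(1.8, 0.7, 0.0)
        eps, _ = fiber_kinematics(m, CyclicLoad(f=0.0, eps_amp=0.0), 0.0, np.array([0.0]))
        assert eps[0] == pytest.approx(0.8)

    def test_perpendicular_fiber_is_isometric(self):
        """theta = 90 deg, fiber along major axis, uniaxial load: zero rate."""
        m = Microstate.from_geometry(1.8, 0.7, np.pi / 2)
        load = CyclicLoad(eps_amp=0.1, f=1.0, r=0.0)
        for t in np.linspace(0, 1, 7):
            _, rate = fiber_kinematics(m, load, t, np.array([0.0]))
            assert rate[0] == pytest.approx(0.0, abs=1e-12)

    def test_max_contraction_rate(self):
        """theta = 0, fiber at phi = 0, half period: rate = -pi f eps_amp."""
        m = Microstate.from_geometry(1.8, 0.7, 0.0)
        load = CyclicLoad(eps_amp=0.1, f=1.0, r=0.0)
        _, rate = fiber_kinematics(m, load, load.T_p / 2, np.array([0.0]))
        assert rate[0] == pytest.approx(-np.pi * load.f * load.eps_amp, rel=1e-12)


class TestPassiveEnergy:
    def test_undeformed_is_zero(self, cp):
        assert passive_energy(Microstate.from_geometry(1.0, 1.0, 0.0), cp) == pytest.approx(0.0)

    def test_rotation_invariance(self, cp):
        e = [passive_energy(Microstate.from_geometry(1.7, 0.8, th), cp) for th in (0.0, 0.4, 1.3)]
        assert np.ptp(e) < 1e-10

    def test_positive_away_from_rest(self, cp):
        for a1, a2 in [(2.0, 0.5), (1.5, 1.5), (0.7, 0.7), (1.2, 0.9)]:
            assert passive_energy(Microstate.from_geometry(a1, a2, 0.0), cp) > 0

    def test_moduli_ordering_enforced(self):
        with pytest.raises(ValueError):
            CellParams(mu_cyto=2.0, kappa_cyto=1.0)
        with pytest.raises(ValueError):
            CellParams(R_N=1.5, R0=1.0)


class TestCellEnergy:
    def test_static_equals_zero_amplitude(self, sfp, cp):
        m = Microstate.from_geometry(1.6, 0.8, 0.4)
        h_static = cycle_averaged_energy(m, CyclicLoad(eps_amp=0.0, f=0.0), sfp, cp)
        h_zero_amp = cycle_averaged_energy(m, CyclicLoad(eps_amp=0.0, f=1.0), sfp, cp)
        assert h_static == pytest.approx(h_zero_amp, rel=1e-12)

    def test_strain_aligned_shape_pays_more(self, sfp, cp):
        """Same elongated shape: aligned with the cyclic strain costs more
        cycle-averaged energy than perpendicular to it."""
        load = CyclicLoad(eps_amp=0.1, f=1.0, r=0.0)
        h_para = cycle_averaged_energy(Microstate.from_geometry(1.8, 0.7, 0.0), load, sfp, cp)
        h_perp = cycle_averaged_energy(Microstate.from_geometry(1.8, 0.7, np.pi / 2), load, sfp, cp)
        assert h_para > h_perp

    def test_cycle_average_independent_of_phase(self, sfp, cp):
        m = Microstate.from_geometry(1.7, 0.75, 0.9)
        load = CyclicLoad(eps_amp=0.1, f=1.0, r=0.0)
        h0 = cycle_averaged_energy(m, load, sfp, cp, n_time=256, t_I=0.0)
        h1 = cycle_averaged_energy(m, load, sfp, cp, n_time=256, t_I=0.37 * load.T_p)
        # the Hill clip makes the integrand only piecewise smooth, so the
        # periodic trapezoid converges at second order, not spectrally
        assert abs(h0 - h1) < 1e-3
        h0f = cycle_averaged_energy(m, load, sfp, cp, n_time=1024, t_I=0.0)
        h1f = cycle_averaged_energy(m, load, sfp, cp, n_time=1024, t_I=0.37 * load.T_p)
        assert abs(h0f - h1f) < abs(h0 - h1) + 1e-12

    def test_quadrature_convergence(self, sfp, cp):
        m = Microstate.from_geometry(1.7, 0.75, 0.9)
        load = CyclicLoad(eps_amp=0.1, f=1.0, r=0.0)
        h64 = cycle_averaged_energy(m, load, sfp, cp, n_time=64)
        h128 = cycle_averaged_energy(m, load, sfp, cp, n_time=128)
        h2048 = cycle_averaged_energy(m, load, sfp, cp, n_time=2048)
        assert abs(h128 - h2048) < 0.6 * abs(h64 - h2048) + 1e-12
        assert abs(h128 - h2048) < 1e-3

    def test_static_energy_theta_independent(self, sfp, cp):
        load = CyclicLoad(eps_amp=0.0, f=0.0)
        vals = [
            cycle_averaged_energy(Microstate.from_geometry(1.8, 0.7, th), load, sfp, cp)
            for th in np.linspace(0, np.pi, 7, endpoint=False)
        ]
        assert np.ptp(vals) < 1e-8

    def test_mirror_symmetry_under_uniaxial_load(self, sfp, cp):
        load = CyclicLoad(eps_amp=0.1, f=1.0, r=0.0)
        for th in (0.3, 0.9, 1.4):
            h1 = cycle_averaged_energy(Microstate.from_geometry(1.8, 0.7, th), load, sfp, cp)
            h2 = cycle_averaged_energy(Microstate.from_geometry(1.8, 0.7, np.pi - th), load, sfp, cp)
            assert h1 == pytest.approx(h2, rel=1e-9)

    def test_relabeling_invariance(self, sfp, cp):
        """(a1, a2, theta) -> (a2, a1, theta + pi/2) is the same ellipse."""
        load = CyclicLoad(eps_amp=0.1, f=1.0, r=0.0)
        h1 = hc.hhat_batch(np.array([1.8]), np.array([0.7]), np.array([0.4]), load, sfp, cp)
        h2 = hc.hhat_batch(np.array([0.7]), np.array([1.8]), np.array([0.4 + np.pi / 2]), load, sfp, cp)
        assert h1[0] == pytest.approx(h2[0], rel=1e-9)


class TestSuspensionEnergy:
    def test_suspension_area(self, cp):
        a = cp.suspension_radius_factor
        assert a * a == pytest.approx(0.9216)

    def test_suspension_energy_negative(self, sfp, cp):
        assert suspension_energy(sfp, cp) < 0

    def test_factor_one_has_no_passive_part(self, sfp):
        cp = CellParams(suspension_radius_factor=1.0)
        m = Microstate.from_geometry(1.0, 1.0, 0.0)
        h_total = suspension_energy(sfp, cp)
        h_inst = hc.cell_energy_instant(m, CyclicLoad(eps_amp=0.0, f=0.0), 0.0, sfp, cp)
        assert h_total == pytest.approx(h_inst, rel=1e-10)
        assert passive_energy(m, cp) == 0.0

    def test_cached_on_cell_params(self, sfp):
        cp = CellParams()
        v1 = suspension_energy(sfp, cp)
        assert cp.H_s == v1
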