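import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import eval_legendre

import nsphere as ns
from nsphere.harmonic_filters import harmonic_constants
from nsphere.model_core import (
    DipoleError,
    OutsideConductorError,
    UnsupportedRegionError,
)
from nsphere.potential_series import degree_terms
from nsphere.reference_oracles import homogeneous_closed_form

from conftest import profile_error

P_MOMENT = 1e-8  # 10 nA*m, a typical cortical source strength


class TestLegendreSequence:
    def test_at_one_all_ones(self):
        np.testing.assert_array_equal(ns.legendre_sequence(1.0, 20), 1.0)

    def test_degree_one_is_identity(self):
        assert ns.legendre_sequence(0.3, 1)[1] == pytest.approx(0.3)

    def test_degree_two(self):
        assert ns.legendre_sequence(0.5, 2)[2] == pytest.approx(-0.125)

    def test_out_of_domain(self):
        with pytest.raises(ValueError):
            ns.legendre_sequence(1.0001, 3)

    @given(x=st.floats(-1.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy(self, x):
        L = 30
        mine = ns.legendre_sequence(x, L)
        ref = eval_legendre(np.arange(L + 1), x)
        np.testing.assert_allclose(mine, ref, rtol=1e-10, atol=1e-12)

    def test_vectorized_shape(self):
        x = np.linspace(-1, 1, 7).reshape(7)
        assert ns.legendre_sequence(x, 5).shape == (6, 7)


class TestLocateShell:
    def test_inner_point(self, classic):
        assert ns.locate_shell(classic, 0.05) == 1

    def test_boundary_belongs_to_inner_shell(self, classic):
        assert ns.locate_shell(classic, 0.092) == 2

    def test_outside_conductor(self, classic):
        with pytest.raises(OutsideConductorError):
            ns.locate_shell(classic, 0.2)

    def test_outer_surface(self, classic):
        assert ns.locate_shell(classic, 0.100) == 3

    def test_continuity_across_boundary(self, classic, classic_constants):
        # the shell assignment at an exact boundary is a convention; the
        # potential must not care
        dip = ns.RadialDipole((0, 0, 0.04), P_MOMENT)
        R2 = classic.radii[1]
        vals = [
            ns.potential_at(classic, classic_constants, dip, r, 0.42)
            for r in (R2 * (1 - 1e-9), R2, R2 * (1 + 1e-9))
        ]
        # the spread is bounded by the physical radial gradient over the
        # 1e-9-relative nudge, not by the shell-assignment convention
        assert float(np.ptp(vals)) < 1e-6 * abs(vals[1])


class TestPotential:
    def test_zero_moment_gives_zero(self, classic, classic_constants):
        dip = ns.RadialDipole((0, 0, 0.05), 0.0)
        res = ns.potential(classic, classic_constants, dip, ns.FieldPoint((0, 0, 0.1)))
        assert res.value == 0.0
        assert res.shell == 3

    def test_linearity_in_moment(self, classic, classic_constants):
        point = ns.FieldPoint((0.03, 0.0, 0.095))
        v1 = ns.potential(
            classic, classic_constants, ns.RadialDipole((0, 0, 0.05), P_MOMENT), point
        ).value
        v3 = ns.potential(
            classic, classic_constants, ns.RadialDipole((0, 0, 0.05), 3 * P_MOMENT), point
        ).value
        assert v3 == pytest.approx(3 * v1, rel=1e-14)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=40, deadline=None)
    def test_rotational_symmetry(self, classic, classic_constants, seed):
        # rotating dipole and point together must not change the potential
        rng = np.random.default_rng(seed)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        dip_pos = np.array([0.01, -0.02, 0.04])
        pt_pos = np.array([0.05, 0.02, 0.08])
        v = ns.potential(
            classic,
            classic_constants,
            ns.RadialDipole(tuple(dip_pos), P_MOMENT),
            ns.FieldPoint(tuple(pt_pos)),
        ).value
        vr = ns.potential(
            classic,
            classic_constants,
            ns.RadialDipole(tuple(Q @ dip_pos), P_MOMENT),
            ns.FieldPoint(tuple(Q @ pt_pos)),
        ).value
        assert vr == pytest.approx(v, rel=1e-10)

    def test_single_sphere_matches_closed_form(self):
        m = ns.SphereModel((0.1,), (1 / 3,))
        hc = harmonic_constants(m, 1000)
        thetas = np.linspace(0.0, np.pi, 73)
        for ecc in (0.1, 0.5, 0.8, 0.95):
            r0 = ecc * m.radii[0]
            dip = ns.RadialDipole((0, 0, r0), P_MOMENT)
            series = ns.potential_at(m, hc, dip, m.outer_radius, np.cos(thetas))
            closed = homogeneous_closed_form(1 / 3, 0.1, r0, thetas, P_MOMENT)
            assert profile_error(series, closed) < 1e-10

    def test_point_below_source_radius_rejected(self, classic, classic_constants):
        dip = ns.RadialDipole((0, 0, 0.05), P_MOMENT)
        with pytest.raises(UnsupportedRegionError):
            ns.potential(classic, classic_constants, dip, ns.FieldPoint((0, 0, 0.01)))

    def test_origin_point_rejected(self, classic, classic_constants):
        dip = ns.RadialDipole((0, 0, 0), P_MOMENT, orientation=(0, 0, 1))
        with pytest.raises(UnsupportedRegionError):
            ns.potential(classic, classic_constants, dip, ns.FieldPoint((0, 0, 0)))

    def test_origin_dipole_needs_orientation(self, classic, classic_constants):
        dip = ns.RadialDipole((0, 0, 0), P_MOMENT)
        with pytest.raises(DipoleError):
            ns.potential(classic, classic_constants, dip, ns.FieldPoint((0, 0, 0.1)))

    def test_origin_dipole_limit_is_pure_cosine(self):
        # with the source at the center only the degree-1 term survives, so
        # the surface potential is 3P cos(theta) / (4 pi sigma R^2)
        m = ns.SphereModel((0.1,), (1 / 3,))
        hc = harmonic_constants(m, 100)
        dip = ns.RadialDipole((0, 0, 0), P_MOMENT, orientation=(0, 0, 1))
        thetas = np.linspace(0, np.pi, 21)
        vals = ns.potential_at(m, hc, dip, 0.1, np.cos(thetas))
        expected = 3 * P_MOMENT * np.cos(thetas) / (4 * np.pi * (1 / 3) * 0.1**2)
        np.testing.assert_allclose(vals, expected, rtol=1e-12, atol=1e-20)

    def test_truncation_convergence(self, classic):
        hc100 = harmonic_constants(classic, 100)
        hc200 = harmonic_constants(classic, 200)
        r0 = 0.95 * classic.radii[0]
        dip = ns.RadialDipole((0, 0, r0), P_MOMENT)
        c = np.cos(np.linspace(0, np.pi, 50))
        v100 = ns.potential_at(classic, hc100, dip, 0.1, c)
        v200 = ns.potential_at(classic, hc200, dip, 0.1, c)
        assert profile_error(v100, v200) < 1e-6

    def test_adaptive_truncation(self, classic, classic_constants):
        dip = ns.RadialDipole((0, 0, 0.01), P_MOMENT)  # low eccentricity
        point = ns.FieldPoint((0, 0.06, 0.08))
        fixed = ns.potential(classic, classic_constants, dip, point)
        adapt = ns.potential(classic, classic_constants, dip, point, adaptive=True)
        assert adapt.degree_used < fixed.degree_used == 100
        assert adapt.value == pytest.approx(fixed.value, rel=1e-10)


class TestPerDegreeBoundaryConditions:
    def test_continuity_and_current(self, classic, classic_constants):
        hc = classic_constants
        R = classic.radii_array()
        sig = classic.conductivity_array()
        ls = np.arange(1, 101, dtype=float)
        for s in range(1, classic.n):
            rb = R[s - 1]
            in_a = hc.A_tilde[:, s - 1] * (rb / R[s - 1]) ** ls
            in_b = hc.B_tilde[:, s - 1] * (R[s - 1] / rb) ** (ls + 1)
            out_a = hc.A_tilde[:, s] * (rb / R[s]) ** ls
            out_b = hc.B_tilde[:, s] * (R[s] / rb) ** (ls + 1)
            scale = np.max(np.abs([in_a, in_b, out_a, out_b]), axis=0)
            assert np.all(np.abs((in_a + in_b) - (out_a + out_b)) < 1e-10 * scale)
            di = sig[s - 1] * (ls * in_a - (ls + 1) * in_b)
            do = sig[s] * (ls * out_a - (ls + 1) * out_b)
            dscale = np.max(
                np.abs([sig[s - 1] * ls * in_a, sig[s - 1] * (ls + 1) * in_b,
                        sig[s] * ls * out_a, sig[s] * (ls + 1) * out_b]),
                axis=0,
            )
            assert np.all(np.abs(di - do) < 1e-10 * dscale)
        # no current through the outer surface
        a = hc.A_tilde[:, -1]
        b = hc.B_tilde[:, -1]
        res = np.abs(ls * a - (ls + 1) * b)
        assert np.all(res < 1e-10 * np.maximum(ls * np.abs(a), (ls + 1) * np.abs(b)))


class TestSurfaceProfile:
    def test_repeated_angles_equal(self, classic, classic_constants):
        dip = ns.RadialDipole((0, 0, 0.04), P_MOMENT)
        out = ns.surface_potential_profile(
            classic, classic_constants, dip, [0.7, 0.7]
        )
        assert out[0].value == out[1].value
        assert out[0].shell == classic.n

    def test_matches_pointwise_potential(self, classic, classic_constants):
        dip = ns.RadialDipole((0, 0, 0.04), P_MOMENT)
        theta = 1.1
        prof = ns.surface_potential_profile(classic, classic_constants, dip, [theta])
        pt = ns.FieldPoint((0.1 * np.sin(theta), 0.0, 0.1 * np.cos(theta)))
        direct = ns.potential(classic, classic_constants, dip, pt)
        assert prof[0].value == pytest.approx(direct.value, rel=1e-12)

    def test_equator_of_centered_dipole_is_zero(self):
        m = ns.SphereModel((0.1,), (1 / 3,))
        hc = harmonic_constants(m, 100)
        dip = ns.RadialDipole((0, 0, 0), P_MOMENT, orientation=(0, 0, 1))
        out = ns.surface_potential_profile(m, hc, dip, [np.pi / 2])
        assert out[0].value == pytest.approx(0.0, abs=1e-18)

    def test_pole_of_centered_dipole(self):
        m = ns.SphereModel((0.1,), (1 / 3,))
        hc = harmonic_constants(m, 100)
        dip = ns.RadialDipole((0, 0, 0), P_MOMENT, orientation=(0, 0, 1))
        out = ns.surface_potential_profile(m, hc, dip, [0.0])
        expected = 3 * P_MOMENT / (4 * np.pi * (1 / 3) * 0.1**2)
        assert out[0].value == pytest.approx(expected, rel=1e-12)


def test_degree_terms_group_source_factor_first(classic, classic_constants):
    # the per-degree summands must stay finite even when A~ alone would not:
    # spot-check that summands decay for an eccentric source
    dip = ns.RadialDipole((0, 0, 0.95 * classic.radii[0]), P_MOMENT)
    terms = degree_terms(classic, classic_constants, dip, 0.1, 1.0)
    assert np.all(np.isfinite(terms))
    assert abs(terms[-1]) < abs(terms[0])
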