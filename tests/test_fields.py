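"""Series evaluation: symmetries, continuity, derivatives, superposition."""

import numpy as np
import pytest
from scipy.special import eval_legendre, lpmv

import foursphere as fs
from foursphere.fields import _evaluate
from conftest import RZ, P


class TestRadialPotential:
    def test_phi_independence(self, model, ctrl):
        v1 = fs.potential_radial(model, RZ, P, (model.r4, 1.0, 0.0), ctrl).value
        v2 = fs.potential_radial(model, RZ, P, (model.r4, 1.0, 2.0), ctrl).value
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_zero_moment_gives_zero(self, model, ctrl):
        assert fs.potential_radial(model, RZ, 0.0, (model.r4, 0.7, 0.0), ctrl).value == 0.0

    def test_scalp_magnitude_decade(self, model, ctrl):
        """Peak scalp potential for a 1e-7 A*m dipole is tens of microvolts."""
        s = fs.potential_radial(model, RZ, P, (model.r4, 0.0, 0.0), ctrl)
        assert 1e-5 < abs(s.value) < 1e-4

    def test_matches_oracle_pipeline(self, model, ctrl):
        a = fs.potential_radial(model, RZ, P, (model.r4, 0.0, 0.0), ctrl)
        b = fs.potential_radial(model, RZ, P, (model.r4, 0.0, 0.0), ctrl, method="linear")
        assert a.value == pytest.approx(b.value, rel=1e-9)

    def test_validity_region_enforced(self, model, ctrl):
        with pytest.raises(fs.ValidityRegionError):
            fs.potential_radial(model, RZ, P, (RZ * 0.5, 0.3, 0.0), ctrl)
        with pytest.raises(fs.OutsideHeadError):
            fs.potential_radial(model, RZ, P, (model.r4 * 1.1, 0.3, 0.0), ctrl)

    def test_legendre_recurrence_matches_scipy(self, model, ctrl):
        """Brain-shell sum cross-checked against an explicit scipy-Legendre sum."""
        r, theta = 0.0789, 0.9
        sample = fs.potential_radial(model, RZ, P, (r, theta, 0.0), ctrl)
        tab = fs.coefficient_table(model, RZ, sample.terms_used)
        n = np.arange(1, sample.terms_used + 1)
        g = tab.A[1][: len(n)] * (r / model.r1) ** n + (RZ / r) ** (n + 1)
        direct = (
            P
            / (4 * np.pi * model.sigma(1) * RZ**2)
            * np.sum(g * n * eval_legendre(n, np.cos(theta)))
        )
        assert sample.value == pytest.approx(direct, rel=1e-12)


class TestTangentialPotential:
    def test_zero_at_phi_zero(self, model, ctrl):
        assert fs.potential_tangential(model, RZ, P, (model.r4, 1.0, 0.0), ctrl).value == 0.0

    def test_odd_in_phi(self, model, ctrl):
        vp = fs.potential_tangential(model, RZ, P, (model.r4, 1.0, 0.8), ctrl).value
        vm = fs.potential_tangential(model, RZ, P, (model.r4, 1.0, -0.8), ctrl).value
        assert vp == pytest.approx(-vm, rel=1e-12)

    def test_zero_on_polar_axis(self, model, ctrl):
        scale = abs(
            fs.potential_tangential(model, RZ, P, (model.r4, np.pi / 2, np.pi / 2), ctrl).value
        )
        for theta in (0.0, np.pi):  # P_n^1(+-1) = 0; float pi leaves sin(pi)~1e-16
            v = fs.potential_tangential(model, RZ, P, (model.r4, theta, 1.0), ctrl).value
            assert abs(v) <= 1e-14 * scale

    def test_matches_oracle_pipeline(self, model, ctrl):
        pt = (model.r4, np.pi / 2, np.pi / 2)
        a = fs.potential_tangential(model, RZ, P, pt, ctrl)
        b = fs.potential_tangential(model, RZ, P, pt, ctrl, method="linear")
        assert a.value == pytest.approx(b.value, rel=1e-9)

    def test_sign_convention_against_infinite_medium(self):
        """A +y tangential dipole in a huge equal-conductivity head must give
        a positive potential on the +y side, matching the unbounded-medium
        dipole formula (this pins the sinφ/Legendre sign convention)."""
        m = fs.make_head_model((7.9e3, 8.0e3, 8.5e3, 9.0e3), (0.33,) * 4, units="cm")
        d = fs.Dipole(position=(0.0, 0.0, RZ), moment=(0.0, P, 0.0))
        pt = np.array([[0.0, 0.09, 0.0]])
        series = fs.potential_dipole(m, d, pt)[0]
        ref = fs.potential_infinite_medium(0.33, d, pt)[0]
        assert ref > 0
        assert series == pytest.approx(ref, rel=1e-6)

    def test_associated_legendre_convention(self, model, ctrl):
        """The internal P_n^1 recurrence is Condon–Shortley free (= -lpmv)."""
        theta = 0.7
        sample = fs.potential_tangential(model, RZ, P, (model.r4, theta, np.pi / 2), ctrl)
        tab = fs.coefficient_table(model, RZ, sample.terms_used)
        n = np.arange(1, sample.terms_used + 1)
        g = tab.A[4][: len(n)] + tab.B[4][: len(n)]
        direct = (
            P
            / (4 * np.pi * model.sigma(1) * RZ**2)
            * np.sum(g * (-lpmv(1, n, np.cos(theta))))
        )
        assert sample.value == pytest.approx(direct, rel=1e-10)


class TestSuperposition:
    def test_45_degree_dipole_is_equal_weighted_sum(self, model, oblique_dipole, ctrl):
        pts = fs.scalp_sample_points(model, 64)
        combined = fs.potential_dipole(model, oblique_dipole, pts, ctrl)
        m = P / np.sqrt(2.0)
        rad = fs.potential_dipole(
            model, fs.Dipole((0, 0, RZ), (0, 0, m)), pts, ctrl
        )
        tan = fs.potential_dipole(
            model, fs.Dipole((0, 0, RZ), (0, m, 0)), pts, ctrl
        )
        scale = np.max(np.abs(combined))
        assert np.max(np.abs(combined - (rad + tan))) / scale < 1e-12

    def test_rotational_covariance(self, model, oblique_dipole, ctrl):
        pts = fs.scalp_sample_points(model, 32)
        base = fs.potential_dipole(model, oblique_dipole, pts, ctrl)
        rng = np.random.default_rng(7)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        d_rot = fs.Dipole(
            position=tuple(q @ oblique_dipole.position),
            moment=tuple(q @ oblique_dipole.moment),
        )
        rotated = fs.potential_dipole(model, d_rot, pts @ q.T, ctrl)
        assert np.max(np.abs(base - rotated)) / np.max(np.abs(base)) < 1e-10

    def test_zero_scalp_mean(self, model, oblique_dipole, ctrl):
        """Only n >= 1 harmonics are present: no monopole, zero surface mean."""
        from foursphere.validation import scalp_surface_mean

        mean, peak = scalp_surface_mean(model, oblique_dipole, ctrl)
        assert abs(mean) / peak < 1e-10


class TestContinuityAndShells:
    def test_interface_values_agree_from_both_shells(self, model, ctrl):
        """Boundary radii are assigned to the inner shell; continuity makes
        the assignment immaterial."""
        theta = np.linspace(0.3, 2.8, 11)
        for s in (1, 2, 3):
            r_if = np.full_like(theta, model.radius(s))
            inner, _ = _evaluate(
                model, RZ, P, r_if, theta, np.zeros_like(theta), "radial", ctrl,
                shell_override=s,
            )
            outer, _ = _evaluate(
                model, RZ, P, r_if, theta, np.zeros_like(theta), "radial", ctrl,
                shell_override=s + 1,
            )
            scale = np.max(np.abs(inner))
            assert np.max(np.abs(inner - outer)) / scale < 1e-8

    def test_shell_assignment(self, model):
        assert fs.shell_of(model, 0.0785) == 1
        assert fs.shell_of(model, model.r1) == 1
        assert fs.shell_of(model, 0.0795) == 2
        assert fs.shell_of(model, model.r4) == 4
        with pytest.raises(fs.OutsideHeadError):
            fs.shell_of(model, model.r4 * 1.01)


class TestRadialDerivative:
    def test_neumann_at_scalp_surface(self, model, ctrl):
        """Per-term cancellation: scalp radial derivative is round-off noise
        relative to the interior derivative scale."""
        for kind in ("radial", "tangential"):
            surf = fs.radial_derivative(
                model, RZ, P, (model.r4, 0.9, 1.0), kind, ctrl
            )
            interior = fs.radial_derivative(
                model, RZ, P, (0.5 * (model.r3 + model.r4), 0.9, 1.0), kind, ctrl
            )
            assert abs(surf) <= 1e-10 * abs(interior)

    def test_current_continuity_across_skull_boundary(self, model, ctrl):
        theta, phi = 0.8, 0.6
        for kind in ("radial", "tangential"):
            d_in, _ = _evaluate(
                model, RZ, P, np.array([model.r3]), np.array([theta]),
                np.array([phi]), kind, ctrl, derivative=True, shell_override=3,
            )
            d_out, _ = _evaluate(
                model, RZ, P, np.array([model.r3]), np.array([theta]),
                np.array([phi]), kind, ctrl, derivative=True, shell_override=4,
            )
            lhs = model.sigma(3) * d_in[0]
            rhs = model.sigma(4) * d_out[0]
            assert lhs == pytest.approx(rhs, rel=1e-8)

    @pytest.mark.parametrize("kind", ["radial", "tangential"])
    def test_finite_difference_agreement(self, model, ctrl, kind):
        r, theta, phi = 0.082, 0.9, 0.7  # interior of the CSF/skull region
        h = 1e-6
        f = lambda rr: _evaluate(
            model, RZ, P, np.array([rr]), np.array([theta]), np.array([phi]),
            kind, ctrl,
        )[0][0]
        numeric = (f(r + h) - f(r - h)) / (2 * h)
        analytic = fs.radial_derivative(model, RZ, P, (r, theta, phi), kind, ctrl)
        assert analytic == pytest.approx(numeric, rel=1e-6)

    def test_interior_harmonicity(self, model, ctrl):
        """Away from sources and interfaces the potential is harmonic: a
        7-point Laplacian vanishes relative to its constituent second
        derivatives (to the (kh)^2 discretization order)."""
        d = fs.Dipole((0, 0, RZ), (0, P / np.sqrt(2), P / np.sqrt(2)))
        x0 = np.array([0.02, 0.015, 0.0805])  # mid-skull radius ~ 8.25 cm
        h = 1e-4
        offsets = np.vstack([np.eye(3) * h, -np.eye(3) * h, np.zeros(3)])
        vals = fs.potential_dipole(model, d, x0 + offsets, ctrl)
        lap = (np.sum(vals[:6]) - 6 * vals[6]) / h**2
        second_scale = max(
            abs(vals[i] + vals[i + 3] - 2 * vals[6]) / h**2 for i in range(3)
        )
        assert abs(lap) < 1e-2 * second_scale
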