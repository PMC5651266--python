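"""The packaged verification suite: reports, tolerances, failure detection."""

import dataclasses

import numpy as np
import pytest

import foursphere as fs
from conftest import RZ, P


class TestBoundaryCheck:
    @pytest.mark.parametrize("moment", [(0, 0, P), (0, P, 0)])
    def test_standard_model_passes(self, model, moment):
        d = fs.Dipole(position=(0, 0, RZ), moment=moment)
        rep = fs.check_boundary_conditions(model, d, samples=30)
        assert rep.passed
        assert rep.max_residual <= 1e-8

    def test_broken_premise_detected(self, model, radial_dipole, ctrl):
        """Potentials computed with one model but residuals judged against a
        perturbed conductivity must fail loudly."""
        rep = fs.check_boundary_conditions(model, radial_dipole, samples=30)
        # mimic post-hoc conductivity perturbation via the coefficient residuals
        c = fs.compute_coefficients(model, RZ, 5)
        perturbed = fs.HeadModel(
            radii=model.radii,
            conductivities=(0.33, 1.65, 0.0165 * 1.5, 0.33),
        )
        res = fs.coefficient_residuals(c, perturbed, RZ)
        assert np.max(res) > 100 * rep.tolerance

    def test_too_few_samples_rejected(self, model, radial_dipole):
        with pytest.raises(fs.ParameterError):
            fs.check_boundary_conditions(model, radial_dipole, samples=5)

    def test_report_invariant(self):
        rep = fs.ValidationReport(
            name="x", max_residual=2.0, samples=1, tolerance=1.0,
            tolerance_source="t", passed=True,
        )
        assert rep.passed is False  # flag is forced consistent with residual


class TestHomogeneousLimit:
    def test_standard_radii_pass(self, model, radial_dipole):
        rep = fs.check_homogeneous_limit(model.radii, 0.33, radial_dipole)
        assert rep.passed and rep.max_residual <= 1e-6

    def test_sigma_scaling_leaves_deviation_unchanged(self, model, radial_dipole):
        r1 = fs.check_homogeneous_limit(model.radii, 0.33, radial_dipole)
        r2 = fs.check_homogeneous_limit(model.radii, 3.3, radial_dipole)
        assert r1.max_residual == pytest.approx(r2.max_residual, rel=1e-6)

    def test_tangential_dipole_rejected(self, model, tangential_dipole):
        with pytest.raises(fs.ParameterError):
            fs.check_homogeneous_limit(model.radii, 0.33, tangential_dipole)

    def test_deviation_is_truncation_limited(self, model, radial_dipole):
        """Tightening the tail tolerance does not worsen the agreement."""
        loose = fs.check_homogeneous_limit(
            model.radii, 0.33, radial_dipole, ctrl=fs.SeriesControl(rel_tol=1e-10)
        )
        tight = fs.check_homogeneous_limit(
            model.radii, 0.33, radial_dipole, ctrl=fs.SeriesControl(rel_tol=1e-13)
        )
        assert tight.max_residual <= loose.max_residual * 1.001


class TestInfiniteLimit:
    def test_monotone_convergence(self, homogeneous_model, oblique_dipole):
        rep = fs.check_infinite_limit(homogeneous_model, oblique_dipole)
        assert rep.passed
        devs = [rep.details["scale_10"], rep.details["scale_100"], rep.details["scale_1000"]]
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] <= 0.01

    def test_unequal_conductivities_rejected(self, model, radial_dipole):
        with pytest.raises(fs.ParameterError):
            fs.check_infinite_limit(model, radial_dipole)


class TestOracleComparison:
    def test_standard_configurations(self, model, ctrl):
        pts = fs.scalp_sample_points(model, 200)
        m45 = P / np.sqrt(2.0)
        for moment in ((0, 0, P), (0, P, 0), (0, m45, m45)):
            d = fs.Dipole(position=(0, 0, RZ), moment=moment)
            rep = fs.compare_with_oracle(model, d, pts, ctrl)
            assert rep.passed and rep.max_residual <= 1e-9

    def test_random_models(self, ctrl):
        rng = np.random.default_rng(490)
        for _ in range(5):
            m = fs.draw_random_model(rng)
            d = fs.draw_random_dipole(rng, m)
            rep = fs.compare_with_oracle(m, d, fs.scalp_sample_points(m, 50), ctrl)
            assert rep.passed, (m, d)

    def test_degenerate_near_equal_radii(self, ctrl):
        m = fs.make_head_model(
            (7.9, 7.9001, 8.5, 9.0), (0.33, 1.65, 0.0165, 0.33), units="cm"
        )
        d = fs.Dipole(position=(0, 0, RZ), moment=(0, P, P))
        rep = fs.compare_with_oracle(m, d, fs.scalp_sample_points(m, 50), ctrl)
        vals = fs.potential_dipole(m, d, fs.scalp_sample_points(m, 50), ctrl)
        assert np.all(np.isfinite(vals))
        assert rep.passed


class TestRandomDraws:
    def test_random_models_are_valid(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = fs.draw_random_model(rng)
            assert np.all(np.diff(m.radii) >= 1e-3 * (1 - 1e-9))
            assert 0.05 <= m.r1 and m.r4 <= 0.12
            assert all(0.004 <= s <= 2.0 for s in m.conductivities)
            d = fs.draw_random_dipole(rng, m)
            assert 0 < d.r_z < m.r1


class TestRunAll:
    @pytest.mark.parametrize("divisor", [20.0, 80.0])
    def test_all_checks_pass_on_standard_model(self, divisor):
        m = fs.default_head_model(divisor)
        reports = fs.run_all_checks(m, boundary_samples=16, oracle_points=50)
        assert len(reports) == 4
        for rep in reports:
            assert rep.passed, rep.name
            assert rep.tolerance_source
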