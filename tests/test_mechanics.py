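"""Potentials, forces and geometry against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import blastopack as bp
from blastopack import ModelParams, ShellSpec
from blastopack.mechanics import self_consistent_pair_distance


class TestEquilibriumDistance:
    @pytest.mark.parametrize("Ri,Rj,theta,expected", [
        (1.0, 1.0, 0.0, 2.0),
        (1.0, 1.0, np.pi / 3, 1.0),
        (2 ** (-1 / 3), 2 ** (-1 / 3), np.pi / 6,
         2 * 2 ** (-1 / 3) * np.cos(np.pi / 6)),
    ])
    def test_examples(self, Ri, Rj, theta, expected):
        assert bp.equilibrium_distance(Ri, Rj, theta) == pytest.approx(
            expected, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bp.equilibrium_distance(-1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            bp.equilibrium_distance(1.0, 1.0, np.pi / 2)


class TestPairPotential:
    @pytest.mark.parametrize("theta_deg", [15, 30, 45])
    def test_minimum_location_and_depth(self, theta_deg):
        """Numeric minimization locates r* with depth -U0 (oracle:
        golden-section search on a bracketing interval)."""
        theta = np.radians(theta_deg)
        p = ModelParams(theta=theta)
        Ri = Rj = 1.0
        rstar = bp.equilibrium_distance(Ri, Rj, theta)
        res = minimize_scalar(
            lambda r: bp.cell_cell_potential(r, Ri, Rj, p),
            bracket=(0.5 * rstar, rstar, 1.4 * rstar),
            method="golden", options={"xtol": 1e-12})
        assert res.x == pytest.approx(rstar, abs=1e-4 * (Ri + Rj))
        assert res.fun == pytest.approx(-1.0, abs=1e-4)

    def test_depth_at_rstar(self, params30):
        rstar = bp.equilibrium_distance(1.0, 1.0, params30.theta)
        assert bp.cell_cell_potential(rstar, 1.0, 1.0, params30) == \
            pytest.approx(-1.0, abs=1e-6)

    def test_tail_vanishes(self, params30):
        assert abs(bp.cell_cell_potential(6.0, 1.0, 1.0, params30)) < 1e-20

    def test_symmetry_in_radii(self, params30, rng):
        for _ in range(20):
            Ri, Rj = rng.uniform(0.4, 1.5, size=2)
            r = rng.uniform(0.3, 1.2) * (Ri + Rj)
            assert bp.cell_cell_potential(r, Ri, Rj, params30) == \
                bp.cell_cell_potential(r, Rj, Ri, params30)

    def test_domain_error(self, params30):
        with pytest.raises(ValueError):
            bp.cell_cell_potential(0.0, 1.0, 1.0, params30)


class TestPairForce:
    def test_zero_at_equilibrium(self, params30):
        rstar = bp.equilibrium_distance(1.0, 1.0, params30.theta)
        f = bp.cell_cell_force(np.array([rstar, 0, 0]), np.zeros(3),
                               1.0, 1.0, params30)
        assert np.linalg.norm(f) < 1e-6

    def test_repulsive_inside(self, params30):
        rstar = bp.equilibrium_distance(1.0, 1.0, params30.theta)
        f = bp.cell_cell_force(np.array([0.8 * rstar, 0, 0]), np.zeros(3),
                               1.0, 1.0, params30)
        assert f[0] > 0  # pushes cell i away from j

    def test_antisymmetric(self, params30, rng):
        for _ in range(10):
            pi, pj = rng.normal(size=(2, 3))
            fij = bp.cell_cell_force(pi, pj, 0.8, 0.6, params30)
            fji = bp.cell_cell_force(pj, pi, 0.6, 0.8, params30)
            np.testing.assert_allclose(fij, -fji, atol=1e-12)

    def test_matches_central_difference(self, params30):
        """Analytic force vs finite-difference gradient of the potential."""
        Ri, Rj = 1.0, 1.0
        h = 1e-6
        for r in np.linspace(0.5, 1.2, 15) * (Ri + Rj):
            f = bp.cell_cell_force(np.array([r, 0, 0]), np.zeros(3),
                                   Ri, Rj, params30)[0]
            fd = -(bp.cell_cell_potential(r + h, Ri, Rj, params30)
                   - bp.cell_cell_potential(r - h, Ri, Rj, params30)) / (2 * h)
            assert f == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_coincident_positions_error(self, params30):
        with pytest.raises(ValueError):
            bp.cell_cell_force(np.zeros(3), np.zeros(3), 1.0, 1.0, params30)


class TestShellGeometry:
    def test_level_examples(self):
        shell = ShellSpec(kind="repulsive", a_axis=2.0, b_axis=1.0)
        assert bp.ellipsoid_level(np.zeros(3), shell) == 0.0
        assert bp.ellipsoid_level(np.array([2.0, 0, 0]), shell) == \
            pytest.approx(1.0)
        assert bp.ellipsoid_level(np.array([0, 0.5, 0]), shell) == \
            pytest.approx(0.25)

    @pytest.mark.parametrize("vs,aspect,expected_b", [
        (1.52, 1.0, 1.52 ** (1 / 3)),
        (1.52, 2.0, (1.52 / 2) ** (1 / 3)),
        (1.0, 1.0, 1.0),
    ])
    def test_axes_from_ratio(self, vs, aspect, expected_b):
        a, b = bp.shell_axes_from_ratio(vs, aspect)
        assert b == pytest.approx(expected_b, abs=1e-10)
        assert a == pytest.approx(aspect * b, abs=1e-10)
        assert a * b * b == pytest.approx(vs, abs=1e-10)

    def test_axes_domain_errors(self):
        with pytest.raises(ValueError):
            bp.shell_axes_from_ratio(-1.0, 1.0)
        with pytest.raises(ValueError):
            bp.shell_axes_from_ratio(1.0, 0.5)


class TestRepulsiveShell:
    def test_inactive_far_from_shell(self):
        shell = ShellSpec(kind="repulsive", a_axis=4.0, b_axis=4.0)
        assert bp.repulsive_shell_potential(np.zeros(3), 1.0, shell) == 0.0

    def test_value_at_half_level(self):
        # unit sphere: level gap and physical gap coincide
        shell = ShellSpec(kind="repulsive", a_axis=1.0, b_axis=1.0,
                          A_strength=10.0)
        u = bp.repulsive_shell_potential(np.array([0.5, 0, 0]), 0.5, shell)
        assert u == pytest.approx(20.0)

    def test_monotonic_in_level(self):
        shell = ShellSpec(kind="repulsive", a_axis=1.0, b_axis=1.0)
        rs = np.linspace(0.55, 0.95, 30)
        us = [bp.repulsive_shell_potential(np.array([r, 0, 0]), 0.5, shell)
              for r in rs]
        assert np.all(np.diff(us) > 0)

    def test_penetration_error(self):
        shell = ShellSpec(kind="repulsive", a_axis=1.0, b_axis=1.0)
        with pytest.raises(bp.ShellPenetrationError):
            bp.repulsive_shell_potential(np.array([1.1, 0, 0]), 0.5, shell)


class TestStickyShell:
    def test_depth_at_equilibrium_gap(self, params30):
        shell = ShellSpec(kind="sticky", a_axis=1.2, b_axis=1.2, Us0=4.0)
        R = 0.63
        cell = bp.Cell(id=0, position=np.zeros(3), base_radius=R)
        gap = R * np.cos(params30.theta)
        pos = np.array([1.2 - gap, 0, 0])
        assert bp.sticky_shell_potential(pos, cell, shell, params30) == \
            pytest.approx(-4.0, abs=1e-10)

    def test_zero_deep_inside(self, params30):
        shell = ShellSpec(kind="sticky", a_axis=3.0, b_axis=3.0, Us0=4.0)
        cell = bp.Cell(id=0, position=np.zeros(3), base_radius=0.63)
        assert bp.sticky_shell_potential(np.zeros(3), cell, shell,
                                         params30) == 0.0

    def test_argmin_over_gap(self, params30):
        """1-D grid minimization oracle for the adhesive well position."""
        shell = ShellSpec(kind="sticky", a_axis=1.5, b_axis=1.5, Us0=4.0)
        R = 0.63
        cell = bp.Cell(id=0, position=np.zeros(3), base_radius=R)
        gaps = np.linspace(0.2, R, 20001)
        us = [bp.sticky_shell_potential(np.array([1.5 - g, 0, 0]), cell,
                                        shell, params30) for g in gaps]
        assert gaps[int(np.argmin(us))] == pytest.approx(
            R * np.cos(params30.theta), abs=1e-4)


class TestShellForce:
    def test_zero_outside_support(self, params30):
        shell = ShellSpec(kind="repulsive", a_axis=4.0, b_axis=4.0)
        cell = bp.Cell(id=0, position=np.zeros(3), base_radius=1.0)
        f = bp.shell_force(np.zeros(3), cell, shell, params30)
        assert np.all(f == 0.0)

    def test_repulsive_points_inward(self, params30, rng):
        shell = ShellSpec(kind="repulsive", a_axis=1.2, b_axis=1.2)
        cell = bp.Cell(id=0, position=np.zeros(3), base_radius=0.63)
        for _ in range(10):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = u * rng.uniform(0.7, 1.0)
            f = bp.shell_force(pos, cell, shell, params30)
            assert np.dot(f, pos) < 0  # toward lower level

    @pytest.mark.parametrize("kind,us0", [("repulsive", 0.0), ("sticky", 4.0)])
    def test_matches_central_difference_sphere(self, kind, us0, params30, rng):
        """For spherical shells the gap is exact, so the analytic force
        must equal the finite-difference gradient."""
        shell = ShellSpec(kind=kind, a_axis=1.3, b_axis=1.3, Us0=us0)
        R = 0.63
        cell = bp.Cell(id=0, position=np.zeros(3), base_radius=R)
        fn = (bp.repulsive_shell_potential if kind == "repulsive"
              else lambda p, r, s: bp.sticky_shell_potential(
                  p, cell, s, params30))
        h = 1e-7
        for _ in range(10):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = u * rng.uniform(0.75, 1.1)  # inside the active band
            f = bp.shell_force(pos, cell, shell, params30)
            for d in range(3):
                dp = np.zeros(3)
                dp[d] = h
                fd = -(fn(pos + dp, R, shell) - fn(pos - dp, R, shell)) / (2 * h)
                assert f[d] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_ellipsoid_force_along_local_normal(self, params30):
        """For ellipsoids the force is -dU/ds along the local outward
        normal (the model's definition); check direction and magnitude
        against a finite difference of the gap-based potential taken along
        that normal."""
        shell = ShellSpec(kind="repulsive", a_axis=2.4, b_axis=0.8)
        R = 0.63
        cell = bp.Cell(id=0, position=np.zeros(3), base_radius=R)
        pos = np.array([1.0, 0.35, 0.0])
        f = bp.shell_force(pos, cell, shell, params30)
        grad_c = np.array([2 * pos[0] / shell.a_axis ** 2,
                           2 * pos[1] / shell.b_axis ** 2,
                           2 * pos[2] / shell.b_axis ** 2])
        n_hat = grad_c / np.linalg.norm(grad_c)
        # force is anti-parallel to the outward normal
        assert np.dot(f, n_hat) < 0
        assert np.linalg.norm(np.cross(f, n_hat)) < 1e-10 * np.linalg.norm(f)


class TestVolumeCorrection:
    @pytest.mark.parametrize("d,Ri,Rj,expected", [
        (2.5, 1.0, 1.0, 0.0),
        (0.0, 1.0, 1.0, 4 * np.pi / 3),
        (1.0, 1.0, 1.0, 5 * np.pi / 12),
    ])
    def test_lens_examples(self, d, Ri, Rj, expected):
        assert bp.sphere_overlap_volume(d, Ri, Rj) == pytest.approx(
            expected, abs=1e-12)

    def test_lens_vs_monte_carlo(self, rng):
        """Closed-form lens volume vs Monte-Carlo integration, 50 random
        geometries, agreement within 3 standard errors."""
        n_mc = 40000
        for _ in range(50):
            Ri, Rj = rng.uniform(0.4, 1.2, size=2)
            d = rng.uniform(0.0, Ri + Rj)
            lo = np.array([-Ri, -Ri, -Ri])
            hi = np.array([Ri, Ri, Ri])
            pts = rng.uniform(lo, hi, size=(n_mc, 3))
            in_i = np.sum(pts ** 2, axis=1) <= Ri ** 2
            dj = pts - np.array([d, 0.0, 0.0])
            in_j = np.sum(dj ** 2, axis=1) <= Rj ** 2
            hits = in_i & in_j
            box = np.prod(hi - lo)
            p = hits.mean()
            est = p * box
            se = box * np.sqrt(max(p * (1 - p), 1e-12) / n_mc)
            exact = bp.sphere_overlap_volume(d, Ri, Rj)
            assert abs(est - exact) <= 3 * se + 1e-9

    def test_corrected_radius_examples(self):
        assert bp.corrected_radius(1.0, 0.0) == pytest.approx(1.0)
        assert bp.corrected_radius(1.0, 4 * np.pi / 3) == pytest.approx(
            2 ** (1 / 3), abs=1e-12)
        assert bp.corrected_radius(1.0, 5 * np.pi / 12) == pytest.approx(
            (1 + 5 / 16) ** (1 / 3), abs=1e-12)

    def test_corrected_radius_monotone(self):
        vols = np.linspace(0.0, 2.0, 50)
        rs = [bp.corrected_radius(0.8, v) for v in vols]
        assert rs[0] == pytest.approx(0.8)
        assert np.all(np.diff(rs) > 0)

    def test_negative_volume_error(self):
        with pytest.raises(ValueError):
            bp.corrected_radius(1.0, -0.1)

    def test_self_consistent_pair_distance(self, params30):
        """The fixed point r = 2 R'(r) cos(theta) sits slightly beyond the
        base-radius equilibrium (overlap inflates R')."""
        R = 0.63
        r_sc = self_consistent_pair_distance(R, params30.theta)
        rstar = 2 * R * np.cos(params30.theta)
        assert r_sc > rstar
        rp = bp.corrected_radius(R, bp.sphere_overlap_volume(r_sc, R, R))
        assert r_sc == pytest.approx(2 * rp * np.cos(params30.theta),
                                     abs=1e-10)


class TestParamValidation:
    def test_alpha_beta_order(self):
        with pytest.raises(ValueError):
            ModelParams(theta=0.5, alpha=2.0, beta=3.0)

    def test_theta_range(self):
        with pytest.raises(ValueError):
            ModelParams(theta=np.pi / 2)

    def test_sticky_requires_us0(self):
        with pytest.raises(ValueError):
            ShellSpec(kind="sticky", a_axis=1.0, b_axis=1.0, Us0=0.0)

    def test_aspect_order(self):
        with pytest.raises(ValueError):
            ShellSpec(kind="repulsive", a_axis=1.0, b_axis=2.0)
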