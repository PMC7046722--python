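"""Superposition, RMSD/RMSF/Rg series and Shrake-Rupley SASA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import trajscope as ts
from trajscope.geometry import fibonacci_sphere, kabsch_superpose, series_density
from .conftest import make_trajectory


def rot_z(deg):
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


def brute_force_min_rmsd(mobile, reference, n_grid=5000, seed=0,
                         n_refine=600):
    """Independent oracle: dense rotation sampling plus annealed local
    refinement (no SVD anywhere)."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def cost(R):
        return np.sqrt(np.mean(np.sum((m @ R.T - r) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best_rot, best = np.eye(3), cost(np.eye(3))
    for R in Rotation.random(n_grid, random_state=seed).as_matrix():
        c = cost(R)
        if c < best:
            best_rot, best = R, c
    scale = 0.2
    for k in range(n_refine):
        delta = Rotation.from_rotvec(rng.standard_normal(3) * scale)
        cand = delta.as_matrix() @ best_rot
        c = cost(cand)
        if c < best:
            best_rot, best = cand, c
        scale = max(scale * 0.99, 1e-5)
    return best


class TestKabsch:
    def test_identity_superposition(self, rng):
        pts = rng.standard_normal((8, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_recovers_zero_rmsd(self, rng):
        pts = rng.standard_normal((8, 3))
        moved = pts @ rot_z(90).T + np.array([1.0, -2.0, 3.0])
        _, _, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_mirror_image_keeps_proper_rotation_and_residual(self):
        # chiral 4-point set; reflection would fit exactly but is forbidden
        pts = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.0, 0], [0, 0, 2.0]])
        mirror = pts * np.array([1.0, 1.0, -1.0])
        rot, _, rmsd = kabsch_superpose(mirror, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)
        assert rmsd > 0.1
        oracle = brute_force_min_rmsd(mirror, pts)
        # dense rotation sampling can only overestimate the true minimum
        assert rmsd <= oracle + 1e-6
        assert rmsd == pytest.approx(oracle, rel=0.05)

    def test_agrees_with_scipy_align_vectors(self, rng):
        a = rng.standard_normal((12, 3))
        b = rng.standard_normal((12, 3))
        rot, _, rmsd = kabsch_superpose(a, b)
        sp_rot, sp_rssd = Rotation.align_vectors(
            b - b.mean(axis=0), a - a.mean(axis=0))
        np.testing.assert_allclose(rot, sp_rot.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(sp_rssd / np.sqrt(len(a)), rel=1e-8)

    def test_uniform_weights_equal_unweighted(self, rng):
        a = rng.standard_normal((6, 3))
        b = rng.standard_normal((6, 3))
        r1, t1, d1 = kabsch_superpose(a, b)
        r2, t2, d2 = kabsch_superpose(a, b, weights=np.full(6, 0.4))
        np.testing.assert_allclose(r1, r2, atol=1e-12)
        np.testing.assert_allclose(t1, t2, atol=1e-12)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRMSDSeries:
    def test_zero_for_reference_frames(self, helix10, helix10_ca):
        frames = np.repeat(helix10.coords[None], 5, axis=0)
        traj = make_trajectory(helix10, frames)
        out = ts.rmsd_series(traj, helix10.coords[helix10_ca.indices],
                             helix10_ca)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_zero_for_rigid_motions(self, helix10, helix10_ca, rng):
        frames = []
        for _ in range(6):
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            frames.append(helix10.coords @ R.T + rng.standard_normal(3))
        traj = make_trajectory(helix10, frames)
        out = ts.rmsd_series(traj, helix10.coords[helix10_ca.indices],
                             helix10_ca)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_gaussian_ensemble_matches_rotation_grid_oracle(self, helix10,
                                                            helix10_ca, rng):
        frames = helix10.coords[None] + rng.standard_normal((20, helix10.n_atoms, 3)) * 0.4
        traj = make_trajectory(helix10, frames)
        ref = helix10.coords[helix10_ca.indices]
        ours = ts.rmsd_series(traj, ref, helix10_ca).values
        oracle = np.array([
            brute_force_min_rmsd(frames[t][helix10_ca.indices], ref, seed=t)
            for t in range(20)])
        assert np.mean(ours) == pytest.approx(np.mean(oracle), rel=0.05)
        # Kabsch is the exact minimum, the sampled grid an upper bound
        assert np.all(ours <= oracle + 1e-9)

    def test_size_mismatch_rejected(self, helix10, helix10_ca):
        traj = make_trajectory(helix10, helix10.coords[None])
        with pytest.raises(ValueError):
            ts.rmsd_series(traj, np.zeros((3, 3)), helix10_ca)


class TestRMSF:
    def test_static_trajectory_is_zero(self, helix10, helix10_ca):
        traj = make_trajectory(helix10, np.repeat(helix10.coords[None], 4, 0))
        out = ts.rmsf_profile(traj, helix10_ca)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_single_frame_rejected(self, helix10, helix10_ca):
        traj = make_trajectory(helix10, helix10.coords[None])
        with pytest.raises(ValueError):
            ts.rmsf_profile(traj, helix10_ca)

    def test_single_oscillating_atom_closed_form(self, helix60, helix60_ca):
        # one CA alternates ±a along x in an otherwise static frame set;
        # no fitting, so the closed form is exact
        a = 0.7
        frames = np.repeat(helix60.coords[None], 10, axis=0)
        atom = helix60_ca.indices[30]
        frames[::2, atom, 0] += a
        frames[1::2, atom, 0] -= a
        traj = make_trajectory(helix60, frames)
        out = ts.rmsf_profile(traj, helix60_ca, superpose=False)
        assert out.values[30] == pytest.approx(a, rel=1e-12)
        others = np.delete(out.values, 30)
        np.testing.assert_allclose(others, 0.0, atol=1e-12)

    def test_isotropic_noise_gives_sigma_sqrt3(self, helix60, helix60_ca):
        sigma = 0.3
        spec = ts.EnsembleSpec(reference=helix60, sigma=sigma, n_frames=2000,
                               seed=5)
        traj = ts.make_gaussian_ensemble(spec)
        out = ts.rmsf_profile(traj, helix60_ca)
        assert out.values.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_time_order_independence(self, helix10, helix10_ca, rng):
        frames = helix10.coords[None] + rng.standard_normal((30, helix10.n_atoms, 3)) * 0.3
        traj = make_trajectory(helix10, frames)
        shuffled = make_trajectory(helix10, frames[rng.permutation(30)])
        a = ts.rmsf_profile(traj, helix10_ca).values
        b = ts.rmsf_profile(shuffled, helix10_ca).values
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestRg:
    def _point_traj(self, coords, masses=None):
        coords = np.asarray(coords, float)
        atoms = [ts.Atom(i + 1, "CA", "C", i + 1, i + 1, "A", c,
                         mass=(masses[i] if masses else 1.0))
                 for i, c in enumerate(coords)]
        residues = [(i + 1, i + 1, "GLY", "A") for i in range(len(coords))]
        s = ts.Structure(atoms=atoms, residues=residues)
        return make_trajectory(s, coords[None]), ts.select_atoms(s, "name CA")

    @pytest.mark.parametrize("coords,expected", [
        ([[1, 0, 0], [-1, 0, 0]], 1.0),
        ([[2, 3, 4], [2, 3, 4], [2, 3, 4]], 0.0),
        ([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], np.sqrt(2)),
    ])
    def test_analytic_cases(self, coords, expected):
        traj, sel = self._point_traj(coords)
        out = ts.rg_series(traj, sel)
        assert out.values[0] == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariance(self, helix10, helix10_ca, rng):
        base = ts.rg_series(make_trajectory(helix10, helix10.coords[None]),
                            helix10_ca).values[0]
        R = Rotation.random(random_state=3).as_matrix()
        moved = helix10.coords @ R.T + np.array([5.0, 6.0, 7.0])
        out = ts.rg_series(make_trajectory(helix10, moved[None]),
                           helix10_ca).values[0]
        assert out == pytest.approx(base, abs=1e-9)

    def test_mass_weighting_changes_result(self):
        coords = [[1.0, 0, 0], [-1.0, 0, 0]]
        traj, sel = self._point_traj(coords, masses=[1.0, 3.0])
        weighted = ts.rg_series(traj, sel, mass_weighted=True).values[0]
        unweighted = ts.rg_series(traj, sel, mass_weighted=False).values[0]
        assert unweighted == pytest.approx(1.0)
        # com at (-0.5,0,0): sqrt((1*1.5^2 + 3*0.5^2)/4) = sqrt(0.75)
        assert weighted == pytest.approx(np.sqrt(0.75), abs=1e-12)


class TestSASA:
    def test_isolated_carbon_matches_analytic_sphere(self):
        _, _, total = ts.sasa(np.zeros((1, 3)), np.array([1.7]),
                              probe_radius=1.4, n_points=960)
        analytic = 4 * np.pi * 3.1**2
        assert total == pytest.approx(analytic, rel=0.02)

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.7, 1.52])
        _, _, total = ts.sasa(coords, radii)
        singles = sum(ts.sasa(c[None], np.array([r]))[2]
                      for c, r in zip(coords, radii))
        assert total == pytest.approx(singles, rel=1e-9)

    def test_engulfed_atom_has_zero_area(self):
        coords = np.zeros((2, 3))
        coords[0, 0] = 0.1
        per_atom, _, _ = ts.sasa(coords, np.array([0.5, 3.0]))
        assert per_atom[0] == 0.0

    def test_monotone_in_neighbour_count(self, rng):
        center = np.zeros(3)
        shells = rng.standard_normal((6, 3))
        shells = 3.0 * shells / np.linalg.norm(shells, axis=1, keepdims=True)
        areas = []
        for k in range(0, 7):
            coords = np.vstack([center, shells[:k]])
            per_atom, _, _ = ts.sasa(coords, np.full(k + 1, 1.7))
            areas.append(per_atom[0])
        assert all(a >= b - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_convergence_with_point_density(self):
        analytic = 4 * np.pi * 3.1**2
        errs = [abs(ts.sasa(np.zeros((1, 3)), np.array([1.7]),
                            n_points=n)[2] - analytic) / analytic
                for n in (60, 240, 960, 3840)]
        assert errs[-1] < 0.01
        assert errs[-1] <= errs[0]

    def test_agrees_with_mdtraj_on_small_helix(self, helix10):
        mdtraj = pytest.importorskip("mdtraj")
        import mdtraj.core.element as elem

        top = mdtraj.Topology()
        chain = top.add_chain()
        residues = [top.add_residue("ALA", chain) for _ in helix10.residues]
        for a in helix10.atoms:
            top.add_atom(a.name, elem.get_by_symbol(a.element),
                         residues[a.residue_index - 1])
        t = mdtraj.Trajectory(helix10.coords[None] / 10.0, top)
        ref = mdtraj.shrake_rupley(t, probe_radius=0.14, n_sphere_points=960,
                                   mode="atom")[0] * 100.0
        _, _, total = ts.sasa(helix10.coords, helix10.atom_radii())
        assert total == pytest.approx(ref.sum(), rel=0.02)

    def test_fibonacci_sphere_is_unit_and_deterministic(self):
        pts = fibonacci_sphere(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_array_equal(pts, fibonacci_sphere(960))


class TestSeriesDensity:
    def test_integral_is_one(self, rng):
        s = ts.SeriesResult(values=rng.standard_normal(500), unit="Å",
                            metric="rmsd")
        edges, dens = series_density(s, n_bins=37)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_single_occupied_bin(self):
        s = ts.SeriesResult(values=np.full(50, 2.5), unit="Å", metric="rg")
        edges, dens = series_density(s, n_bins=10)
        assert np.count_nonzero(dens) == 1
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0)

    def test_uniform_grid_gives_equal_densities(self):
        s = ts.SeriesResult(values=np.arange(10) + 0.5, unit="Å", metric="x")
        edges, dens = series_density(s, n_bins=10)
        np.testing.assert_allclose(dens, dens[0])
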