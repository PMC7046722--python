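"""Cross-correlation maps and essential-dynamics PCA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import trajscope as ts
from trajscope.collective import dccm_reference_double_loop
from .conftest import make_trajectory


def _point_structure(n):
    atoms = [ts.Atom(i + 1, "CA", "C", i + 1, i + 1, "A",
                     np.array([3.8 * i, 0.0, 0.0])) for i in range(n)]
    residues = [(i + 1, i + 1, "GLY", "A") for i in range(n)]
    return ts.Structure(atoms=atoms, residues=residues)


def anti_correlated_pair_trajectory(n_frames=50, seed=0):
    """Atom 2's displacement is exactly minus atom 1's in every frame."""
    rng = np.random.default_rng(seed)
    s = _point_structure(2)
    d = rng.standard_normal((n_frames, 3)) * 0.5
    d -= d.mean(axis=0)
    frames = np.repeat(s.coords[None], n_frames, axis=0)
    frames[:, 0, :] += d
    frames[:, 1, :] -= d
    return make_trajectory(s, frames), ts.select_atoms(s, "name CA")


class TestDCCM:
    def test_self_correlation_is_exactly_one(self, correlated_ensemble,
                                             helix60_ca):
        d = ts.dccm(correlated_ensemble, helix60_ca, superpose=False)
        np.testing.assert_array_equal(np.diag(d.matrix), 1.0)

    def test_constructed_anticorrelated_pair_is_minus_one(self):
        traj, sel = anti_correlated_pair_trajectory()
        d = ts.dccm(traj, sel, superpose=False)
        assert d.matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)
        assert d.matrix[1, 0] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("superpose", [True, False])
    def test_matches_double_loop_oracle(self, helix10, helix10_ca, superpose):
        spec = ts.EnsembleSpec(reference=helix10, sigma=0.4, n_frames=50,
                               seed=11)
        traj = ts.make_gaussian_ensemble(spec)
        fast = ts.dccm(traj, helix10_ca, superpose=superpose).matrix
        slow = dccm_reference_double_loop(traj, helix10_ca,
                                          superpose=superpose)
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_planted_block_correlation_recovered(self, correlated_ensemble,
                                                 helix60_ca):
        d = ts.dccm(correlated_ensemble, helix60_ca, superpose=False)
        block = d.matrix[0:5, 5:10]
        assert abs(block.mean() - 0.8) < 0.05
        # sign/magnitude pattern: inside the correlated group high, outside low
        outside = d.matrix[0:10, 20:]
        assert np.abs(outside).max() < 0.1

    def test_independent_atoms_stay_below_null_bound(self, helix60,
                                                     helix60_ca):
        spec = ts.EnsembleSpec(reference=helix60, sigma=0.5, n_frames=5000,
                               seed=4)
        traj = ts.make_gaussian_ensemble(spec)
        d = ts.dccm(traj, helix60_ca, superpose=False)
        off = d.matrix[~np.eye(60, dtype=bool)]
        assert np.abs(off).max() < 3.0 / np.sqrt(5000) * 1.5

    def test_invariant_under_global_rotation_of_frames(self, helix10,
                                                       helix10_ca):
        spec = ts.EnsembleSpec(reference=helix10, sigma=0.4, n_frames=200,
                               seed=12)
        traj = ts.make_gaussian_ensemble(spec)
        R = Rotation.from_euler("xyz", [30, -40, 75], degrees=True).as_matrix()
        rotated = make_trajectory(helix10,
                                  np.einsum("tij,kj->tik", traj.frames, R))
        a = ts.dccm(traj, helix10_ca).matrix
        b = ts.dccm(rotated, helix10_ca).matrix
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_zero_variance_atom_flagged_missing(self):
        s = _point_structure(3)
        rng = np.random.default_rng(0)
        frames = np.repeat(s.coords[None], 40, axis=0)
        frames[:, :2, :] += rng.standard_normal((40, 2, 3))
        traj = make_trajectory(s, frames)
        d = ts.dccm(traj, ts.select_atoms(s, "name CA"), superpose=False)
        assert d.missing_mask is not None
        assert np.isnan(d.matrix[2, 0]) and np.isnan(d.matrix[2, 2])
        assert d.matrix[0, 0] == 1.0

    def test_fewer_than_two_frames_rejected(self, helix10, helix10_ca):
        traj = make_trajectory(helix10, helix10.coords[None])
        with pytest.raises(ValueError):
            ts.dccm(traj, helix10_ca)


class TestPCA:
    def test_trace_equals_eigenvalue_sum_and_coordinate_variance(
            self, correlated_ensemble, helix60_ca):
        p = ts.pca_covariance(correlated_ensemble, helix60_ca,
                              superpose=False)
        assert p.eigenvalues.sum() == pytest.approx(p.trace, rel=1e-8)
        disp = correlated_ensemble.frames[:, helix60_ca.indices, :]
        disp = disp - disp.mean(axis=0)
        per_coord_var = disp.reshape(len(disp), -1).var(axis=0).sum()
        assert p.trace == pytest.approx(per_coord_var, rel=1e-8)
        assert p.variance_fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_planted_dominant_mode_recovered(self, helix10, helix10_ca, rng):
        v = rng.standard_normal(30)
        v /= np.linalg.norm(v)
        amps = rng.standard_normal(2000) * 1.5
        frames = np.repeat(helix10.coords[None], 2000, axis=0)
        frames[:, helix10_ca.indices, :] += \
            (amps[:, None] * v[None]).reshape(2000, 10, 3)
        traj = make_trajectory(helix10, frames)
        p = ts.pca_covariance(traj, helix10_ca, superpose=False)
        assert p.variance_fractions[0] >= 0.99
        assert abs(np.dot(p.eigenvectors[:, 0], v)) >= 0.99

    def test_isotropic_trace_is_3n_sigma_squared(self, helix60, helix60_ca):
        sigma = 0.5
        spec = ts.EnsembleSpec(reference=helix60, sigma=sigma, n_frames=4000,
                               seed=9)
        traj = ts.make_gaussian_ensemble(spec)
        p = ts.pca_covariance(traj, helix60_ca, superpose=False)
        assert p.trace == pytest.approx(3 * 60 * sigma**2, rel=0.05)

    def test_spectrum_sorted_and_covariance_reconstructed(self, helix10,
                                                          helix10_ca):
        spec = ts.EnsembleSpec(reference=helix10, sigma=0.4, n_frames=300,
                               seed=21)
        traj = ts.make_gaussian_ensemble(spec)
        p = ts.pca_covariance(traj, helix10_ca, superpose=False)
        assert np.all(np.diff(p.eigenvalues) <= 1e-12)
        gram = p.eigenvectors.T @ p.eigenvectors
        np.testing.assert_allclose(gram, np.eye(30), atol=1e-8)
        disp = traj.frames[:, helix10_ca.indices, :]
        disp = (disp - disp.mean(axis=0)).reshape(300, -1)
        cov = disp.T @ disp / 300
        recon = (p.eigenvectors * p.eigenvalues) @ p.eigenvectors.T
        np.testing.assert_allclose(recon, cov, atol=1e-8)

    def test_projection_variance_equals_eigenvalue(self, helix10, helix10_ca):
        spec = ts.EnsembleSpec(reference=helix10, sigma=0.4, n_frames=400,
                               seed=22)
        traj = ts.make_gaussian_ensemble(spec)
        p = ts.pca_covariance(traj, helix10_ca, superpose=False)
        proj = ts.project_onto_pcs(traj, helix10_ca, p, k=3, superpose=False)
        np.testing.assert_allclose(proj.var(axis=0), p.eigenvalues[:3],
                                   rtol=1e-8)

    def test_mean_structure_projects_to_zero(self, helix10, helix10_ca):
        spec = ts.EnsembleSpec(reference=helix10, sigma=0.4, n_frames=100,
                               seed=23)
        traj = ts.make_gaussian_ensemble(spec)
        p = ts.pca_covariance(traj, helix10_ca, superpose=False)
        mean_traj = make_trajectory(helix10, traj.frames.mean(axis=0)[None])
        mean_traj.frames[0, helix10_ca.indices] = p.mean_structure
        proj = ts.project_onto_pcs(mean_traj, helix10_ca, p, k=2,
                                   superpose=False)
        np.testing.assert_allclose(proj, 0.0, atol=1e-9)

    def test_two_state_trajectory_gives_bimodal_pc1(self, helix10,
                                                    helix10_ca):
        shift = 4.0
        coords_b = helix10.coords.copy()
        coords_b[helix10_ca.indices[5:]] += np.array([shift, 0, 0])
        spec = ts.TwoStateSpec(conformer_a=helix10.coords,
                               conformer_b=coords_b, topology=helix10,
                               p_a=0.5, jitter=0.05, n_frames=1000, seed=8)
        traj = ts.make_two_state_trajectory(spec)
        p = ts.pca_covariance(traj, helix10_ca, superpose=False)
        proj = ts.project_onto_pcs(traj, helix10_ca, p, k=1,
                                   superpose=False)[:, 0]
        lo, hi = proj[proj < proj.mean()], proj[proj >= proj.mean()]
        separation = hi.mean() - lo.mean()
        # planted inter-state distance along PC1: shift * sqrt(5 CAs moved)
        assert separation == pytest.approx(shift * np.sqrt(5), rel=0.05)

    def test_invalid_k_rejected(self, helix10, helix10_ca):
        spec = ts.EnsembleSpec(reference=helix10, sigma=0.3, n_frames=50,
                               seed=1)
        traj = ts.make_gaussian_ensemble(spec)
        p = ts.pca_covariance(traj, helix10_ca)
        with pytest.raises(ValueError):
            ts.project_onto_pcs(traj, helix10_ca, p, k=0)
        with pytest.raises(ValueError):
            ts.project_onto_pcs(traj, helix10_ca, p, k=31)


class TestModeProfile:
    def _localized_mode_pca(self, helix10, helix10_ca):
        v = np.zeros(30)
        v[3 * 4: 3 * 5] = [0.6, 0.8, 0.0]   # all weight on residue 5's CA
        amps = np.random.default_rng(2).standard_normal(500)
        frames = np.repeat(helix10.coords[None], 500, axis=0)
        frames[:, helix10_ca.indices, :] += \
            (amps[:, None] * v[None]).reshape(500, 10, 3)
        traj = make_trajectory(helix10, frames)
        return ts.pca_covariance(traj, helix10_ca, superpose=False)

    def test_localized_mode_profile(self, helix10, helix10_ca):
        p = self._localized_mode_pca(helix10, helix10_ca)
        profile, plus, minus = ts.mode_profile(p, helix10, helix10_ca, mode=0)
        assert np.argmax(profile.values) == 4
        others = np.delete(profile.values, 4)
        np.testing.assert_allclose(others, 0.0, atol=1e-6)
        assert np.sum(profile.values**2) == pytest.approx(1.0, abs=1e-9)
        # extremes displaced symmetrically about the mean
        np.testing.assert_allclose(plus + minus, 2 * p.mean_structure,
                                   atol=1e-9)

    def test_invalid_mode_rejected(self, helix10, helix10_ca):
        p = self._localized_mode_pca(helix10, helix10_ca)
        with pytest.raises(ValueError):
            ts.mode_profile(p, helix10, helix10_ca, mode=99)
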