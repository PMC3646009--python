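"""Superposition, RMSF, covariance PCA, subspace overlap, correlations."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from srpatch.io import read_pdb
from srpatch.synth import (
    EnsembleSpec,
    build_ensemble,
    internal_modes,
    make_hinge_mode,
    orthonormalize,
)
from srpatch.trajectory import (
    Ensemble,
    PCAResult,
    correlated_motions,
    covariance_pca,
    kabsch_superpose,
    porcupine_export,
    rmsf,
    subspace_overlap,
)


def random_modes(n3: int, k: int, rng) -> np.ndarray:
    return orthonormalize(rng.normal(size=(k, n3)))


def random_internal_modes(bundle, k: int, rng) -> np.ndarray:
    """Random orthonormal modes free of rigid translation/rotation, so frame
    superposition cannot absorb part of the planted motion."""
    ca = bundle.single_chain().ca_coords()
    return internal_modes(rng.normal(size=(k, ca.size)), ca)


class TestKabsch:
    def test_rotated_copy_superposes_exactly(self, rng):
        x = rng.normal(size=(20, 3))
        rot = Rotation.from_euler("zyx", [0.3, -1.0, 2.2]).as_matrix()
        y = x @ rot.T + np.array([1.0, -2.0, 3.0])
        _, _, rmsd = kabsch_superpose(y, x)
        assert rmsd < 1e-9

    def test_self_superposition_identity(self, rng):
        x = rng.normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(x, x)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_proper_rotation_even_for_reflected_input(self, rng):
        x = rng.normal(size=(12, 3))
        y = x * np.array([1.0, 1.0, -1.0])  # mirror image
        rot, _, _ = kabsch_superpose(y, x)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_quaternion_oracle_on_perturbed_tetrahedra(self):
        # independent optimal-rotation route via scipy's quaternion solver
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]], float)
        mobile = ref.copy()
        mobile[3] += np.array([1.0, 0, 0])
        rot_s, rssd = Rotation.align_vectors(ref - ref.mean(0), mobile - mobile.mean(0))
        oracle_rmsd = rssd / np.sqrt(len(ref))
        _, _, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd == pytest.approx(oracle_rmsd, abs=1e-9)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)


class TestRmsf:
    def test_static_ensemble_zero(self, bundle):
        ref = bundle.single_chain().ca_coords()
        e = Ensemble(np.repeat(ref[None], 5, axis=0))
        assert np.allclose(rmsf(e), 0.0, atol=1e-12)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            Ensemble(np.zeros((1, 10, 3)))

    def test_isotropic_noise_closed_form(self, bundle):
        sigma = 0.5
        spec = EnsembleSpec(np.zeros((0, 3 * 58)), (),
                            noise_sigma=sigma, n_frames=2000, seed=5)
        e = build_ensemble(bundle, spec)
        values = rmsf(e)
        expected = sigma * np.sqrt(3.0)
        assert np.mean(values) == pytest.approx(expected, rel=0.05)

    def test_hinge_mode_rmsf_follows_lever_arm(self, bundle, bundle_spec):
        # pivot inside the second loop: the mobile C-terminal helix swings
        # with amplitude proportional to its distance from the rotation axis
        h1, h2, _ = bundle_spec.helix_lengths
        pivot = h1 + bundle_spec.loop_lengths[0] + h2 + 1
        mode = make_hinge_mode(bundle, pivot)
        e = build_ensemble(bundle, EnsembleSpec(mode, (3.0,), 0.05, 600, 3))
        values = rmsf(e)
        assert values[-5:].mean() > values[pivot - 2:pivot + 3].mean()
        mode_norms = np.linalg.norm(mode.reshape(-1, 3), axis=1)
        mobile = slice(pivot + 1, len(values))
        r = np.corrcoef(values[mobile], mode_norms[mobile])[0, 1]
        assert r > 0.8


class TestPca:
    def test_single_planted_mode_recovered(self, bundle, rng):
        mode = random_internal_modes(bundle, 1, rng)
        e = build_ensemble(bundle, EnsembleSpec(mode, (3.0,), 0.0, 500, 7))
        pca = covariance_pca(e)
        assert abs(np.dot(pca.eigenvectors[0], mode[0])) > 0.99
        assert pca.eigenvalues[1] <= 1e-4 * pca.eigenvalues[0] + 1e-9

    def test_trace_identity(self, bundle, rng):
        modes = random_modes(3 * 58, 3, rng)
        e = build_ensemble(bundle, EnsembleSpec(modes, (3.0, 2.0, 1.0), 0.1, 400, 7))
        from srpatch.trajectory import superpose_ensemble
        sup = superpose_ensemble(e)
        x = sup.coords.reshape(sup.n_frames, -1)
        total_var = ((x - x.mean(0)) ** 2).mean(axis=0).sum()
        pca = covariance_pca(e)
        assert pca.eigenvalues.sum() == pytest.approx(total_var, rel=1e-6)

    def test_eigenvalue_order_matches_amplitudes(self, bundle, rng):
        modes = random_internal_modes(bundle, 3, rng)
        e = build_ensemble(bundle, EnsembleSpec(modes, (3.0, 2.0, 1.0), 0.05, 2000, 9))
        pca = covariance_pca(e)
        for k in range(3):
            assert abs(np.dot(pca.eigenvectors[k], modes[k])) > 0.95

    def test_rigid_motion_of_all_frames_irrelevant(self, bundle, rng):
        modes = random_modes(3 * 58, 1, rng)
        e = build_ensemble(bundle, EnsembleSpec(modes, (2.0,), 0.1, 200, 11))
        rot = Rotation.from_euler("xyz", [1.0, 0.5, -0.7]).as_matrix()
        moved = Ensemble(e.coords @ rot.T + np.array([4.0, 5.0, -6.0]), e.aa,
                         e.author_numbers)
        a, b = covariance_pca(e), covariance_pca(moved)
        assert np.allclose(a.eigenvalues[:10], b.eigenvalues[:10], rtol=1e-6, atol=1e-9)
        assert np.allclose(rmsf(e), rmsf(moved), rtol=1e-6)


class TestSubspaceOverlap:
    def _pca_from(self, vecs):
        k, n3 = vecs.shape
        return PCAResult(np.arange(k, 0, -1, dtype=float), vecs, np.zeros((n3 // 3, 3)))

    def test_identical_sets_give_one(self, rng):
        v = random_modes(60, 10, rng)
        p = self._pca_from(v)
        ov = subspace_overlap(p, p, k=10)
        assert ov.average_square_projection == pytest.approx(1.0)

    def test_orthogonal_complement_gives_zero(self):
        eye = np.eye(60)
        a = self._pca_from(eye[:10])
        b = self._pca_from(eye[10:20])
        assert subspace_overlap(a, b, 10).average_square_projection == pytest.approx(0.0)

    def test_swapping_eigenvectors_preserves_subspace(self, rng):
        v = random_modes(60, 10, rng)
        swapped = v.copy()
        swapped[[0, 1]] = swapped[[1, 0]]
        ov = subspace_overlap(self._pca_from(v), self._pca_from(swapped), 10)
        assert ov.average_square_projection == pytest.approx(1.0)
        assert ov.pair_matrix[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert ov.pair_matrix[0, 1] == pytest.approx(1.0)

    def test_symmetric(self, rng):
        a = self._pca_from(random_modes(90, 10, rng))
        b = self._pca_from(random_modes(90, 10, rng))
        ab = subspace_overlap(a, b, 10).average_square_projection
        ba = subspace_overlap(b, a, 10).average_square_projection
        assert abs(ab - ba) < 1e-12

    def test_random_subspaces_concentrate_at_k_over_dim(self, rng):
        dim, k = 300, 10
        vals = [subspace_overlap(self._pca_from(random_modes(dim, k, rng)),
                                 self._pca_from(random_modes(dim, k, rng)),
                                 k).average_square_projection
                for _ in range(5)]
        expected = k / dim
        assert expected / 3 < np.mean(vals) < expected * 3

    def test_dimension_mismatch_rejected(self, rng):
        a = self._pca_from(random_modes(30, 5, rng))
        b = self._pca_from(random_modes(60, 5, rng))
        with pytest.raises(ValueError):
            subspace_overlap(a, b, 5)


class TestCorrelatedMotions:
    def test_common_mode_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, 3)) * 10
        frames = []
        for t in range(100):
            shift = np.sin(t / 7.0) * np.array([1.0, 0, 0])
            f = base.copy()
            f[2] += shift
            f[7] += shift
            frames.append(f)
        pairs = correlated_motions(Ensemble(np.array(frames)), threshold=0.8)
        assert any(i == 2 and j == 7 for i, j, _ in pairs)

    def test_antiphase_reported_with_negative_sign(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 3)) * 10
        frames = []
        for t in range(100):
            shift = np.sin(t / 7.0) * np.array([1.0, 0, 0])
            f = base.copy()
            f[2] += shift
            f[7] -= shift
            frames.append(f)
        pairs = correlated_motions(Ensemble(np.array(frames)), threshold=0.8)
        match = [c for i, j, c in pairs if i == 2 and j == 7]
        assert match and match[0] < -0.8

    def test_independent_noise_below_threshold(self, bundle):
        spec = EnsembleSpec(np.zeros((0, 3 * 58)), (), 0.3, 2000, 13)
        e = build_ensemble(bundle, spec)
        assert correlated_motions(e, threshold=0.8) == []


class TestPorcupine:
    def _pca(self, bundle, rng):
        modes = random_modes(3 * 58, 1, rng)
        e = build_ensemble(bundle, EnsembleSpec(modes, (3.0,), 0.05, 200, 21))
        return covariance_pca(e)

    def test_zero_mode_writes_identical_models(self, bundle, tmp_path, rng):
        p = self._pca(bundle, rng)
        p.eigenvectors[5] = 0.0
        out = tmp_path / "zero.pdb"
        porcupine_export(p, 5, 5.0, out)
        m1, m2 = read_pdb(out, model_policy="all")
        assert np.allclose(m1.coords(), m2.coords())

    def test_displacement_equals_scale_times_component(self, bundle, tmp_path, rng):
        p = self._pca(bundle, rng)
        out = tmp_path / "m0.pdb"
        porcupine_export(p, 0, 5.0, out)
        m1, m2 = read_pdb(out, model_policy="all")
        disp = m2.coords() - m1.coords()
        expected = 5.0 * p.eigenvectors[0].reshape(-1, 3)
        assert np.allclose(disp, expected, atol=2e-3)  # PDB precision

    def test_round_trip_preserves_direction(self, bundle, tmp_path, rng):
        p = self._pca(bundle, rng)
        out = tmp_path / "m.pdb"
        porcupine_export(p, 0, 5.0, out)
        m1, m2 = read_pdb(out, model_policy="all")
        disp = (m2.coords() - m1.coords()).reshape(-1)
        cos = np.dot(disp, 5.0 * p.eigenvectors[0]) / (
            np.linalg.norm(disp) * 5.0)
        assert cos > 0.999

    def test_mode_out_of_range(self, bundle, tmp_path, rng):
        p = self._pca(bundle, rng)
        with pytest.raises(ValueError):
            porcupine_export(p, 10 ** 6, 5.0, tmp_path / "x.pdb")
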