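"""Patch machinery, OMP sparse coding, K-SVD learning, reconstruction."""

import itertools

import numpy as np
import pytest

from dictmri import dictionary as dl
from dictmri import fourier, metrics
from dictmri import synthetic as syn


class TestPatches:
    def test_whole_image_single_patch(self, rng):
        img = rng.random((8, 8))
        Y = dl.extract_patches(img, dl.PatchConfig(patch_size=8, stride=8))
        assert Y.shape == (64, 1)
        np.testing.assert_array_equal(Y[:, 0], img.ravel())

    def test_grid_count(self, rng):
        Y = dl.extract_patches(rng.random((16, 16)), dl.PatchConfig(patch_size=8, stride=4))
        assert Y.shape[1] == 9

    def test_reassembly_inverts_extraction(self, phantom32):
        cfg = dl.PatchConfig(patch_size=8, stride=3, remove_mean=False)
        Y = dl.extract_patches(phantom32, cfg)
        back = dl.reassemble_patches(Y, phantom32.shape, cfg)
        np.testing.assert_allclose(back, phantom32, atol=1e-12)

    def test_patch_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            dl.extract_patches(np.zeros((4, 4)), dl.PatchConfig(patch_size=8, stride=1))


def _random_dictionary(rng, dim=5, n_atoms=8, T=2):
    D = rng.standard_normal((dim, n_atoms))
    D /= np.linalg.norm(D, axis=0)
    return dl.PatchDictionary(atoms=D, sparsity_T=T)


class TestOMP:
    def test_identity_basis_single_atom(self):
        dic = dl.PatchDictionary(atoms=np.eye(8), sparsity_T=1)
        y = np.zeros(8)
        y[5] = 3.0
        x = dl.omp_code(y, dic)
        assert x[5] == pytest.approx(3.0)
        assert np.count_nonzero(x) == 1

    def test_orthonormal_two_atom_exact(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        dic = dl.PatchDictionary(atoms=q, sparsity_T=2)
        y = 2.0 * q[:, 1] + 1.0 * q[:, 2]
        x = dl.omp_code(y, dic)
        assert x[1] == pytest.approx(2.0)
        assert x[2] == pytest.approx(1.0)
        assert np.linalg.norm(y - q @ x) < 1e-10

    def test_zero_sparsity_gives_zero_code(self, rng):
        dic = _random_dictionary(rng)
        y = rng.standard_normal(5)
        x = dl.omp_code(y, dic, T=0)
        assert not x.any()

    def test_excess_sparsity_clipped_with_warning(self, rng):
        dic = _random_dictionary(rng)
        with pytest.warns(UserWarning):
            x = dl.omp_code(rng.standard_normal(5), dic, T=100)
        assert np.count_nonzero(x) <= dic.n_atoms

    def test_residual_orthogonal_to_selected_atoms(self, rng):
        dic = _random_dictionary(rng, dim=10, n_atoms=16, T=4)
        y = rng.standard_normal(10)
        x = dl.omp_code(y, dic)
        resid = y - dic.atoms @ x
        support = np.flatnonzero(x)
        assert np.abs(dic.atoms[:, support].T @ resid).max() < 1e-8

    def test_sparsity_constraint_always_holds(self, rng):
        dic = _random_dictionary(rng, dim=8, n_atoms=12, T=3)
        Y = rng.standard_normal((8, 40))
        X = dl.omp_code_batch(Y, dic)
        assert (np.count_nonzero(X, axis=0) <= 3).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_greedy_never_beats_exhaustive(self, seed):
        # full 100-seed sweep lives in the acceptance suite
        r = np.random.default_rng(seed)
        D = r.standard_normal((5, 8))
        D /= np.linalg.norm(D, axis=0)
        dic = dl.PatchDictionary(atoms=D, sparsity_T=2)
        y = r.standard_normal(5)
        res_greedy = np.linalg.norm(y - D @ dl.omp_code(y, dic))
        best = np.linalg.norm(y)
        for k in (1, 2):
            for sup in itertools.combinations(range(8), k):
                c, *_ = np.linalg.lstsq(D[:, list(sup)], y, rcond=None)
                best = min(best, np.linalg.norm(y - D[:, list(sup)] @ c))
        assert res_greedy >= best - 1e-9


class TestLearnDictionary:
    def test_zero_iters_returns_initial_coding(self, rng):
        Y = rng.standard_normal((16, 64))
        dic, X, trace = dl.learn_dictionary(Y, n_atoms=20, T=3, iters=0, seed=0)
        assert len(trace) == 1
        assert trace[0] == pytest.approx(np.linalg.norm(Y - dic.atoms @ X) ** 2)

    def test_objective_nonincreasing_on_phantom_patches(self, phantom64):
        Y = dl.extract_patches(phantom64, dl.PatchConfig(8, 4))
        Y = Y - Y.mean(axis=0, keepdims=True)
        dic, X, trace = dl.learn_dictionary(Y, n_atoms=64, T=8, iters=10, seed=0)
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
        assert trace[-1] <= trace[0]
        assert (np.count_nonzero(X, axis=0) <= 8).all()
        np.testing.assert_allclose(np.linalg.norm(dic.atoms, axis=0), 1.0, atol=1e-10)

    def test_exact_sparse_recovery(self):
        # data exactly T-sparse in a known dictionary: recovery mode drives
        # the relative residual (far) below 1%
        rng = np.random.default_rng(0)
        D_true = rng.standard_normal((16, 32))
        D_true /= np.linalg.norm(D_true, axis=0)
        n = 1500
        X_true = np.zeros((32, n))
        for j in range(n):
            sup = rng.choice(32, 3, replace=False)
            X_true[sup, j] = rng.standard_normal(3)
        Y = D_true @ X_true
        dic, X, _ = dl.learn_dictionary(
            Y, 32, 3, iters=60, seed=0, refine=True, restarts=8, stop_rel=1e-3
        )
        rel = np.linalg.norm(Y - dic.atoms @ X) / np.linalg.norm(Y)
        assert rel < 0.01

    def test_all_zero_data_rejected(self):
        with pytest.raises(ValueError):
            dl.learn_dictionary(np.zeros((8, 32)), n_atoms=8, T=2)


class TestReconstruction:
    def test_full_sampling_forces_ground_truth(self, phantom64):
        s = syn.simulate_acquisition(phantom64, np.ones_like(phantom64, bool))
        x, _ = dl.reconstruct_dict(
            s, dl.PatchConfig(8, 4), dl.DictReconSpec(n_atoms=64, outer_iters=1, train_iters=1)
        )
        assert np.abs(np.real(x) - phantom64).max() < 1e-6 and np.abs(np.imag(x)).max() < 1e-6

    def test_data_consistency_exact_on_sampled_entries(self, sample40):
        x, _ = dl.reconstruct_dict(
            sample40, dl.PatchConfig(8, 4),
            dl.DictReconSpec(n_atoms=64, outer_iters=2, train_iters=2),
        )
        k = fourier.fft2c(x)
        assert np.abs(k[sample40.mask] - sample40.data[sample40.mask]).max() < 1e-10

    def test_beats_zero_filled(self, phantom64, sample40):
        x, _ = dl.reconstruct_dict(sample40)
        zf = np.clip(fourier.zero_filled(sample40.data), 0, 1)
        assert metrics.psnr(phantom64, np.clip(np.real(x), 0, 1)) > metrics.psnr(phantom64, zf)

    def test_unit_norm_atoms_enforced(self):
        with pytest.raises(ValueError):
            dl.PatchDictionary(atoms=2 * np.eye(4), sparsity_T=1)
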