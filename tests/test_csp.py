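"""Multiclass CSP: covariance estimation, joint diagonalization, MI ranking."""

import numpy as np
import pytest
from scipy.linalg import eigh
from scipy.stats import ortho_group

from mdeeg.containers import EpochSet
from mdeeg.csp import (
    apply_csp,
    estimate_class_covs,
    fit_csp,
    fit_jad,
    joint_diagonalize,
    mutual_information_scores,
)


def trace_normed(d):
    m = np.diag(np.asarray(d, float))
    return m / np.trace(m)


def gaussian_epochs(rng, cov_per_class, n_per_class, n_samples=100, fs=100.0):
    chol = [np.linalg.cholesky(c) for c in cov_per_class]
    data, labels = [], []
    for ci, L in enumerate(chol):
        for _ in range(n_per_class):
            data.append(L @ rng.standard_normal((L.shape[0], n_samples)))
            labels.append(ci)
    names = [f"c{i}" for i in range(len(cov_per_class))]
    return EpochSet(np.stack(data), np.array(labels), fs, names)


class TestClassCovariances:
    def test_monte_carlo_recovers_true_covariance(self, rng):
        # 2000 trials from diag(4,1): the trace-normalized estimate converges
        true = np.diag([4.0, 1.0])
        epochs = gaussian_epochs(rng, [true, true], 1000, n_samples=50)
        covs, priors = estimate_class_covs(epochs)
        np.testing.assert_allclose(covs[0], trace_normed([4, 1]), atol=0.02)

    def test_identical_trials_give_identical_covs(self, rng):
        x = rng.standard_normal((1, 3, 50))
        data = np.tile(x, (6, 1, 1))
        epochs = EpochSet(data, np.repeat([0, 1, 2], 2), 100.0, ["a", "b", "c"])
        covs, _ = estimate_class_covs(epochs)
        np.testing.assert_allclose(covs[0], covs[1])
        np.testing.assert_allclose(covs[1], covs[2])

    def test_balanced_priors(self, small_epochs):
        _, priors = estimate_class_covs(small_epochs)
        np.testing.assert_allclose(priors, 1 / 3)

    def test_small_class_rejected(self, rng):
        epochs = EpochSet(rng.standard_normal((3, 2, 20)),
                          np.array([0, 0, 1]), 10.0, ["a", "b"])
        with pytest.raises(ValueError, match="class 1"):
            estimate_class_covs(epochs)


class TestFitJad:
    def test_two_class_matches_generalized_eigendecomposition(self):
        r1, r2 = trace_normed([4, 1]), trace_normed([1, 4])
        model = fit_jad([r1, r2], np.array([0.5, 0.5]))
        for r in (r1, r2):
            a = model.W @ r @ model.W.T
            off = a - np.diag(np.diag(a))
            assert np.abs(off).max() < 1e-8
        # filters align with the generalized eigenvectors up to sign/scale
        _, evecs = eigh(r1, r1 + r2)
        for w in model.W:
            cosines = np.abs(evecs.T @ w) / (np.linalg.norm(evecs, axis=0) * np.linalg.norm(w))
        assert np.isclose(np.sort(cosines)[-1], 1.0, atol=1e-8)

    def test_equal_covariances_carry_no_information(self):
        r = trace_normed([2, 1, 1])
        model = fit_jad([r, r, r], np.full(3, 1 / 3))
        v = np.einsum("jn,nm,jm->j", model.W, r, model.W)
        np.testing.assert_allclose(v, 1.0, atol=1e-10)  # whitened variances all 1
        np.testing.assert_allclose(model.mi_scores, model.mi_scores[0], atol=1e-10)

    def test_whitening_identity(self, rng):
        covs = []
        for _ in range(3):
            a = rng.standard_normal((4, 4))
            s = a @ a.T + 4 * np.eye(4)
            covs.append(s / np.trace(s))
        priors = np.full(3, 1 / 3)
        model = fit_jad(covs, priors)
        acc = sum(p * model.W @ r @ model.W.T for p, r in zip(priors, covs))
        np.testing.assert_allclose(acc, np.eye(4), atol=1e-8)

    def test_beats_random_orthogonal_rotations(self, rng):
        covs = []
        for _ in range(3):
            a = rng.standard_normal((4, 4))
            s = a @ a.T + 4 * np.eye(4)
            covs.append(s / np.trace(s))
        priors = np.full(3, 1 / 3)
        model = fit_jad(covs, priors)

        def off_frob(mats):
            return sum(np.sum((m - np.diag(np.diag(m))) ** 2) for m in mats)

        ours = off_frob([model.W @ r @ model.W.T for r in covs])
        evals, evecs = np.linalg.eigh(sum(p * r for p, r in zip(priors, covs)))
        whitener = (evecs / np.sqrt(evals)).T
        whitened = [whitener @ r @ whitener.T for r in covs]
        rotations = ortho_group.rvs(4, size=1000, random_state=7)
        best_random = min(off_frob([q.T @ c @ q for c in whitened]) for q in rotations)
        assert ours <= best_random + 1e-12

    def test_mi_invariant_to_filter_sign(self):
        r1, r2 = trace_normed([4, 1, 2]), trace_normed([1, 4, 2])
        priors = np.array([0.5, 0.5])
        model = fit_jad([r1, r2], priors)
        v_flip = np.einsum("jn,inm,jm->ji", -model.W, np.stack([r1, r2]), -model.W)
        np.testing.assert_allclose(
            mutual_information_scores(v_flip, priors), model.mi_scores
        )

    def test_singular_average_cov_advises_ridge(self):
        degenerate = np.zeros((2, 2))
        degenerate[0, 0] = 1.0
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_jad([degenerate, degenerate], np.array([0.5, 0.5]))
        fit_jad([degenerate, degenerate], np.array([0.5, 0.5]), ridge=1e-3)

    def test_jacobi_recovers_known_rotation(self, rng):
        # rotate two diagonal matrices by a random orthogonal Q; the Jacobi
        # sweep must diagonalize both again
        q = ortho_group.rvs(5, random_state=3)
        mats = np.stack([q @ np.diag(rng.uniform(0.5, 3, 5)) @ q.T for _ in range(3)])
        v = joint_diagonalize(mats)
        for a in mats:
            d = v.T @ a @ v
            assert np.abs(d - np.diag(np.diag(d))).max() < 1e-8


class TestApplyCsp:
    def test_identity_projection_is_noop(self, small_epochs):
        model = fit_csp(small_epochs)
        n = model.n_channels
        model.W = np.eye(n)
        model.order = np.arange(n)
        out = apply_csp(model, small_epochs, L=n)
        np.testing.assert_allclose(out.data, small_epochs.data)
        assert out.domain == "spatial"

    def test_projected_variance_ratio_matches_eigenvalues(self, rng):
        # two-class toy: the top filter's variance ratio between classes
        # equals the generalized eigenvalue ratio
        c1, c2 = np.diag([4.0, 1.0]), np.diag([1.0, 4.0])
        epochs = gaussian_epochs(rng, [c1, c2], 400, n_samples=200)
        model = fit_csp(epochs)
        z = apply_csp(model, epochs)
        v0 = z.data[epochs.labels == 0].var(axis=(0, 2))
        v1 = z.data[epochs.labels == 1].var(axis=(0, 2))
        ratios = np.sort(v0 / v1)
        # theoretical extreme generalized eigenvalue ratio for 4:1 vs 1:4 is 4/1 : 1/4
        np.testing.assert_allclose(ratios, [0.25, 4.0], rtol=0.15)

    def test_shape_preserved_at_full_rank(self, rng):
        epochs = EpochSet(rng.standard_normal((12, 31, 1000)),
                          np.repeat([0, 1, 2], 4), 250.0, ["a", "b", "c"])
        model = fit_csp(epochs)
        out = apply_csp(model, epochs)
        assert out.data.shape == (12, 31, 1000)

    def test_channel_mismatch_rejected(self, small_epochs, rng):
        model = fit_csp(small_epochs)
        other = EpochSet(rng.standard_normal((4, 7, 50)),
                         np.zeros(4, int), 100.0, ["a"])
        with pytest.raises(ValueError, match="channels"):
            apply_csp(model, other)

    def test_training_only_fit_differs_with_leaked_trials(self, rng):
        # guard: refitting with test trials appended must change the filters
        c1, c2 = np.diag([4.0, 1.0]), np.diag([1.0, 4.0])
        train = gaussian_epochs(rng, [c1, c2], 20)
        extra = gaussian_epochs(rng, [c1, c2], 5)
        w_train = fit_csp(train).W
        pooled = EpochSet(
            np.concatenate([train.data, extra.data]),
            np.concatenate([train.labels, extra.labels]),
            train.fs, train.class_names,
        )
        w_pooled = fit_csp(pooled).W
        assert not np.allclose(w_train, w_pooled)


class TestSerialization:
    def test_fitted_model_roundtrip(self, tmp_path, small_epochs, rng):
        from mdeeg.csp import load_csp, save_csp

        model = fit_csp(small_epochs, ridge=1e-6)
        path = tmp_path / "csp.npz"
        save_csp(model, path)
        back = load_csp(path)
        np.testing.assert_array_equal(back.W, model.W)
        np.testing.assert_array_equal(back.order, model.order)
        assert back.meta == model.meta
        test = EpochSet(rng.standard_normal((3, 4, 50)), np.zeros(3, int),
                        100.0, ["a"])
        np.testing.assert_array_equal(
            apply_csp(back, test).data, apply_csp(model, test).data
        )
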