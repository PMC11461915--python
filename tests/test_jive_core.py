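import numpy as np
import pytest

from jivebatch.io_preprocess import log_normalize
from jivebatch.jive import (
    JIVEModel,
    center,
    correct_batches,
    fit_jive,
    partial_svd,
    variance_explained,
)
from jivebatch.simulate import simulate_lowrank

from conftest import make_collection


class TestCenter:
    def test_pooled_mean_subtracted(self):
        coll = make_collection([[[1.0, 2.0]], [[3.0]]], value_space="lognorm")
        centered, means = center(coll)
        np.testing.assert_allclose(means, [2.0])
        np.testing.assert_allclose(centered.matrices[0], [[-1.0, 0.0]])
        np.testing.assert_allclose(centered.matrices[1], [[1.0]])

    def test_pooled_not_per_batch(self):
        coll = make_collection([[[1.0, 1.0]], [[3.0, 3.0]]], value_space="lognorm")
        centered, means = center(coll)
        np.testing.assert_allclose(means, [2.0])
        np.testing.assert_allclose(centered.matrices[0], [[-1.0, -1.0]])
        np.testing.assert_allclose(centered.matrices[1], [[1.0, 1.0]])

    def test_idempotent_on_centered_values(self, rng):
        m = rng.normal(size=(4, 10))
        m -= m.mean(axis=1, keepdims=True)
        coll = make_collection([m[:, :5], m[:, 5:]], value_space="lognorm")
        centered, means = center(coll)
        np.testing.assert_allclose(means, 0.0, atol=1e-12)
        np.testing.assert_allclose(centered.matrices[0], m[:, :5], atol=1e-12)

    def test_requires_lognorm(self, two_batch_counts):
        with pytest.raises(ValueError, match="log-normalized"):
            center(two_batch_counts)


class TestPartialSVD:
    def test_identity(self):
        t = partial_svd(np.eye(5), 1)
        assert t.s[0] == pytest.approx(1.0)

    def test_rank1_recovery(self, rng):
        u = rng.normal(size=7)
        u /= np.linalg.norm(u)
        v = rng.normal(size=4)
        v /= np.linalg.norm(v)
        t = partial_svd(3.5 * np.outer(u, v), 1)
        assert t.s[0] == pytest.approx(3.5)
        assert abs(np.dot(t.u[:, 0], u)) == pytest.approx(1.0)
        assert abs(np.dot(t.v[:, 0], v)) == pytest.approx(1.0)

    @pytest.mark.parametrize("shape,k", [((20, 15), 3), ((15, 20), 3), ((200, 40), 5), ((40, 200), 7)])
    def test_matches_full_svd(self, rng, shape, k):
        m = rng.normal(size=shape)
        t = partial_svd(m, k)
        u_full, s_full, vt_full = np.linalg.svd(m, full_matrices=False)
        np.testing.assert_allclose(t.s, s_full[:k], rtol=1e-10)
        # compare subspaces via projectors (sign/rotation free)
        np.testing.assert_allclose(
            t.u @ t.u.T, u_full[:, :k] @ u_full[:, :k].T, atol=1e-8
        )
        np.testing.assert_allclose(
            t.v @ t.v.T, vt_full[:k].T @ vt_full[:k], atol=1e-8
        )

    def test_orthonormality_and_order(self, rng):
        t = partial_svd(rng.normal(size=(30, 25)), 4)
        np.testing.assert_allclose(t.u.T @ t.u, np.eye(4), atol=1e-10)
        np.testing.assert_allclose(t.v.T @ t.v, np.eye(4), atol=1e-10)
        assert np.all(np.diff(t.s) <= 0) and np.all(t.s >= 0)

    def test_sign_convention(self, rng):
        t = partial_svd(rng.normal(size=(12, 9)), 3)
        for j in range(3):
            assert t.u[np.argmax(np.abs(t.u[:, j])), j] > 0

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError, match="out of range"):
            partial_svd(rng.normal(size=(5, 4)), 5)
        with pytest.raises(ValueError, match="out of range"):
            partial_svd(rng.normal(size=(5, 4)), 0)


class TestFitJIVE:
    def test_noise_free_exact_recovery(self):
        coll, _ = simulate_lowrank(
            n_rows=(30, 40), p=25, joint_rank=2, individual_ranks=(1, 1), noise_sd=0.0, seed=0
        )
        model = fit_jive(coll, 2, [1, 1], tol=1e-10, max_iter=3000)
        Y = np.vstack([m.T for m in coll.matrices])
        recon = np.vstack(model.joint_blocks()) + np.vstack(model.individual_blocks())
        assert np.linalg.norm(Y - recon) < 1e-8 * np.linalg.norm(Y)
        assert model.converged

    def test_degenerate_ranks_zero(self, rng):
        m = rng.normal(size=(6, 8))
        coll = make_collection([m[:, :4], m[:, 4:]], value_space="lognorm")
        centered, _ = center(coll)
        model = fit_jive(centered, 0, [0, 0])
        assert model.n_iter == 1
        assert np.all(np.vstack(model.joint_blocks()) == 0)
        assert np.all(np.vstack(model.individual_blocks()) == 0)
        np.testing.assert_allclose(
            model.objective_trace[-1],
            sum(float(np.sum(m * m)) for m in centered.matrices),
        )

    def test_orthogonality_invariant(self, rng):
        coll, _ = simulate_lowrank(
            n_rows=(25, 35), p=30, joint_rank=2, individual_ranks=(2, 3), noise_sd=0.5, seed=4
        )
        model = fit_jive(coll, 2, [2, 3])
        scale = max(np.linalg.norm(m.T) for m in coll.matrices)
        for s_i in model.individual_loadings:
            assert np.linalg.norm(model.joint_loadings @ s_i.T) < 1e-8 * scale

    def test_objective_nonincreasing(self, rng):
        coll, _ = simulate_lowrank(
            n_rows=(20, 20), p=15, joint_rank=1, individual_ranks=(2, 2), noise_sd=1.0, seed=9
        )
        model = fit_jive(coll, 1, [2, 2])
        diffs = np.diff(model.objective_trace)
        assert np.all(diffs <= 1e-9 * model.objective_trace[0])

    def test_additivity_reconstruction(self):
        coll, _ = simulate_lowrank(
            n_rows=(15, 25), p=20, joint_rank=2, individual_ranks=(1, 2), noise_sd=1.0, seed=2
        )
        model = fit_jive(coll, 2, [1, 2])
        # Y = J + A + R exactly where R is defined as the remainder; check
        # that J and A are genuinely low rank and orthogonal instead
        for j_block, r in zip(model.joint_blocks(), [2, 2]):
            assert np.linalg.matrix_rank(j_block, tol=1e-8) <= r
        for a_block, ri in zip(model.individual_blocks(), [1, 2]):
            assert np.linalg.matrix_rank(a_block, tol=1e-8) <= ri

    def test_identical_batches_pure_joint(self, rng):
        x = rng.normal(size=(10, 3)) @ rng.normal(size=(3, 12))
        coll = make_collection([x.T, x.T], value_space="centered")
        model = fit_jive(coll, 3, [0, 0], tol=1e-12, max_iter=2000)
        j1, j2 = model.joint_blocks()
        np.testing.assert_allclose(j1, j2, atol=1e-8)
        np.testing.assert_allclose(j1, x, atol=1e-6)

    def test_requires_centered(self, two_batch_counts):
        with pytest.raises(ValueError, match="centered"):
            fit_jive(two_batch_counts, 1, [1, 1])

    def test_rank_exceeding_dims_errors(self, rng):
        m = rng.normal(size=(4, 6))
        coll = make_collection([m[:, :3], m[:, 3:]], value_space="centered")
        with pytest.raises(ValueError, match="rank"):
            fit_jive(coll, 10, [1, 1])
        with pytest.raises(ValueError, match="rank"):
            fit_jive(coll, 1, [10, 1])

    def test_multistart_bruteforce_oracle(self):
        """Final SSE matches a 20-restart random-init alternating minimizer."""
        seed = 3
        rng = np.random.default_rng(seed)
        Ys = [rng.standard_normal((10, 8)) for _ in range(2)]
        coll = make_collection([y.T for y in Ys], value_space="centered")
        model = fit_jive(coll, 1, [1, 1], tol=1e-12, max_iter=5000, n_restarts=20, seed=99)
        sse = model.objective_trace[-1]
        best = _bruteforce_als_best(Ys, 1, [1, 1], n_restarts=20, seed=seed * 7)
        assert sse == pytest.approx(best, rel=1e-8)


def _bruteforce_als_best(Ys, r, ranks, n_restarts, seed):
    """Independent multi-start alternating minimizer (full numpy SVDs only)."""
    ns = [y.shape[0] for y in Ys]
    p = Ys[0].shape[1]
    Y = np.vstack(Ys)
    offsets = np.concatenate([[0], np.cumsum(ns)])
    best = np.inf
    master = np.random.default_rng(seed)
    for _ in range(n_restarts):
        rng = np.random.default_rng(master.integers(2**63))
        A = [
            (rng.standard_normal((ni, ri)) @ rng.standard_normal((ri, p)))
            if ri > 0
            else np.zeros((ni, p))
            for ni, ri in zip(ns, ranks)
        ]
        J = np.zeros_like(Y)
        V = np.zeros((p, 0))
        for _ in range(20000):
            J_old, A_old = J.copy(), [a.copy() for a in A]
            if r > 0:
                u, s, vt = np.linalg.svd(Y - np.vstack(A), full_matrices=False)
                J = (u[:, :r] * s[:r]) @ vt[:r]
                V = vt[:r].T
            A = []
            for i, y in enumerate(Ys):
                resid = y - J[offsets[i] : offsets[i + 1]]
                if ranks[i] > 0:
                    if V.shape[1]:
                        resid = resid - (resid @ V) @ V.T
                    u, s, vt = np.linalg.svd(resid, full_matrices=False)
                    A.append((u[:, : ranks[i]] * s[: ranks[i]]) @ vt[: ranks[i]])
                else:
                    A.append(np.zeros_like(y))
            change = max(
                np.linalg.norm(J - J_old),
                max(np.linalg.norm(a - ao) for a, ao in zip(A, A_old)),
            ) / max(np.linalg.norm(Y), 1e-12)
            if change < 1e-12:
                break
        best = min(best, float(np.sum((Y - J - np.vstack(A)) ** 2)))
    return best


class TestVarianceExplained:
    def test_pure_joint(self):
        coll, _ = simulate_lowrank(
            n_rows=(20, 30), p=15, joint_rank=1, individual_ranks=(0, 0), noise_sd=0.0, seed=1
        )
        model = fit_jive(coll, 1, [0, 0], tol=1e-12, max_iter=2000)
        ve = variance_explained(model, coll)
        np.testing.assert_allclose(ve, [[1, 0, 0], [1, 0, 0]], atol=1e-10)

    def test_pure_noise_zero_ranks(self, rng):
        m = rng.normal(size=(8, 12))
        coll = make_collection([m[:, :6], m[:, 6:]], value_space="centered")
        model = fit_jive(coll, 0, [0, 0])
        ve = variance_explained(model, coll)
        np.testing.assert_allclose(ve, [[0, 0, 1], [0, 0, 1]], atol=1e-12)

    def test_rows_sum_to_one_and_match_norms(self):
        coll, _ = simulate_lowrank(
            n_rows=(25, 25), p=20, joint_rank=2, individual_ranks=(1, 1), noise_sd=0.8, seed=6
        )
        model = fit_jive(coll, 2, [1, 1])
        ve = variance_explained(model, coll)
        np.testing.assert_allclose(ve.sum(axis=1), 1.0, atol=1e-6)
        # direct Frobenius-norm oracle
        for i, (m, ji, ai) in enumerate(
            zip(coll.matrices, model.joint_blocks(), model.individual_blocks())
        ):
            y = m.T
            tot = np.sum(y**2)
            assert ve[i, 0] == pytest.approx(np.sum(ji**2) / tot)
            assert ve[i, 1] == pytest.approx(np.sum(ai**2) / tot)
            assert ve[i, 2] == pytest.approx(np.sum((y - ji - ai) ** 2) / tot)


class TestCorrectBatches:
    def test_joint_only_recovers_input(self):
        coll, _ = simulate_lowrank(
            n_rows=(20, 20), p=15, joint_rank=2, individual_ranks=(0, 0), noise_sd=0.0, seed=5
        )
        model = fit_jive(coll, 2, [0, 0], tol=1e-12, max_iter=2000)
        corrected, scores = correct_batches(model)
        np.testing.assert_allclose(corrected, coll.stacked(), atol=1e-8)
        assert scores.shape == (40, 2)

    def test_zero_rank_warns_and_is_zero(self, rng):
        m = rng.normal(size=(6, 10))
        coll = make_collection([m[:, :5], m[:, 5:]], value_space="centered")
        model = fit_jive(coll, 0, [1, 1])
        with pytest.warns(UserWarning, match="identically zero"):
            corrected, _ = correct_batches(model)
        np.testing.assert_array_equal(corrected, 0.0)

    def test_output_rank_bounded(self):
        coll, _ = simulate_lowrank(
            n_rows=(25, 25), p=30, joint_rank=3, individual_ranks=(2, 2), noise_sd=1.0, seed=8
        )
        model = fit_jive(coll, 3, [2, 2])
        corrected, _ = correct_batches(model)
        svals = np.linalg.svd(corrected, compute_uv=False)
        assert np.sum(svals > 1e-8 * svals[0]) <= 3

    def test_add_back_means(self, rng):
        counts = make_collection([rng.poisson(8.0, (5, 6)), rng.poisson(8.0, (5, 7))])
        lognorm = log_normalize(counts)
        centered, means = center(lognorm)
        model = fit_jive(centered, 2, [1, 1], gene_means=means)
        plain, _ = correct_batches(model, add_back_means=False)
        shifted, _ = correct_batches(model, add_back_means=True)
        np.testing.assert_allclose(shifted - plain, np.tile(means[:, None], (1, 13)))


class TestModelSerialization:
    def test_npz_roundtrip(self, tmp_path):
        coll, _ = simulate_lowrank(
            n_rows=(10, 12), p=9, joint_rank=1, individual_ranks=(1, 2), noise_sd=0.3, seed=12
        )
        model = fit_jive(coll, 1, [1, 2])
        model.save(tmp_path / "model.npz")
        loaded = JIVEModel.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(loaded.joint_scores, model.joint_scores)
        np.testing.assert_array_equal(loaded.joint_loadings, model.joint_loadings)
        for a, b in zip(loaded.individual_scores, model.individual_scores):
            np.testing.assert_array_equal(a, b)
        assert loaded.individual_ranks == model.individual_ranks
        assert loaded.batch_labels == model.batch_labels
        assert loaded.cell_ids == model.cell_ids
        assert loaded.converged == model.converged
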