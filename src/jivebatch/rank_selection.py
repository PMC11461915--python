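"""Permutation-test selection of joint and individual ranks.

The shared axis here is genes (horizontal integration), so the null for the
joint rank is built by independently permuting the gene (column) order of
each transposed batch: this destroys cross-batch gene alignment, and with it
any joint structure, while leaving each batch's own covariance intact.  The
null for an individual rank permutes the entries within each column of that
batch's joint-removed residual, destroying all low-rank structure.

A singular value is deemed significant when it exceeds the (1 - alpha)
quantile of the corresponding null singular values; testing is sequential
and stops at the first non-significant value, so selected ranks are leading
blocks.  Joint and individual tests alternate with model refits until the
ranks stabilize.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from jivebatch.io_preprocess import BatchCollection
from jivebatch.jive import fit_jive

DEFAULT_R_MAX = 50


@dataclass
class RankSelectionResult:
    """Selected ranks plus the permutation-null evidence behind them."""

    joint_rank: int
    individual_ranks: list[int]
    n_permutations: int
    alpha: float
    joint_singular_values: np.ndarray
    joint_null_quantiles: np.ndarray
    individual_singular_values: list[np.ndarray]
    individual_null_quantiles: list[np.ndarray]
    n_cycles: int
    converged: bool
    history: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "joint_rank": self.joint_rank,
            "individual_ranks": self.individual_ranks,
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "joint_singular_values": self.joint_singular_values.tolist(),
            "joint_null_quantiles": self.joint_null_quantiles.tolist(),
            "individual_singular_values": [s.tolist() for s in self.individual_singular_values],
            "individual_null_quantiles": [q.tolist() for q in self.individual_null_quantiles],
            "n_cycles": self.n_cycles,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _leading_count(observed: np.ndarray, null_q: np.ndarray) -> int:
    """Number of leading observed singular values exceeding their null quantile."""
    r = 0
    for obs, q in zip(observed, null_q):
        if obs > q:
            r += 1
        else:
            break
    return r


def _svals(matrix: np.ndarray, k: int) -> np.ndarray:
    s = np.linalg.svd(matrix, compute_uv=False)
    return s[:k]


def select_ranks_permutation(
    collection: BatchCollection,
    n_perm: int = 100,
    alpha: float = 0.05,
    max_cycles: int = 10,
    seed: int | np.random.Generator | None = None,
    r_max: int = DEFAULT_R_MAX,
) -> RankSelectionResult:
    """Choose the joint rank and per-batch individual ranks by permutation testing.

    Parameters
    ----------
    collection
        Centered collection with at least two batches.
    n_perm
        Null sample size per test; must be at least 19 so that a
        ``1 - alpha`` quantile at ``alpha = 0.05`` is attainable.
    alpha
        Per-singular-value significance level.
    max_cycles
        Cap on test-refit alternations.
    seed
        Seed or generator driving every permutation.
    r_max
        Upper bound on any tested rank, limiting SVD cost on large inputs.
    """
    if collection.value_space != "centered":
        raise ValueError("rank selection expects a centered collection")
    if collection.n_batches < 2:
        raise ValueError("rank selection requires at least 2 batches")
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 for alpha = 0.05 to be attainable")
    rng = np.random.default_rng(seed)

    Ys = [m.T.copy() for m in collection.matrices]
    ns = [y.shape[0] for y in Ys]
    n, p = sum(ns), Ys[0].shape[1]
    k = len(Ys)

    if all(np.allclose(y, y.flat[0] if y.size else 0.0) for y in Ys):
        warnings.warn("degenerate constant input: selecting all ranks 0", stacklevel=2)
        zq = np.zeros(0)
        return RankSelectionResult(
            joint_rank=0,
            individual_ranks=[0] * k,
            n_permutations=n_perm,
            alpha=alpha,
            joint_singular_values=zq,
            joint_null_quantiles=zq,
            individual_singular_values=[zq.copy() for _ in range(k)],
            individual_null_quantiles=[zq.copy() for _ in range(k)],
            n_cycles=0,
            converged=True,
        )

    k_joint = min(r_max, n, p)
    k_indiv = [min(r_max, ni, p) for ni in ns]

    r, ranks = 0, [0] * k
    A = [np.zeros_like(y) for y in Ys]
    J_blocks = [np.zeros_like(y) for y in Ys]

    history: list[tuple[int, tuple[int, ...]]] = []
    joint_obs = np.zeros(0)
    joint_q = np.zeros(0)
    indiv_obs = [np.zeros(0)] * k
    indiv_q = [np.zeros(0)] * k
    converged = False
    cycle = 0

    for cycle in range(1, max_cycles + 1):
        # (a) joint rank: stacked matrix with individual structure removed,
        # null = per-batch independent gene-order permutation
        resid_joint = [y - a for y, a in zip(Ys, A)]
        joint_obs = _svals(np.vstack(resid_joint), k_joint)
        null = np.empty((n_perm, k_joint))
        for t in range(n_perm):
            perm_stack = np.vstack(
                [ri[:, rng.permutation(p)] for ri in resid_joint]
            )
            null[t] = _svals(perm_stack, k_joint)
        joint_q = np.quantile(null, 1 - alpha, axis=0)
        r_new = _leading_count(joint_obs, joint_q)

        # (b) individual ranks: per batch, joint-removed residual, null =
        # independent permutation of the entries within each column
        ranks_new = []
        for i in range(k):
            resid_i = Ys[i] - J_blocks[i]
            indiv_obs[i] = _svals(resid_i, k_indiv[i])
            null_i = np.empty((n_perm, k_indiv[i]))
            for t in range(n_perm):
                # independent row shuffle per column via random-key argsort
                keys = np.argsort(rng.random(resid_i.shape), axis=0)
                shuffled = np.take_along_axis(resid_i, keys, axis=0)
                null_i[t] = _svals(shuffled, k_indiv[i])
            indiv_q[i] = np.quantile(null_i, 1 - alpha, axis=0)
            ranks_new.append(_leading_count(indiv_obs[i], indiv_q[i]))

        history.append((r_new, tuple(ranks_new)))
        if r_new == r and ranks_new == ranks:
            converged = True
            break
        r, ranks = r_new, ranks_new

        # (c) refit at the new ranks and repeat; zero-initialized so that
        # aligned cross-batch structure is attributed to the joint part first
        model = fit_jive(collection, r, ranks, tol=1e-6, max_iter=500, init="zero")
        J_blocks = model.joint_blocks()
        A = model.individual_blocks()

    return RankSelectionResult(
        joint_rank=r,
        individual_ranks=ranks,
        n_permutations=n_perm,
        alpha=alpha,
        joint_singular_values=joint_obs,
        joint_null_quantiles=joint_q,
        individual_singular_values=[np.asarray(s) for s in indiv_obs],
        individual_null_quantiles=[np.asarray(q) for q in indiv_q],
        n_cycles=cycle,
        converged=converged,
        history=history,
    )
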