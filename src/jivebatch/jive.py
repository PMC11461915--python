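"""Joint-and-individual low-rank decomposition of multi-batch expression data.

Each batch matrix ``X_i`` (genes x cells) is transposed to ``Y_i = X_i.T``
(cells x genes); the stacked cells-by-genes matrix is decomposed as

    Y_i = U_i S + W_i S_i + R_i

with a joint structure ``U S`` shared across batches (``S`` is a common
r x p loading matrix), per-batch individual structures ``W_i S_i`` whose
loadings are constrained orthogonal to the joint loadings (``S S_i.T = 0``),
and residuals ``R_i``.  Estimation alternates two least-squares steps —
truncated SVD of the stacked matrix with individual structure removed, then
truncated SVD of each joint-removed residual projected onto the orthogonal
complement of the joint row space — driving the summed squared residual down
monotonically.  The joint structure supplies both the batch-corrected matrix
``(U_i S).T`` and the per-cell embedding ``U``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import svds

from jivebatch.io_preprocess import BatchCollection, with_value_space

logger = logging.getLogger(__name__)

# above this many matrix entries the dense math path warns about memory
_DENSE_WARN_ENTRIES = 200_000_000


@dataclass
class SVDTriplet:
    """The ``k`` leading singular triplets of a matrix.

    ``u`` has orthonormal columns (m x k), ``s`` is non-increasing and
    nonnegative, ``v`` has orthonormal columns (p x k); ``M ~ u @ diag(s) @ v.T``.
    """

    u: np.ndarray
    s: np.ndarray
    v: np.ndarray


def partial_svd(matrix: np.ndarray, k: int) -> SVDTriplet:
    """Return the ``k`` leading singular triplets of ``matrix``.

    Equals the first ``k`` columns/values of a full SVD up to sign of paired
    singular vectors; for reproducibility each left singular vector is
    flipped so that its largest-magnitude entry is positive.
    """
    matrix = np.asarray(matrix, dtype=float)
    m, p = matrix.shape
    if not 1 <= k <= min(m, p):
        raise ValueError(f"k={k} out of range for a {m}x{p} matrix")
    small, large = min(m, p), max(m, p)
    if small > 50 and large >= 2 * small:
        # strongly rectangular: eigendecomposition of the small-side Gram
        # matrix is much cheaper than an SVD of the full matrix
        u, s, vt = _gram_svd(matrix, k)
    elif k < small - 1 and small > 20 and k <= small // 4:
        u, s, vt = svds(matrix, k=k, solver="arpack", random_state=0)
        order = np.argsort(-s)
        u, s, vt = u[:, order], s[order], vt[order, :]
    else:
        u, s, vt = np.linalg.svd(matrix, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k, :]
    # deterministic sign: largest-|entry| of each left vector positive
    for j in range(k):
        i = np.argmax(np.abs(u[:, j]))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
            vt[j, :] = -vt[j, :]
    return SVDTriplet(u=u, s=s, v=vt.T)


def _gram_svd(matrix: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leading triplets via the Gram matrix of the smaller dimension."""
    m, p = matrix.shape
    if m <= p:
        g = matrix @ matrix.T
        w, q = np.linalg.eigh(g)  # ascending
        w, q = w[::-1][:k], q[:, ::-1][:, :k]
        s = np.sqrt(np.maximum(w, 0.0))
        u = q
        vt = np.empty((k, p))
        for j in range(k):
            vt[j] = (matrix.T @ u[:, j]) / s[j] if s[j] > 0 else 0.0
    else:
        g = matrix.T @ matrix
        w, q = np.linalg.eigh(g)
        w, q = w[::-1][:k], q[:, ::-1][:, :k]
        s = np.sqrt(np.maximum(w, 0.0))
        vt = q.T
        u = np.empty((m, k))
        for j in range(k):
            u[:, j] = (matrix @ q[:, j]) / s[j] if s[j] > 0 else 0.0
    return u, s, vt


@dataclass
class JIVEModel:
    """A fitted joint/individual decomposition.

    ``joint_scores`` is the stacked n x r score matrix ``U`` (blocks ``U_i``
    of n_i rows in batch order); ``joint_loadings`` is the shared r x p
    matrix ``S``; ``individual_scores[i]`` / ``individual_loadings[i]`` are
    ``W_i`` (n_i x r_i) and ``S_i`` (r_i x p).  ``gene_means`` is the pooled
    per-gene mean removed by centering (zeros if the input was already
    centered upstream).
    """

    joint_scores: np.ndarray
    joint_loadings: np.ndarray
    individual_scores: list[np.ndarray]
    individual_loadings: list[np.ndarray]
    joint_rank: int
    individual_ranks: list[int]
    n_cells: list[int]
    gene_means: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    batch_labels: list[str]
    cell_ids: list[list[str]]

    @property
    def n_batches(self) -> int:
        return len(self.individual_ranks)

    @property
    def n_genes(self) -> int:
        return self.joint_loadings.shape[1]

    def joint_blocks(self) -> list[np.ndarray]:
        """Per-batch joint structures ``J_i = U_i S`` (n_i x p)."""
        out, start = [], 0
        for ni in self.n_cells:
            out.append(self.joint_scores[start : start + ni] @ self.joint_loadings)
            start += ni
        return out

    def individual_blocks(self) -> list[np.ndarray]:
        """Per-batch individual structures ``A_i = W_i S_i`` (n_i x p)."""
        return [
            w @ s for w, s in zip(self.individual_scores, self.individual_loadings)
        ]

    def save(self, path) -> None:
        """Serialize to a single ``.npz`` archive with named entries."""
        entries = {
            "joint_scores": self.joint_scores,
            "joint_loadings": self.joint_loadings,
            "joint_rank": np.array(self.joint_rank),
            "individual_ranks": np.array(self.individual_ranks),
            "n_cells": np.array(self.n_cells),
            "gene_means": self.gene_means,
            "objective_trace": self.objective_trace,
            "converged": np.array(self.converged),
            "n_iter": np.array(self.n_iter),
            "batch_labels": np.array(self.batch_labels),
        }
        for i, (w, s) in enumerate(zip(self.individual_scores, self.individual_loadings)):
            entries[f"individual_scores_{i}"] = w
            entries[f"individual_loadings_{i}"] = s
            entries[f"cell_ids_{i}"] = np.array(self.cell_ids[i])
        np.savez(path, **entries)

    @classmethod
    def load(cls, path) -> "JIVEModel":
        with np.load(path, allow_pickle=False) as z:
            k = len(z["individual_ranks"])
            return cls(
                joint_scores=z["joint_scores"],
                joint_loadings=z["joint_loadings"],
                individual_scores=[z[f"individual_scores_{i}"] for i in range(k)],
                individual_loadings=[z[f"individual_loadings_{i}"] for i in range(k)],
                joint_rank=int(z["joint_rank"]),
                individual_ranks=[int(r) for r in z["individual_ranks"]],
                n_cells=[int(n) for n in z["n_cells"]],
                gene_means=z["gene_means"],
                objective_trace=z["objective_trace"],
                converged=bool(z["converged"]),
                n_iter=int(z["n_iter"]),
                batch_labels=[str(b) for b in z["batch_labels"]],
                cell_ids=[[str(c) for c in z[f"cell_ids_{i}"]] for i in range(k)],
            )


def center(collection: BatchCollection) -> tuple[BatchCollection, np.ndarray]:
    """Subtract each gene's pooled mean across all cells of all batches.

    Pooled (not per-batch) centering is deliberate: per-batch centering would
    itself remove batch location effects and confound the decomposition's
    attribution of variation.
    """
    if collection.value_space != "lognorm":
        raise ValueError("center expects log-normalized values")
    pooled = collection.stacked()
    means = pooled.mean(axis=1)
    out = with_value_space(collection, "centered")
    out.matrices = [m - means[:, None] for m in collection.matrices]
    return out, means


def _truncated(matrix: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Best rank-``rank`` approximation as (scores, loadings)."""
    if rank == 0:
        return (
            np.zeros((matrix.shape[0], 0)),
            np.zeros((0, matrix.shape[1])),
        )
    t = partial_svd(matrix, rank)
    return t.u * t.s, t.v.T


def fit_jive(
    collection: BatchCollection,
    joint_rank: int,
    individual_ranks: list[int] | int,
    tol: float = 1e-6,
    max_iter: int = 1000,
    gene_means: np.ndarray | None = None,
    init: str = "individual",
    n_restarts: int = 1,
    seed: int | np.random.Generator | None = None,
) -> JIVEModel:
    """Fit the decomposition by alternating SSE minimization.

    Parameters
    ----------
    collection
        Centered collection with at least two batches.
    joint_rank, individual_ranks
        Rank of the shared structure and per-batch ranks (an int is
        broadcast to all batches).  Rank 0 yields an identically-zero
        structure.
    tol
        Convergence threshold on the maximum relative Frobenius change of
        the joint structure and every individual structure.
    max_iter
        Iteration cap; the ``converged`` flag records whether ``tol`` was
        reached.
    gene_means
        Optional pooled gene means removed upstream, stored for
        back-transformation.
    init
        ``"individual"`` (default) seeds each individual structure with the
        rank-r_i SVD of its own batch before the first joint step, so that
        strong batch-specific variation (e.g. batch mean offsets) is
        attributed to the individual structures rather than being locked
        into the joint one; ``"zero"`` starts from A_i = 0.
    n_restarts, seed
        Alternating least squares can stall in local optima on small noisy
        problems; ``n_restarts > 1`` reruns the fit from that many
        additional random individual-structure initializations (seeded) and
        keeps the model with the lowest final SSE.
    """
    if collection.value_space != "centered":
        raise ValueError("fit_jive expects a centered collection; call center() first")
    k = collection.n_batches
    if k < 2:
        raise ValueError("correction workflows require at least 2 batches")
    if isinstance(individual_ranks, (int, np.integer)):
        individual_ranks = [int(individual_ranks)] * k
    if len(individual_ranks) != k:
        raise ValueError("one individual rank per batch required")
    r = int(joint_rank)
    ranks = [int(x) for x in individual_ranks]
    if r < 0 or any(x < 0 for x in ranks):
        raise ValueError("ranks must be nonnegative")

    Ys = [m.T.copy() for m in collection.matrices]  # n_i x p each
    ns = [y.shape[0] for y in Ys]
    n, p = sum(ns), Ys[0].shape[1]
    if r > min(n, p):
        raise ValueError(f"joint rank {r} exceeds min(n={n}, p={p})")
    for i, (ri, ni) in enumerate(zip(ranks, ns)):
        if ri > min(ni, p):
            raise ValueError(f"individual rank {ri} exceeds dimensions of batch {i}")
    if n * p > _DENSE_WARN_ENTRIES:
        logger.warning("dense decomposition of %d x %d matrix; expect high memory use", n, p)

    Y = np.vstack(Ys)
    total_sq = float(np.sum(Y * Y))
    offsets = np.concatenate([[0], np.cumsum(ns)])

    if init not in ("individual", "zero"):
        raise ValueError(f"unknown init {init!r}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    A0 = [np.zeros_like(y) for y in Ys]
    if init == "individual":
        for i in range(k):
            if ranks[i] > 0:
                w0, s0 = _truncated(Ys[i], ranks[i])
                A0[i] = w0 @ s0

    scale = np.sqrt(total_sq) if total_sq > 0 else 1.0
    best = _als(Y, Ys, offsets, r, ranks, tol, max_iter, A0, scale)
    if n_restarts > 1:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts - 1):
            A_rand = [
                (rng.standard_normal((ni, ri)) @ rng.standard_normal((ri, p))) * scale / p
                if ri > 0
                else np.zeros((ni, p))
                for ni, ri in zip(ns, ranks)
            ]
            cand = _als(Y, Ys, offsets, r, ranks, tol, max_iter, A_rand, scale)
            if cand[-1][-1] < best[-1][-1]:
                best = cand

    U_scores, S, W, Si, converged, n_iter, trace = best
    return JIVEModel(
        joint_scores=U_scores,
        joint_loadings=S,
        individual_scores=list(W),
        individual_loadings=list(Si),
        joint_rank=r,
        individual_ranks=ranks,
        n_cells=ns,
        gene_means=(
            np.asarray(gene_means, dtype=float)
            if gene_means is not None
            else np.zeros(p)
        ),
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
        batch_labels=list(collection.batch_labels),
        cell_ids=[list(c) for c in collection.cell_ids],
    )


def _als(Y, Ys, offsets, r, ranks, tol, max_iter, A_init, scale):
    """One alternating-least-squares run from a given individual-structure start."""
    k = len(Ys)
    n, p = Y.shape
    ns = [y.shape[0] for y in Ys]
    J = np.zeros_like(Y)
    A = [a.copy() for a in A_init]
    V = np.zeros((p, 0))
    U_scores = np.zeros((n, r))
    S = np.zeros((r, p))
    W = [np.zeros((ni, ri)) for ni, ri in zip(ns, ranks)]
    Si = [np.zeros((ri, p)) for ri in ranks]
    trace: list[float] = []
    converged = False
    n_iter = 0

    for it in range(1, max_iter + 1):
        n_iter = it
        J_old, A_old = J, [a.copy() for a in A]

        # joint step: best rank-r fit to the stacked matrix with current
        # individual structure removed
        if r > 0:
            trip = partial_svd(Y - np.vstack(A), r)
            U_scores = trip.u * trip.s
            S = trip.v.T
            V = trip.v
            J = U_scores @ S
        else:
            J = np.zeros_like(Y)
            V = np.zeros((p, 0))

        # individual step: per batch, best rank-r_i fit to the joint-removed
        # residual projected onto the orthogonal complement of the joint row
        # space (this enforces S S_i.T = 0 by construction)
        A = []
        for i in range(k):
            resid_i = Ys[i] - J[offsets[i] : offsets[i + 1]]
            if ranks[i] > 0:
                if V.shape[1] > 0:
                    resid_i = resid_i - (resid_i @ V) @ V.T
                W[i], Si[i] = _truncated(resid_i, ranks[i])
                A.append(W[i] @ Si[i])
            else:
                W[i] = np.zeros((ns[i], 0))
                Si[i] = np.zeros((0, p))
                A.append(np.zeros_like(Ys[i]))

        trace.append(float(np.sum((Y - J - np.vstack(A)) ** 2)))

        dj = np.linalg.norm(J - J_old) / scale
        da = max(
            (np.linalg.norm(a - ao) / scale for a, ao in zip(A, A_old)), default=0.0
        )
        if max(dj, da) < tol or (r == 0 and all(x == 0 for x in ranks)):
            converged = True
            break

    return U_scores, S, W, Si, converged, n_iter, trace


def variance_explained(model: JIVEModel, collection: BatchCollection) -> np.ndarray:
    """Per-batch (joint, individual, residual) variance proportions.

    Rows index batches; each row is ``(|J_i|^2, |A_i|^2, |R_i|^2) / |Y_i|^2``
    and sums to 1 at convergence.
    """
    if collection.n_batches != model.n_batches:
        raise ValueError("batch count mismatch between model and collection")
    rows = []
    joints = model.joint_blocks()
    indivs = model.individual_blocks()
    for m, ji, ai in zip(collection.matrices, joints, indivs):
        y = m.T
        if y.shape != ji.shape:
            raise ValueError("shape mismatch between model and collection")
        tot = float(np.sum(y * y))
        if tot == 0:
            rows.append([0.0, 0.0, 1.0])
            continue
        jn = float(np.sum(ji * ji))
        an = float(np.sum(ai * ai))
        rn = float(np.sum((y - ji - ai) ** 2))
        rows.append([jn / tot, an / tot, rn / tot])
    return np.asarray(rows)


def correct_batches(
    model: JIVEModel, add_back_means: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Batch-corrected matrix and joint-score embedding.

    The corrected block for batch ``i`` is ``(U_i S).T`` (p x n_i); blocks are
    concatenated in batch order.  ``add_back_means`` restores the pooled gene
    means removed by centering.  Also returns ``U`` (n x r), the per-cell
    embedding used for metric computation.
    """
    if model.joint_rank == 0 and not add_back_means:
        warnings.warn("joint rank is 0: corrected matrix is identically zero", stacklevel=2)
    corrected = np.hstack([j.T for j in model.joint_blocks()])
    if add_back_means:
        corrected = corrected + model.gene_means[:, None]
    return corrected, model.joint_scores.copy()
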