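"""Synthetic multi-batch data with ground truth.

Two generators:

* :func:`simulate_lowrank` — Gaussian benchmark matrices built exactly as
  joint + individual + noise, with the individual loadings constructed
  orthogonal to the joint ones, for testing decomposition recovery.
* :func:`simulate_counts` — a Gamma-Poisson single-cell count model with
  multiplicative cell-type differential-expression factors and per-batch
  factors, log-normal library sizes and optional logistic dropout.  The
  location parameters of the DE and batch factors are the knobs swept by
  :func:`simulation_grid`, which enumerates the full 100-condition design
  (5 DE locations x 5 batch locations x balanced/unbalanced batches x
  balanced/unbalanced cell-type proportions).

A location parameter of 0 means the effect is absent (all factors exactly 1).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from jivebatch.io_preprocess import BatchCollection

DE_LOCATIONS = (0.0, 0.25, 0.5, 0.75, 1.0)
BATCH_LOCATIONS = (0.0, 0.25, 0.5, 0.75, 1.0)
BALANCED_BATCHES = (500, 500)
UNBALANCED_BATCHES = (800, 200)
BALANCED_TYPES = (1 / 3, 1 / 3, 1 / 3)
UNBALANCED_TYPES = (0.5, 0.3, 0.2)


@dataclass
class SimulationConfig:
    """Parameters of the Gamma-Poisson count simulator."""

    n_genes: int = 5000
    cells_per_batch: tuple[int, ...] = BALANCED_BATCHES
    n_cell_types: int = 3
    cell_type_proportions: tuple[float, ...] = BALANCED_TYPES
    de_location: float = 0.5
    batch_location: float = 0.5
    de_scale: float = 0.4
    batch_scale: float = 0.1
    de_prob: float = 0.1
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    libsize_location: float = 9.0
    libsize_scale: float = 0.2
    dropout: bool = False
    dropout_midpoint: float = 0.0
    dropout_shape: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_type_proportions) != self.n_cell_types:
            raise ValueError("one proportion per cell type required")
        if not np.isclose(sum(self.cell_type_proportions), 1.0):
            raise ValueError("cell type proportions must sum to 1")
        if any(c <= 0 for c in self.cells_per_batch):
            raise ValueError("cells_per_batch must be positive")
        for name in ("de_scale", "batch_scale", "libsize_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cells_per_batch"] = list(self.cells_per_batch)
        d["cell_type_proportions"] = list(self.cell_type_proportions)
        return d


@dataclass
class SimulationTruth:
    """Ground truth labels and generative factors of a simulated collection."""

    batch_labels: np.ndarray
    cell_type_labels: np.ndarray | None = None
    batch_factors: np.ndarray | None = None  # genes x batches
    de_factors: np.ndarray | None = None  # genes x cell types
    gene_means: np.ndarray | None = None
    library_sizes: np.ndarray | None = None
    expected_counts: np.ndarray | None = None  # genes x cells
    joint: list[np.ndarray] | None = None  # low-rank fixtures only
    individual: list[np.ndarray] | None = None
    noise: list[np.ndarray] | None = None
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "batch_labels": [str(b) for b in self.batch_labels],
            "cell_type_labels": (
                [str(t) for t in self.cell_type_labels]
                if self.cell_type_labels is not None
                else None
            ),
            "batch_factors": (
                self.batch_factors.tolist() if self.batch_factors is not None else None
            ),
            "de_factors": self.de_factors.tolist() if self.de_factors is not None else None,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ----------------------------------------------------------------------


def _orthonormal_rows(rng: np.random.Generator, rank: int, p: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((p, rank)))
    return q.T


def simulate_lowrank(
    n_rows: tuple[int, ...] = (200, 200),
    p: int = 1000,
    joint_rank: int = 1,
    individual_ranks: tuple[int, ...] = (1, 1),
    joint_scale: float = 1.0,
    individual_scale: float = 1.0,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[BatchCollection, SimulationTruth]:
    """Gaussian benchmark batches ``Y_i = U_i S + W_i S_i + E_i``.

    ``S`` has orthonormal rows shared by all batches; every ``S_i`` is drawn
    in the orthogonal complement of ``S`` so that ``S @ S_i.T = 0`` exactly.
    Scores are i.i.d. normal with the given scales and noise is
    ``N(0, noise_sd^2)``.  Matrices are returned gene x cell (``p x n_i``,
    the transpose of ``Y_i``) in centered space, with the exact joint,
    individual and noise matrices stored in the truth.
    """
    rng = np.random.default_rng(seed)
    k = len(n_rows)
    if joint_rank < 0 or any(r < 0 for r in individual_ranks):
        raise ValueError("ranks must be nonnegative")
    if len(individual_ranks) != k:
        raise ValueError("one individual rank per batch required")
    max_rank = joint_rank + max(individual_ranks, default=0)
    if max_rank > min(min(n_rows), p):
        raise ValueError("joint_rank + individual rank exceeds matrix dimensions")

    basis = _orthonormal_rows(rng, joint_rank + sum(individual_ranks), p)
    S = basis[:joint_rank]
    rest = basis[joint_rank:]

    matrices, joints, indivs, noises = [], [], [], []
    start = 0
    for i, ni in enumerate(n_rows):
        Ui = joint_scale * rng.standard_normal((ni, joint_rank))
        Ji = Ui @ S
        ri = individual_ranks[i]
        Si = rest[start : start + ri]
        start += ri
        Wi = individual_scale * rng.standard_normal((ni, ri))
        Ai = Wi @ Si
        Ei = noise_sd * rng.standard_normal((ni, p))
        matrices.append((Ji + Ai + Ei).T)
        joints.append(Ji)
        indivs.append(Ai)
        noises.append(Ei)

    gene_ids = [f"gene{g}" for g in range(p)]
    batch_labels = [f"batch{i + 1}" for i in range(k)]
    cell_ids = [
        [f"{batch_labels[i]}_cell{j}" for j in range(ni)] for i, ni in enumerate(n_rows)
    ]
    collection = BatchCollection(
        matrices=matrices,
        gene_ids=gene_ids,
        batch_labels=batch_labels,
        cell_ids=cell_ids,
        value_space="centered",
    )
    truth = SimulationTruth(
        batch_labels=np.concatenate(
            [np.repeat(batch_labels[i], ni) for i, ni in enumerate(n_rows)]
        ),
        joint=joints,
        individual=indivs,
        noise=noises,
        config={
            "n_rows": list(n_rows),
            "p": p,
            "joint_rank": joint_rank,
            "individual_ranks": list(individual_ranks),
            "joint_scale": joint_scale,
            "individual_scale": individual_scale,
            "noise_sd": noise_sd,
        },
    )
    return collection, truth


# ----------------------------------------------------------------------


def simulate_counts(config: SimulationConfig) -> tuple[BatchCollection, SimulationTruth]:
    """Gamma-Poisson multi-batch counts with DE and batch factors.

    Gene base means are Gamma(shape, rate).  Each non-reference cell type
    multiplies a random ``de_prob`` subset of genes by
    ``exp(+/- N(de_location, de_scale^2))``; each batch multiplies every
    gene by ``exp(+/- N(batch_location, batch_scale^2))``.  A location of 0
    leaves all factors at exactly 1.  Expected per-cell expression is the
    factored gene mean renormalized to the cell's log-normal library size;
    counts are Poisson, optionally thinned by logistic dropout on the log
    expected mean.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_genes
    k = len(config.cells_per_batch)
    T = config.n_cell_types

    lam = rng.gamma(config.mean_shape, 1.0 / config.mean_rate, size=p)

    de = np.ones((p, T))
    if config.de_location > 0:
        for t in range(1, T):
            hit = rng.random(p) < config.de_prob
            sign = rng.choice([-1.0, 1.0], size=p)
            mag = rng.normal(config.de_location, config.de_scale, size=p)
            de[hit, t] = np.exp(sign[hit] * mag[hit])

    bf = np.ones((p, k))
    if config.batch_location > 0:
        for b in range(k):
            sign = rng.choice([-1.0, 1.0], size=p)
            mag = rng.normal(config.batch_location, config.batch_scale, size=p)
            bf[:, b] = np.exp(sign * mag)

    matrices, cell_ids, cell_types = [], [], []
    batch_labels = [f"batch{b + 1}" for b in range(k)]
    all_types, all_lib, all_expected = [], [], []
    type_names = [f"type{t + 1}" for t in range(T)]
    for b, nb in enumerate(config.cells_per_batch):
        types = rng.choice(T, size=nb, p=np.asarray(config.cell_type_proportions))
        lib = rng.lognormal(config.libsize_location, config.libsize_scale, size=nb)
        base = (lam * bf[:, b])[:, None] * de[:, types]  # p x nb
        expected = base / base.sum(axis=0) * lib
        counts = rng.poisson(expected).astype(float)
        if config.dropout:
            with np.errstate(divide="ignore"):
                logmean = np.log(np.where(expected > 0, expected, np.nan))
            pdrop = 1.0 / (
                1.0 + np.exp(-config.dropout_shape * (logmean - config.dropout_midpoint))
            )
            pdrop = np.nan_to_num(pdrop, nan=0.0)
            counts[rng.random(expected.shape) < pdrop] = 0.0
        matrices.append(counts)
        cell_ids.append([f"{batch_labels[b]}_cell{j}" for j in range(nb)])
        cell_types.append([type_names[t] for t in types])
        all_types.append(types)
        all_lib.append(lib)
        all_expected.append(expected)

    collection = BatchCollection(
        matrices=matrices,
        gene_ids=[f"gene{g}" for g in range(p)],
        batch_labels=batch_labels,
        cell_ids=cell_ids,
        cell_types=cell_types,
        value_space="counts",
    )
    truth = SimulationTruth(
        batch_labels=collection.batch_vector(),
        cell_type_labels=collection.cell_type_vector(),
        batch_factors=bf,
        de_factors=de,
        gene_means=lam,
        library_sizes=np.concatenate(all_lib),
        expected_counts=np.hstack(all_expected),
        config=config.to_dict(),
    )
    return collection, truth


def simulation_grid(base_seed: int = 1000) -> list[SimulationConfig]:
    """The full Cartesian simulation design: 100 configurations.

    5 DE locations x 5 batch locations x {balanced, unbalanced batches}
    x {balanced, unbalanced cell-type proportions}, each with a
    deterministic per-condition seed.
    """
    configs = []
    combos = itertools.product(
        DE_LOCATIONS,
        BATCH_LOCATIONS,
        (BALANCED_BATCHES, UNBALANCED_BATCHES),
        (BALANCED_TYPES, UNBALANCED_TYPES),
    )
    for idx, (de_loc, b_loc, batches, props) in enumerate(combos):
        configs.append(
            SimulationConfig(
                de_location=de_loc,
                batch_location=b_loc,
                cells_per_batch=batches,
                cell_type_proportions=props,
                seed=base_seed + idx,
            )
        )
    return configs
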