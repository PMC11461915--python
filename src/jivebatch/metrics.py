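"""Quantitative evaluation of batch mixing and cell-type preservation.

Implements the metric protocols used to compare correction methods:

* **kBET** — chi-squared tests of local vs. global batch composition over
  randomly sampled fixed-size neighborhoods, reported as an acceptance rate.
* **ASW** — mean silhouette width under batch labels (mixing; lower better)
  and cell-type labels (purity; higher better), medianed over repeated 80%
  subsamples.
* **LISI** — per-cell effective number of batches (iLISI) or cell types
  (cLISI) from the inverse Simpson index of Gaussian-kernel neighborhood
  label distributions.
* **PVCA** — eigenvalue-weighted attribution of top-PC variance to batch,
  cell type and residual via one-way variance components.

Values compared across several correction methods are min-max scaled to
[0, 1] per metric; ASW-batch and cLISI are reported as ``1 - value`` so that
larger is always better.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

DEFAULT_KBET_FRACTIONS = (0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass
class Embedding:
    """Per-cell coordinates with labels attached.

    ``coords`` is n x d; ``batches`` has one entry per cell; ``cell_types``
    is optional but required by the cell-type metrics.
    """

    coords: np.ndarray
    batches: np.ndarray
    cell_types: np.ndarray | None = None
    source: str = "external"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.batches = np.asarray(self.batches)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D (cells x dimensions)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite entries")
        if len(self.batches) != self.coords.shape[0]:
            raise ValueError("one batch label per cell required")
        if self.cell_types is not None:
            self.cell_types = np.asarray(self.cell_types)
            if len(self.cell_types) != self.coords.shape[0]:
                raise ValueError("one cell-type label per cell required")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class MetricReport:
    """Collected metric values for one embedding/method."""

    kbet_acceptance: dict[float, float] = field(default_factory=dict)
    asw_batch: float | None = None
    asw_cell: float | None = None
    ilisi_batch: float | None = None
    clisi_cell: float | None = None
    pvca: tuple[float, float, float] | None = None
    scaled: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path) -> None:
        payload = {
            "kbet_acceptance": {str(k): v for k, v in self.kbet_acceptance.items()},
            "asw_batch": self.asw_batch,
            "asw_cell": self.asw_cell,
            "ilisi_batch": self.ilisi_batch,
            "clisi_cell": self.clisi_cell,
            "pvca": list(self.pvca) if self.pvca is not None else None,
            "scaled": self.scaled,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ----------------------------------------------------------------------


def pca_embed(
    matrix: np.ndarray,
    batches: np.ndarray,
    cell_types: np.ndarray | None = None,
    d: int = 30,
) -> Embedding:
    """Embed cells on the ``d`` leading principal components of a p x n matrix."""
    matrix = np.asarray(matrix, dtype=float)
    p, n = matrix.shape
    if not 1 <= d <= min(p, n):
        raise ValueError(f"d={d} out of range for a {p}x{n} matrix")
    scores = PCA(n_components=d, svd_solver="auto", random_state=0).fit_transform(matrix.T)
    return Embedding(coords=scores, batches=batches, cell_types=cell_types, source="pca-of-matrix")


def kbet_acceptance(
    embedding: Embedding,
    fraction: float,
    alpha: float = 0.05,
    n_tests: int = 100,
    seed: int | np.random.Generator | None = None,
) -> float:
    """kBET acceptance rate at one neighborhood-size fraction.

    For ``n_tests`` randomly chosen cells (without replacement), the
    ``k0``-nearest neighborhood (Euclidean, query cell included,
    ``k0 = round(fraction * n)``) is tested with a Pearson chi-squared test
    against the global batch proportions; acceptance is one minus the
    rejection fraction at level ``alpha``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = embedding.n_cells
    labels, counts = np.unique(embedding.batches, return_counts=True)
    if len(labels) < 2:
        raise ValueError("kBET requires at least 2 batches")
    if np.any(counts == 0):
        raise ValueError("a batch is absent from the data")
    global_props = counts / n

    k0 = int(round(fraction * n))
    if k0 < len(labels):
        raise ValueError(f"neighborhood size {k0} smaller than number of batches")
    nn = NearestNeighbors(n_neighbors=k0).fit(embedding.coords)
    n_tests = min(n_tests, n)
    queries = rng.choice(n, size=n_tests, replace=False)
    _, idx = nn.kneighbors(embedding.coords[queries])

    label_codes = np.searchsorted(labels, embedding.batches)
    rejected = 0
    expected = global_props * k0
    for row in idx:
        observed = np.bincount(label_codes[row], minlength=len(labels))
        chi2 = np.sum((observed - expected) ** 2 / expected)
        pval = stats.chi2.sf(chi2, df=len(labels) - 1)
        if pval < alpha:
            rejected += 1
    return 1.0 - rejected / n_tests


def _mean_silhouette(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width; singleton-cluster points contribute 0."""
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 distinct labels")
    vals = silhouette_samples(coords, labels)
    vals = vals.copy()
    singleton = np.isin(labels, uniq[counts == 1])
    vals[singleton] = 0.0
    return float(vals.mean())


def asw_report(
    embedding: Embedding,
    subsample_fraction: float = 0.8,
    repeats: int = 20,
    seed: int | np.random.Generator | None = None,
    max_resample: int = 50,
) -> tuple[float, float | None]:
    """Median batch and cell-type silhouette widths over repeated subsamples.

    Each repeat draws ``subsample_fraction`` of the cells without
    replacement (redrawing, with a warning, if any cluster has fewer than 2
    members) and computes the mean Euclidean silhouette width once with
    batch labels and once with cell-type labels as clusters.  Returns the
    medians over repeats; the cell-type median is None when cell types are
    absent.
    """
    rng = np.random.default_rng(seed)
    n = embedding.n_cells
    m = max(2, int(round(subsample_fraction * n)))
    if len(np.unique(embedding.batches)) < 2:
        raise ValueError("ASW batch requires at least 2 batches")
    has_types = embedding.cell_types is not None

    batch_vals, cell_vals = [], []
    for _ in range(repeats):
        for attempt in range(max_resample):
            idx = rng.choice(n, size=m, replace=False)
            ok = np.all(np.unique(embedding.batches[idx], return_counts=True)[1] >= 2)
            if ok and has_types:
                ok = np.all(
                    np.unique(embedding.cell_types[idx], return_counts=True)[1] >= 2
                )
            if ok:
                break
            if attempt == 0:
                warnings.warn("subsample left a singleton cluster; resampling", stacklevel=2)
        batch_vals.append(_mean_silhouette(embedding.coords[idx], embedding.batches[idx]))
        if has_types:
            cell_vals.append(
                _mean_silhouette(embedding.coords[idx], embedding.cell_types[idx])
            )
    return (
        float(np.median(batch_vals)),
        float(np.median(cell_vals)) if has_types else None,
    )


def lisi_scores(
    embedding: Embedding,
    labels: np.ndarray,
    perplexity: float = 30.0,
    n_bisect: int = 50,
    tol: float = 1e-5,
) -> np.ndarray:
    """Per-cell local inverse Simpson index of a label set.

    For each cell, Gaussian-kernel weights over its ``K = 3 * perplexity``
    nearest neighbors (self excluded) are tuned by bisection on the kernel
    bandwidth until the weight entropy equals ``log(perplexity)``; the score
    is the inverse Simpson index of the kernel-weighted label distribution
    and lies in ``[1, #labels]``.
    """
    labels = np.asarray(labels)
    coords = embedding.coords
    n = coords.shape[0]
    uniq = np.unique(labels)
    if len(labels) != n:
        raise ValueError("one label per cell required")
    if len(uniq) == 1:
        return np.ones(n)

    if n <= 3 * perplexity:
        new_perp = max(2.0, (n - 1) / 3.0)
        warnings.warn(
            f"n={n} too small for perplexity {perplexity}; lowering to {new_perp:.1f}",
            stacklevel=2,
        )
        perplexity = new_perp
    K = min(n - 1, int(round(3 * perplexity)))

    nn = NearestNeighbors(n_neighbors=K + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    d2 = dist**2
    codes = np.searchsorted(uniq, labels)
    target = np.log(perplexity)

    scores = np.empty(n)
    for i in range(n):
        w = _entropy_calibrated_weights(d2[i], target, n_bisect, tol)
        q = np.bincount(codes[idx[i]], weights=w, minlength=len(uniq))
        scores[i] = 1.0 / np.sum(q**2)
    return scores


def _entropy_calibrated_weights(
    d2: np.ndarray, target_entropy: float, n_bisect: int, tol: float
) -> np.ndarray:
    """Normalized Gaussian weights with entropy tuned to ``target_entropy``.

    Bisection on the precision ``beta`` in ``exp(-beta * d2)``; standard
    perplexity calibration.
    """
    beta = 1.0
    lo, hi = -np.inf, np.inf
    base = d2 - d2.min()  # stabilize exponentials
    w = np.exp(-beta * base)
    for _ in range(n_bisect):
        sw = w.sum()
        h = np.log(sw) + beta * np.sum(base * w) / sw
        diff = h - target_entropy
        if abs(diff) < tol:
            break
        if diff > 0:
            lo = beta
            beta = beta * 2 if np.isinf(hi) else (beta + hi) / 2
        else:
            hi = beta
            beta = beta / 2 if np.isinf(lo) else (beta + lo) / 2
        w = np.exp(-beta * base)
    return w / w.sum()


def scale_across_methods(values: dict[str, float], invert: bool = False) -> dict[str, float]:
    """Min-max scale one metric across methods to [0, 1]; optionally report 1 - x."""
    vals = np.asarray(list(values.values()), dtype=float)
    lo, hi = vals.min(), vals.max()
    if len(values) < 2 or hi == lo:
        warnings.warn("fewer than 2 distinct values; scaled results degenerate to 0", stacklevel=2)
        scaled = {k: 0.0 for k in values}
    else:
        scaled = {k: (v - lo) / (hi - lo) for k, v in values.items()}
    if invert:
        scaled = {k: 1.0 - v for k, v in scaled.items()}
    return scaled


# ----------------------------------------------------------------------
# PVCA


def _oneway_variance_component(y: np.ndarray, labels: np.ndarray) -> float:
    """One-way random-effect variance component by the method of moments.

    ANOVA estimator for unbalanced groups; negative estimates truncated at 0.
    A single-level factor contributes 0.
    """
    uniq, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    a, n = len(uniq), len(y)
    if a < 2 or n <= a:
        return 0.0
    grand = y.mean()
    group_means = np.bincount(inverse, weights=y) / counts
    ss_between = np.sum(counts * (group_means - grand) ** 2)
    ss_within = np.sum((y - group_means[inverse]) ** 2)
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (n - a)
    n0 = (n - np.sum(counts**2) / n) / (a - 1)
    return max(0.0, (ms_between - ms_within) / n0)


def pvca(
    matrix: np.ndarray,
    batch_labels: np.ndarray,
    cell_labels: np.ndarray,
    n_pcs: int = 10,
) -> tuple[float, float, float]:
    """Principal variance component analysis over batch and cell-type factors.

    Computes the ``n_pcs`` leading principal components of the p x n matrix
    (cells as observations), estimates one-way variance components for batch
    and cell type on each PC score vector plus a residual, and averages the
    per-PC proportions weighted by each PC's share of the retained
    eigenvalues.  Returns ``(prop_batch, prop_cell, prop_residual)`` summing
    to 1.
    """
    matrix = np.asarray(matrix, dtype=float)
    batch_labels = np.asarray(batch_labels)
    cell_labels = np.asarray(cell_labels)
    p, n = matrix.shape
    if len(batch_labels) != n or len(cell_labels) != n:
        raise ValueError("label lengths must equal the number of cells")
    n_pcs = min(n_pcs, min(p, n))
    pca = PCA(n_components=n_pcs, random_state=0).fit(matrix.T)
    scores = pca.transform(matrix.T)  # n x n_pcs
    eigvals = pca.explained_variance_
    weights = eigvals / eigvals.sum()

    props = np.zeros(3)
    for j in range(n_pcs):
        y = scores[:, j]
        var_b = _oneway_variance_component(y, batch_labels)
        var_c = _oneway_variance_component(y, cell_labels)
        total = y.var(ddof=1)
        var_r = max(total - var_b - var_c, 0.0)
        parts = np.array([var_b, var_c, var_r])
        if parts.sum() == 0:
            parts = np.array([0.0, 0.0, 1.0])
        props += weights[j] * parts / parts.sum()
    props = props / props.sum()
    return float(props[0]), float(props[1]), float(props[2])


def evaluate_embedding(
    embedding: Embedding,
    kbet_fractions: tuple[float, ...] = DEFAULT_KBET_FRACTIONS,
    matrix: np.ndarray | None = None,
    metrics: tuple[str, ...] = ("kbet", "asw", "lisi"),
    seed: int | None = None,
    kbet_alpha: float = 0.05,
    kbet_n_tests: int = 100,
    asw_repeats: int = 20,
    lisi_perplexity: float = 30.0,
) -> MetricReport:
    """Run the configured metrics on one embedding into a :class:`MetricReport`.

    All stochastic steps draw from one generator seeded with ``seed``.  PVCA
    runs on ``matrix`` (p x n) when provided and requested.
    """
    rng = np.random.default_rng(seed)
    report = MetricReport(seed=seed)
    if "kbet" in metrics:
        for f in kbet_fractions:
            report.kbet_acceptance[f] = kbet_acceptance(
                embedding, f, alpha=kbet_alpha, n_tests=kbet_n_tests, seed=rng
            )
    if "asw" in metrics:
        report.asw_batch, report.asw_cell = asw_report(
            embedding, repeats=asw_repeats, seed=rng
        )
    if "lisi" in metrics:
        report.ilisi_batch = float(
            np.median(lisi_scores(embedding, embedding.batches, perplexity=lisi_perplexity))
        )
        if embedding.cell_types is not None:
            report.clisi_cell = float(
                np.median(
                    lisi_scores(embedding, embedding.cell_types, perplexity=lisi_perplexity)
                )
            )
    if "pvca" in metrics and matrix is not None and embedding.cell_types is not None:
        report.pvca = pvca(matrix, embedding.batches, embedding.cell_types)
    return report
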