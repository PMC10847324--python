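"""Cell filtering, TP10K normalization, HVG selection, scaling, PCA,
SNN-graph modularity clustering, and Wilcoxon rank-sum differential
expression."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io import CountMatrix

logger = logging.getLogger(__name__)

NORMALIZATION_CONSTANT = 10_000.0


@dataclass
class NormalizedMatrix:
    """Genes x cells log-normalized expression: ln(count/total * 1e4 + 1)."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    normalization_constant: float = NORMALIZATION_CONSTANT

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_cells(self, mask_or_idx) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            self.values[:, idx], self.gene_ids, np.asarray(self.cell_ids)[idx],
            self.normalization_constant,
        )


@dataclass
class ClusterAssignment:
    """Integer cluster id per cell, clusters numbered from 0."""

    labels: np.ndarray
    cell_ids: np.ndarray
    resolution: float

    def sizes(self) -> dict[int, int]:
        uniq, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), cnt.tolist()))

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cell_ids, name="cluster")


def filter_cells(m: CountMatrix, min_genes: int = 400) -> CountMatrix:
    """Retain cells detecting at least ``min_genes`` genes (count > 0)."""
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    detected = np.asarray((m.values > 0).sum(axis=0)).ravel()
    keep = detected >= min_genes
    if not keep.any():
        logger.warning("filter_cells removed every cell (min_genes=%d)", min_genes)
    return m.subset_cells(keep)


def lognormalize_tp10k(m: CountMatrix) -> NormalizedMatrix:
    """ln(count / cell_total * 10,000 + 1), per cell."""
    totals = np.asarray(m.values.sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts: {list(np.asarray(m.cell_ids)[zero][:5])}"
        )
    dense = m.dense().astype(float)
    values = np.log1p(dense / totals[None, :] * NORMALIZATION_CONSTANT)
    return NormalizedMatrix(values, np.asarray(m.gene_ids), np.asarray(m.cell_ids))


def select_hvg(nm: NormalizedMatrix, n_hvg: int, n_bins: int = 20) -> list[str]:
    """Top genes by trend-normalized variance.

    Genes are binned into ``n_bins`` equal-frequency bins of mean
    expression; the expected variance of a gene is the mean variance of
    its bin, and the selection score is observed/expected variance.
    Constant genes score -inf. Ties broken by gene id.
    """
    if n_hvg > nm.n_genes:
        raise ValueError("n_hvg exceeds number of genes")
    means = nm.values.mean(axis=1)
    variances = nm.values.var(axis=1, ddof=1) if nm.n_cells > 1 else np.zeros(nm.n_genes)
    order = np.lexsort((nm.gene_ids.astype(str), means))
    bins = np.empty(nm.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(nm.n_genes) * n_bins) // nm.n_genes, n_bins - 1
    )
    score = np.full(nm.n_genes, -np.inf)
    for b in range(n_bins):
        mask = bins == b
        if not mask.any():
            continue
        expected = variances[mask].mean()
        score[mask] = variances[mask] / expected if expected > 0 else 0.0
    score[variances == 0] = -np.inf
    # rank: score desc, gene id asc
    idx = np.lexsort((nm.gene_ids.astype(str), -score))
    return [nm.gene_ids[i] for i in idx[:n_hvg]]


def scale_center(nm: NormalizedMatrix, genes, clip: float = 10.0) -> np.ndarray:
    """Per-gene zero-mean unit-variance scaling with clipping, over a gene subset.

    Returns a genes x cells array in the order of ``genes``. Constant genes
    become all zeros.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene subset")
    sub = nm.values[nm.gene_index(genes), :]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True) if nm.n_cells > 1 else np.ones_like(mu)
    sd = np.where(sd > 0, sd, 1.0)
    out = (sub - mu) / sd
    return np.clip(out, -clip, clip)


def pca_embed(scaled: np.ndarray, n_pcs: int = 16) -> np.ndarray:
    """PCA embedding (cells x n_pcs) of a genes x cells scaled matrix.

    Deterministic full SVD; each component's sign is fixed so that its
    largest-magnitude gene loading is positive.
    """
    X = scaled.T  # cells x genes
    n_cells, n_genes = X.shape
    if n_pcs > min(n_genes, n_cells):
        raise ValueError("n_pcs exceeds min(n_genes, n_cells)")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    for k in range(n_pcs):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    return U * S[None, :]


def pca_explained_variance(scaled: np.ndarray, n_pcs: int) -> np.ndarray:
    X = scaled.T
    Xc = X - X.mean(axis=0, keepdims=True)
    S = np.linalg.svd(Xc, compute_uv=False)
    ev = S**2 / max(X.shape[0] - 1, 1)
    return ev[:n_pcs]


def snn_graph(embedding: np.ndarray, k_neighbors: int = 20, prune: float = 1 / 15):
    """SNN graph: kNN (Euclidean, self included) -> Jaccard edge weights.

    Returns an igraph.Graph with 'weight' edge attribute; edges with
    Jaccard overlap <= ``prune`` are dropped.
    """
    import igraph as ig
    from sklearn.neighbors import NearestNeighbors

    n = embedding.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells to build an SNN graph")
    k = min(k_neighbors, n)
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh = sp.csr_matrix(
        (np.ones(n * k), (np.repeat(np.arange(n), k), idx.ravel())), shape=(n, n)
    )
    shared = (neigh @ neigh.T).tocoo()  # |N(i) & N(j)|
    jac = shared.data / (2 * k - shared.data)
    keep = (jac > prune) & (shared.row < shared.col)
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep].tolist()
    return g


def snn_cluster(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 0.2,
    seed: int = 0,
    cell_ids=None,
) -> ClusterAssignment:
    """SNN graph + modularity (RB configuration) optimization via Leiden.

    Deterministic given the seed; cluster ids are renumbered from 0 in
    decreasing size order.
    """
    import leidenalg

    g = snn_graph(embedding, k_neighbors=k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # stable renumbering: by decreasing size, ties by smallest member index
    uniq, counts = np.unique(labels, return_counts=True)
    first = np.array([np.argmax(labels == u) for u in uniq])
    order = np.lexsort((first, -counts))
    remap = {int(uniq[o]): r for r, o in enumerate(order)}
    labels = np.array([remap[int(l)] for l in labels])
    if cell_ids is None:
        cell_ids = np.arange(len(labels))
    return ClusterAssignment(labels, np.asarray(cell_ids), resolution)


@dataclass
class DEResult:
    table: pd.DataFrame  # index gene: logFC, p_value, p_adjusted, mean_a, mean_b


def wilcoxon_de(
    nm: NormalizedMatrix,
    group_a,
    group_b,
    p_adjust: str = "bonferroni",
) -> DEResult:
    """Per-gene Wilcoxon rank-sum test (normal approximation, tie-corrected)
    between two disjoint cell groups.

    logFC = ln((mean(expm1 x)_a + 1) / (mean(expm1 x)_b + 1)), natural log.
    """
    ids = list(nm.cell_ids)
    pos = {c: i for i, c in enumerate(ids)}
    ia = np.array([pos[c] for c in group_a], dtype=int)
    ib = np.array([pos[c] for c in group_b], dtype=int)
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("both groups need >= 3 cells")
    if set(ia) & set(ib):
        raise ValueError("groups overlap")
    Xa = nm.values[:, ia]
    Xb = nm.values[:, ib]
    res = scipy.stats.mannwhitneyu(
        Xa, Xb, axis=1, alternative="two-sided", method="asymptotic"
    )
    mean_a = np.expm1(Xa).mean(axis=1)
    mean_b = np.expm1(Xb).mean(axis=1)
    logfc = np.log((mean_a + 1.0) / (mean_b + 1.0))
    p = np.asarray(res.pvalue, dtype=float)
    # fully tied genes have a degenerate rank-sum distribution: no evidence
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = adjust_pvalues(p, method=p_adjust)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "p_value": p,
            "p_adjusted": p_adj,
            "mean_a": mean_a,
            "mean_b": mean_b,
        },
        index=pd.Index(nm.gene_ids, name="gene"),
    )
    return DEResult(table)


def adjust_pvalues(p: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * p.size / (np.arange(p.size) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown adjustment {method!r}")
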