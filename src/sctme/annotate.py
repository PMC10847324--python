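"""Template-based cluster annotation and binned module-score classification.

Clusters inherit the majority label among their template cells when that
label's within-cluster ratio reaches ``r_min`` (default 0.7), otherwise
they are "undecided". Module scores follow the binned-control convention:
mean signature expression minus mean expression of bin-matched random
control genes, computed on log-normalized values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneSignatureSet
from .preprocess import ClusterAssignment, NormalizedMatrix

logger = logging.getLogger(__name__)

UNDECIDED = "undecided"
NOT_ASSIGNED = "NA"


@dataclass
class TacaResult:
    """Per-cluster type ratios, assigned labels, and per-cell labels."""

    ratios: pd.DataFrame  # cluster x type, r_ti
    cluster_labels: dict[int, str]
    cell_labels: pd.Series  # index cell_id
    r_min: float
    template_counts: pd.Series  # template cells per cluster


def taca_assign(
    clusters: ClusterAssignment,
    template: Mapping[str, str],
    r_min: float = 0.7,
) -> TacaResult:
    """Assign each cluster the majority template label if its ratio >= r_min.

    ``template`` maps template cell ids to known type labels. Clusters
    without template cells, and clusters whose top ratio ties or falls
    below ``r_min``, are labeled "undecided". All cells inherit their
    cluster's label.
    """
    if not template:
        raise ValueError("empty template annotation")
    cell_ids = np.asarray(clusters.cell_ids)
    labels = np.asarray(clusters.labels)
    cluster_ids = sorted(set(labels.tolist()))
    types = sorted(set(template.values()))

    in_template = np.array([c in template for c in cell_ids])
    if not in_template.any():
        raise ValueError("no template cells present in the clustering")
    tmpl_types = pd.Series(
        [template[c] for c in cell_ids[in_template]],
        index=pd.Index(labels[in_template], name="cluster"),
    )
    counts = (
        tmpl_types.groupby(level=0).value_counts().unstack(fill_value=0)
    )
    counts = counts.reindex(index=cluster_ids, columns=types, fill_value=0)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        ratios = counts.div(totals.replace(0, np.nan), axis=0)

    cluster_labels: dict[int, str] = {}
    for cl in cluster_ids:
        n_tmpl = int(totals.loc[cl])
        if n_tmpl == 0:
            logger.warning("cluster %d has no template cells; undecided", cl)
            cluster_labels[cl] = UNDECIDED
            continue
        r = ratios.loc[cl]
        top = r.max()
        winners = [t for t in types if r[t] == top]
        if top >= r_min and len(winners) == 1:
            cluster_labels[cl] = winners[0]
        else:
            cluster_labels[cl] = UNDECIDED
    cell_labels = pd.Series(
        [cluster_labels[int(l)] for l in labels],
        index=pd.Index(cell_ids, name="cell_id"),
        name="cell_type",
    )
    return TacaResult(
        ratios=ratios.fillna(0.0),
        cluster_labels=cluster_labels,
        cell_labels=cell_labels,
        r_min=r_min,
        template_counts=totals,
    )


@dataclass
class ModuleScores:
    """Per-cell scores for each signature label."""

    scores: pd.DataFrame  # cells x labels
    n_bins: int
    n_controls: int
    seed: int


def module_score(
    nm: NormalizedMatrix,
    signature: Sequence[str],
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
    exclude_signature: bool = True,
) -> np.ndarray:
    """Binned-control module score per cell.

    Genes are ranked by mean expression across cells and cut into
    ``n_bins`` equal-frequency bins. For each signature gene, ``n_controls``
    control genes are sampled from its bin (without replacement when the
    bin is large enough, otherwise with replacement and a warning).
    Score = mean signature expression - mean control-pool expression.
    """
    sig = [g for g in signature if g in set(nm.gene_ids)]
    dropped = len(signature) - len(sig)
    if not sig:
        raise ValueError("signature entirely absent from matrix")
    if dropped:
        logger.warning("dropping %d signature genes absent from matrix", dropped)

    means = nm.values.mean(axis=1)
    order = np.lexsort((nm.gene_ids.astype(str), means))
    bins = np.empty(nm.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(nm.n_genes) * n_bins) // nm.n_genes, n_bins - 1
    )
    gene_pos = {g: i for i, g in enumerate(nm.gene_ids)}
    sig_idx = np.array([gene_pos[g] for g in sig], dtype=int)
    sig_set = set(sig_idx.tolist())

    rng = np.random.default_rng(seed)
    control_idx: list[np.ndarray] = []
    small_bins = 0
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        if exclude_signature:
            pool = np.array([p for p in pool if p not in sig_set], dtype=int)
        if pool.size == 0:
            raise ValueError(
                f"no eligible control genes in bin of {nm.gene_ids[gi]!r}"
            )
        if pool.size >= n_controls:
            chosen = rng.choice(pool, size=n_controls, replace=False)
        else:
            small_bins += 1
            chosen = rng.choice(pool, size=n_controls, replace=True)
        control_idx.append(chosen)
    if small_bins:
        logger.warning(
            "%d of %d signature genes sit in bins with fewer than %d eligible "
            "controls; sampling with replacement for those",
            small_bins, len(sig_idx), n_controls,
        )
    controls = np.concatenate(control_idx)
    sig_mean = nm.values[sig_idx, :].mean(axis=0)
    ctrl_mean = nm.values[controls, :].mean(axis=0)
    return sig_mean - ctrl_mean


def score_signatures(
    nm: NormalizedMatrix,
    signatures: GeneSignatureSet,
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
) -> ModuleScores:
    """Module scores for every label of a signature set."""
    cols = {}
    for k, label in enumerate(signatures.labels):
        cols[label] = module_score(
            nm,
            signatures.signatures[label],
            n_bins=n_bins,
            n_controls=n_controls,
            seed=seed + k,
        )
    scores = pd.DataFrame(cols, index=pd.Index(nm.cell_ids, name="cell_id"))
    return ModuleScores(scores, n_bins, n_controls, seed)


def assign_by_max_positive_score(scores: ModuleScores) -> pd.Series:
    """Highest-scoring label per cell if that score is positive, else "NA".

    Ties are broken by label (column) order.
    """
    df = scores.scores
    if df.shape[1] == 0:
        raise ValueError("no labels scored")
    vals = df.to_numpy()
    best = vals.argmax(axis=1)  # first max wins -> column-order tie break
    top = vals[np.arange(len(df)), best]
    labels = np.where(top > 0, df.columns.to_numpy(dtype=object)[best], NOT_ASSIGNED)
    return pd.Series(labels, index=df.index, name="label")


def classify_cells(
    nm: NormalizedMatrix,
    signature_sets: Mapping[str, GeneSignatureSet],
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Label columns (one per signature set) via module scores + argmax rule.

    ``signature_sets`` maps an output column name (e.g. "cycle_phase") to a
    signature set; each set gets an independent sub-seed.
    """
    out = {}
    for k, (column, sigset) in enumerate(signature_sets.items()):
        ms = score_signatures(
            nm, sigset, n_bins=n_bins, n_controls=n_controls, seed=seed + 1000 * k
        )
        out[column] = assign_by_max_positive_score(ms)
    return pd.DataFrame(out)
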