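"""Ligand-receptor interaction analysis.

Per sample, each (LR pair, ordered subcluster pair) gets an enrichment
statistic — the average of the ligand's mean expression in the sender
subcluster and the receptor's mean in the receiver — gated on the ligand
(receptor) being detected in at least 10% of sender (receiver) cells.
A permutation null shuffles subcluster labels within the sample. The
per-sample "significant means" matrix zeroes entries failing the p-value
threshold or the minimum-cell-count rule, and group contrasts across
samples use an empirical-Bayes moderated t-statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .io import LRDatabase
from .preprocess import NormalizedMatrix, adjust_pvalues

logger = logging.getLogger(__name__)

EXPRESSION_FRACTION_GATE = 0.10


@dataclass(frozen=True)
class SubclusterPair:
    """Ordered (sender, receiver) subcluster pair with cell counts."""

    sender: str
    receiver: str
    n_sender: int
    n_receiver: int


@dataclass
class LRTestResult:
    """Long-format results for one sample."""

    table: pd.DataFrame  # ligand, receptor, sender, receiver, n_sender,
    #                      n_receiver, statistic, p_value
    sample_id: str
    n_permutations: int


def build_lr_db(sources: Sequence[pd.DataFrame | LRDatabase]) -> LRDatabase:
    """Union of pair tables, deduplicated on (ligand, receptor); provenance
    tags of duplicates are concatenated with '+'."""
    frames = []
    for src in sources:
        df = src.pairs if isinstance(src, LRDatabase) else src.copy()
        if "source" not in df.columns:
            df = df.assign(source="unspecified")
        frames.append(df[["ligand", "receptor", "source"]])
    if not frames:
        raise ValueError("no sources given")
    allp = pd.concat(frames, ignore_index=True)
    if allp.empty:
        raise ValueError("empty union of LR sources")
    merged = (
        allp.groupby(["ligand", "receptor"], sort=True)["source"]
        .apply(lambda s: "+".join(dict.fromkeys(s)))
        .reset_index()
    )
    return LRDatabase(merged)


def _cluster_means(expr: np.ndarray, onehot: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Mean per (gene, cluster): expr (G x C) @ onehot (C x K) / counts."""
    return (expr @ onehot) / counts[None, :]


def lr_mean_statistic(
    nm: NormalizedMatrix,
    pair: tuple[str, str],
    sc: SubclusterPair,
    labels: Mapping[str, str] | pd.Series,
) -> float | None:
    """Average of ligand mean in sender and receptor mean in receiver.

    Returns None (undefined) when either gene is absent or fails the 10%
    expression-fraction gate in its subcluster.
    """
    ligand, receptor = pair
    gene_set = set(nm.gene_ids)
    if ligand not in gene_set or receptor not in gene_set:
        return None
    lab = pd.Series(labels).reindex(nm.cell_ids)
    sender_idx = np.flatnonzero((lab == sc.sender).to_numpy())
    receiver_idx = np.flatnonzero((lab == sc.receiver).to_numpy())
    if sender_idx.size == 0 or receiver_idx.size == 0:
        return None
    gi = nm.gene_index([ligand, receptor])
    lig_expr = nm.values[gi[0], sender_idx]
    rec_expr = nm.values[gi[1], receiver_idx]
    if (lig_expr > 0).mean() < EXPRESSION_FRACTION_GATE:
        return None
    if (rec_expr > 0).mean() < EXPRESSION_FRACTION_GATE:
        return None
    return float((lig_expr.mean() + rec_expr.mean()) / 2.0)


def permutation_test(
    nm: NormalizedMatrix,
    pair: tuple[str, str],
    sc: SubclusterPair,
    labels: Mapping[str, str] | pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for one (LR pair, subcluster pair).

    Subcluster labels are permuted across all cells of the sample; the
    add-one convention gives p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is low; p-values will be coarse", n_perm)
    obs = lr_mean_statistic(nm, pair, sc, labels)
    if obs is None:
        raise ValueError("statistic undefined for this pair")
    lab = pd.Series(labels).reindex(nm.cell_ids).to_numpy()
    sender_mask = lab == sc.sender
    receiver_mask = lab == sc.receiver
    gi = nm.gene_index(list(pair))
    lig = nm.values[gi[0], :]
    rec = nm.values[gi[1], :]
    n_s, n_r = int(sender_mask.sum()), int(receiver_mask.sum())
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(lab))
        stat = (lig[perm[sender_mask]].mean() + rec[perm[receiver_mask]].mean()) / 2.0
        if stat >= obs - 1e-12:
            ge += 1
    return (1 + ge) / (1 + n_perm)


def lr_test_sample(
    nm: NormalizedMatrix,
    labels: pd.Series,
    db: LRDatabase,
    sample_id: str = "sample",
    n_perm: int = 1000,
    seed: int = 0,
    subclusters: Sequence[str] | None = None,
) -> LRTestResult:
    """All (LR pair, ordered subcluster pair) tests for one sample.

    One shared permutation stream is used for the whole sample: each
    permutation shuffles the label vector once and all pair statistics are
    recomputed from the permuted cluster means.
    """
    lab = labels.reindex(nm.cell_ids)
    if lab.isna().any():
        raise ValueError("labels missing for some cells")
    clusters = sorted(lab.unique().tolist()) if subclusters is None else list(subclusters)
    k = len(clusters)
    cl_index = {c: j for j, c in enumerate(clusters)}
    member = lab.map(cl_index).to_numpy()
    onehot = np.zeros((nm.n_cells, k))
    onehot[np.arange(nm.n_cells), member] = 1.0
    counts = onehot.sum(axis=0)
    if (counts == 0).any():
        raise ValueError("empty subcluster in requested set")

    gene_set = set(nm.gene_ids)
    pairs = [
        (l, r) for l, r in db.pair_tuples() if l in gene_set and r in gene_set
    ]
    genes = sorted({g for p in pairs for g in p})
    if not genes:
        return LRTestResult(
            pd.DataFrame(columns=["ligand", "receptor", "sender", "receiver",
                                  "n_sender", "n_receiver", "statistic", "p_value"]),
            sample_id, n_perm)
    gidx = nm.gene_index(genes)
    expr = nm.values[gidx, :]
    gpos = {g: i for i, g in enumerate(genes)}

    means = _cluster_means(expr, onehot, counts)  # genes x clusters
    detected = _cluster_means((expr > 0).astype(float), onehot, counts)

    rng = np.random.default_rng(seed)
    perm_means = np.empty((n_perm, len(genes), k))
    for p in range(n_perm):
        perm = rng.permutation(nm.n_cells)
        perm_means[p] = _cluster_means(expr[:, perm], onehot, counts)

    rows = []
    for ligand, receptor in pairs:
        li, ri = gpos[ligand], gpos[receptor]
        for s in clusters:
            for r in clusters:
                sj, rj = cl_index[s], cl_index[r]
                gate = (
                    detected[li, sj] >= EXPRESSION_FRACTION_GATE
                    and detected[ri, rj] >= EXPRESSION_FRACTION_GATE
                )
                if not gate:
                    continue
                obs = (means[li, sj] + means[ri, rj]) / 2.0
                null = (perm_means[:, li, sj] + perm_means[:, ri, rj]) / 2.0
                ge = int((null >= obs - 1e-12).sum())
                rows.append(
                    dict(
                        ligand=ligand, receptor=receptor,
                        sender=s, receiver=r,
                        n_sender=int(counts[sj]), n_receiver=int(counts[rj]),
                        statistic=float(obs),
                        p_value=(1 + ge) / (1 + n_perm),
                    )
                )
    return LRTestResult(pd.DataFrame(rows), sample_id, n_perm)


def significant_means(
    result: LRTestResult,
    alpha: float = 0.05,
    min_cells: int = 50,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Significant-means matrix M (LR pair x ordered subcluster pair).

    m = statistic when p < alpha and both subclusters have >= min_cells
    cells, else 0. ``adjust="within-sample-bh"`` applies Benjamini-Hochberg
    across the sample's tests before thresholding (default: raw p).
    """
    t = result.table
    if t.empty:
        return pd.DataFrame()
    p = t["p_value"].to_numpy()
    if adjust == "within-sample-bh":
        p = adjust_pvalues(p, method="bh")
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    ok = (p < alpha) & (t["n_sender"] >= min_cells) & (t["n_receiver"] >= min_cells)
    m = np.where(ok, t["statistic"], 0.0)
    out = t.assign(m=m)
    lr = out["ligand"] + "_" + out["receptor"]
    scp = out["sender"] + ">" + out["receiver"]
    return out.assign(lr_pair=lr, subcluster_pair=scp).pivot_table(
        index="lr_pair", columns="subcluster_pair", values="m", fill_value=0.0,
        aggfunc="first",
    )


def count_interactions(M: pd.DataFrame, by: str = "sample") -> object:
    """Number of nonzero significant means per margin.

    by="sample" -> int; by="subcluster_pair" -> Series per column;
    by="subcluster" -> Series per participating subcluster (sender or
    receiver side of a nonzero entry).
    """
    if M.empty:
        nz = pd.DataFrame()
    else:
        nz = M != 0
    if by == "sample":
        return int(nz.values.sum()) if len(nz) else 0
    if by == "subcluster_pair":
        return nz.sum(axis=0) if len(nz) else pd.Series(dtype=int)
    if by == "subcluster":
        out: dict[str, int] = {}
        for col in (nz.columns if len(nz) else []):
            s, r = col.split(">")
            c = int(nz[col].sum())
            out[s] = out.get(s, 0) + c
            if r != s:
                out[r] = out.get(r, 0) + c
        return pd.Series(out, dtype=int).sort_index()
    raise ValueError(f"unknown margin {by!r}")


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t contrast


@dataclass
class ContrastResult:
    lr_pair: str
    coefficient: float
    s2: float
    s2_post: float
    t_statistic: float
    df_total: float
    p_value: float
    p_adjusted: float


@dataclass
class ContrastFit:
    results: list[ContrastResult]
    d0: float
    s0_sq: float
    signature: list[str]  # significant positive LR pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2): log residual variances are
    matched to a scaled inverse-chi-square prior via digamma/trigamma
    identities; trigamma inversion by Newton's method (tol 1e-8, fallback
    d0=4 on non-convergence)."""
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all residual variances are zero; degenerate ensemble")
    z = np.log(positive)
    e = z - scipy.special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = z.var(ddof=1) - scipy.special.polygamma(1, df / 2.0) if z.size > 1 else 0.0
    if evar <= 0:
        # no excess spread over sampling noise: infinite prior df
        d0 = np.inf
        s0_sq = float(np.exp(e.mean()))
        return d0, s0_sq
    # solve trigamma(d0/2) = evar for d0/2 by Newton iteration
    x = 0.5 + 1.0 / evar  # standard starting value
    converged = False
    for _ in range(100):
        tri = scipy.special.polygamma(1, x)
        delta = tri * (1.0 - tri / evar) / scipy.special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-8 * x:
            converged = True
            break
        if x <= 0:
            break
    if not converged or not np.isfinite(x) or x <= 0:
        logger.warning("trigamma inversion did not converge; fallback d0=4")
        d0 = 4.0
    else:
        d0 = 2.0 * x
    s0_sq = float(np.exp(
        e.mean() + scipy.special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    ))
    return float(d0), s0_sq


def moderated_variance(s2: np.ndarray, df: float, d0: float, s0_sq: float) -> np.ndarray:
    """Shrunken variance: (d0*s0^2 + df*s2) / (d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


def lr_contrast(
    M_by_sample: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    contrast: str,
    alpha: float = 0.05,
    p_adjust: str = "bh",
    d0_override: float | None = None,
) -> ContrastFit:
    """Moderated-t contrast of per-sample LR significant means.

    ``M_by_sample``: samples x LR pairs table (e.g. per-sample sums of
    significant means). ``contrast``: group label tested against the rest.
    A two-group mean-difference linear model is fitted per LR pair; the
    residual-variance ensemble sets the shrinkage prior. ``d0_override``
    forces the prior df (0 -> ordinary t; inf -> pooled prior variance).
    """
    g = pd.Series(groups).reindex(M_by_sample.index)
    if g.isna().any():
        raise ValueError("group labels missing for some samples")
    in_group = (g == contrast).to_numpy()
    n1, n2 = int(in_group.sum()), int((~in_group).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples on each side of the contrast")
    X = M_by_sample.to_numpy(dtype=float)
    # drop all-zero LR pairs (absent across samples)
    keep = ~(np.abs(X).sum(axis=0) == 0)
    pairs = M_by_sample.columns.to_numpy()[keep]
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("no LR pairs with nonzero means")

    mean1 = X[in_group].mean(axis=0)
    mean2 = X[~in_group].mean(axis=0)
    coef = mean1 - mean2
    df_resid = n1 + n2 - 2
    rss = ((X[in_group] - mean1) ** 2).sum(axis=0) + (
        (X[~in_group] - mean2) ** 2
    ).sum(axis=0)
    s2 = rss / df_resid
    if (s2 == 0).all():
        raise ValueError("all residual variances are zero; degenerate ensemble")

    if d0_override is not None:
        d0 = float(d0_override)
        if np.isinf(d0):
            _, s0_sq = estimate_variance_prior(s2, df_resid)
        elif d0 == 0:
            s0_sq = float("nan")
        else:
            _, s0_sq = estimate_variance_prior(s2, df_resid)
    else:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)

    if d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = moderated_variance(s2, df_resid, d0, s0_sq)
    se_scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = coef / (se_scale * np.sqrt(s2_post))
    if np.isinf(d0):
        df_total = float("inf")
        p = 2 * scipy.stats.norm.sf(np.abs(t_stat))
    else:
        df_total = df_resid + d0
        p = 2 * scipy.stats.t.sf(np.abs(t_stat), df=df_total)
    p = np.where(np.isnan(t_stat), 1.0, p)
    p_adj = adjust_pvalues(p, method=p_adjust)

    results = [
        ContrastResult(
            lr_pair=str(pairs[i]),
            coefficient=float(coef[i]),
            s2=float(s2[i]),
            s2_post=float(s2_post[i]),
            t_statistic=float(t_stat[i]) if np.isfinite(t_stat[i]) else float("nan"),
            df_total=float(df_total) if np.isfinite(df_total) else float("inf"),
            p_value=float(p[i]),
            p_adjusted=float(p_adj[i]),
        )
        for i in range(len(pairs))
    ]
    signature = [
        r.lr_pair for r in results if r.coefficient > 0 and r.p_adjusted < alpha
    ]
    return ContrastFit(results=results, d0=float(d0), s0_sq=float(s0_sq), signature=signature)
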