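"""Synthetic multi-sample cohorts with planted structure.

Counts are drawn as ``noise(library_size_c * rate_gt)`` where ``rate_gt``
is a per-gene base rate (log-normal across genes) elevated by
``marker_fold`` on each type's marker genes and by planted ligand-receptor
activity in designated sender/receiver types. Each sample has its own
sub-seeded RNG stream so partial regeneration is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellTable, CountMatrix, LINEAGE_MAP


class SpecError(ValueError):
    """Invalid cohort specification."""


@dataclass
class CellTypeSpec:
    name: str
    n_marker_genes: int = 20
    marker_fold: float = 10.0


@dataclass
class SampleSpec:
    sample_id: str
    site: str
    histotype: str
    n_cells: int
    composition: Mapping[str, float]
    enrichment: str = "none"


@dataclass
class PlantedLR:
    ligand_gene: str
    receptor_gene: str
    sender_type: str
    receiver_type: str
    fold: float = 8.0


@dataclass
class CohortSpec:
    n_genes: int
    cell_types: list[CellTypeSpec]
    samples: list[SampleSpec]
    library_size_mean_log: float = np.log(2000.0)
    library_size_sd_log: float = 0.3
    noise: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 0.5
    planted_lr: list[PlantedLR] = field(default_factory=list)
    template_sample_id: str | None = None
    base_rate_sd_log: float = 0.5
    batch_effect_sd_log: float = 0.0  # optional per-sample gene effect
    seed: int = 0

    def validate(self) -> None:
        type_names = [t.name for t in self.cell_types]
        if len(set(type_names)) != len(type_names):
            raise SpecError("duplicate cell type names")
        for s in self.samples:
            tot = sum(s.composition.values())
            if abs(tot - 1.0) > 1e-9:
                raise SpecError(
                    f"sample {s.sample_id}: composition sums to {tot}, not 1"
                )
            unknown = set(s.composition) - set(type_names)
            if unknown:
                raise SpecError(f"sample {s.sample_id}: unknown types {unknown}")
        n_marker = sum(t.n_marker_genes for t in self.cell_types)
        n_lr = 2 * len(self.planted_lr)
        if n_marker + n_lr > self.n_genes:
            raise SpecError("not enough genes for markers and planted LR pairs")
        if self.noise not in ("poisson", "negative_binomial"):
            raise SpecError(f"unknown noise model {self.noise!r}")


@dataclass
class CohortTruth:
    cell_types: pd.Series  # index cell_id -> true type
    composition: pd.DataFrame  # sample x type, percentages
    planted_lr: list[PlantedLR]
    marker_genes: dict[str, list[str]]
    lr_gene_of: dict[str, str]  # planted gene name -> role


def _allocate_counts(n_cells: int, composition: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation: exact, deterministic type counts."""
    items = sorted(composition.items())
    raw = {t: n_cells * p for t, p in items}
    counts = {t: int(np.floor(v)) for t, v in raw.items()}
    short = n_cells - sum(counts.values())
    remainders = sorted(items, key=lambda kv: (-(raw[kv[0]] - counts[kv[0]]), kv[0]))
    for t, _ in remainders[:short]:
        counts[t] += 1
    return counts


def generate_cohort(spec: CohortSpec):
    """Generate (CountMatrix, CellTable, CohortTruth) for a cohort spec."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    # independent streams: gene structure, then one per sample
    gene_ss, *sample_ss = root.spawn(1 + len(spec.samples))
    gene_rng = np.random.default_rng(gene_ss)

    genes = np.array([f"G{i:05d}" for i in range(spec.n_genes)], dtype=object)
    base = np.exp(gene_rng.normal(0.0, spec.base_rate_sd_log, size=spec.n_genes))

    # reserve marker genes per type, then planted LR genes, from the front
    marker_genes: dict[str, list[str]] = {}
    cursor = 0
    type_names = [t.name for t in spec.cell_types]
    fold_matrix = np.ones((spec.n_genes, len(type_names)))
    for k, t in enumerate(spec.cell_types):
        idx = np.arange(cursor, cursor + t.n_marker_genes)
        cursor += t.n_marker_genes
        marker_genes[t.name] = list(genes[idx])
        fold_matrix[idx, k] = t.marker_fold
    lr_gene_of: dict[str, str] = {}
    for p, lr in enumerate(spec.planted_lr):
        li, ri = cursor, cursor + 1
        cursor += 2
        genes[li] = lr.ligand_gene
        genes[ri] = lr.receptor_gene
        lr_gene_of[lr.ligand_gene] = f"ligand:{lr.sender_type}"
        lr_gene_of[lr.receptor_gene] = f"receptor:{lr.receiver_type}"
        fold_matrix[li, type_names.index(lr.sender_type)] = lr.fold
        fold_matrix[ri, type_names.index(lr.receiver_type)] = lr.fold

    # per-type expression profiles, normalized so rates sum to 1 per type
    profiles = base[:, None] * fold_matrix
    profiles /= profiles.sum(axis=0, keepdims=True)

    blocks = []
    meta_rows = []
    truth_types = {}
    comp_rows = {}
    for s, ss in zip(spec.samples, sample_ss):
        rng = np.random.default_rng(ss)
        counts_by_type = _allocate_counts(s.n_cells, s.composition)
        sample_profiles = profiles
        if spec.batch_effect_sd_log > 0:
            batch = np.exp(
                rng.normal(0.0, spec.batch_effect_sd_log, size=spec.n_genes)
            )
            sample_profiles = profiles * batch[:, None]
            sample_profiles = sample_profiles / sample_profiles.sum(
                axis=0, keepdims=True
            )
        cell_idx = 0
        cols = []
        for tname in sorted(counts_by_type):
            n_t = counts_by_type[tname]
            if n_t == 0:
                continue
            k = type_names.index(tname)
            libs = np.exp(
                rng.normal(
                    spec.library_size_mean_log, spec.library_size_sd_log, size=n_t
                )
            )
            lam = sample_profiles[:, k][:, None] * libs[None, :]
            if spec.noise == "poisson":
                block = rng.poisson(lam)
            else:
                r = 1.0 / spec.nb_dispersion
                # NB as gamma-mixed poisson
                shape = rng.gamma(r, lam / r)
                block = rng.poisson(shape)
            cols.append(block)
            for j in range(n_t):
                cid = f"{s.sample_id}:C{cell_idx + j:05d}"
                truth_types[cid] = tname
                meta_rows.append(
                    dict(
                        cell_id=cid,
                        sample_id=s.sample_id,
                        site=s.site,
                        histotype=s.histotype,
                        enrichment=s.enrichment,
                    )
                )
            cell_idx += n_t
        blocks.append(np.concatenate(cols, axis=1))
        comp_rows[s.sample_id] = {
            t: 100.0 * counts_by_type.get(t, 0) / s.n_cells for t in type_names
        }

    values = sp.csr_matrix(np.concatenate(blocks, axis=1))
    meta = pd.DataFrame(meta_rows)
    matrix = CountMatrix(values, genes, meta["cell_id"].to_numpy(dtype=object))
    cells = CellTable(meta)
    truth = CohortTruth(
        cell_types=pd.Series(truth_types, name="true_type"),
        composition=pd.DataFrame(comp_rows).T.rename_axis("sample_id"),
        planted_lr=list(spec.planted_lr),
        marker_genes=marker_genes,
        lr_gene_of=lr_gene_of,
    )
    return matrix, cells, truth


def template_annotation(cells: CellTable, truth: CohortTruth, template_sample_id: str) -> dict[str, str]:
    """True labels restricted to the template sample's cells."""
    mask = cells.df["sample_id"] == template_sample_id
    ids = cells.df.loc[mask, "cell_id"]
    return {cid: truth.cell_types[cid] for cid in ids}


def pseudo_ihc(
    truth: CohortTruth,
    noise_sd: float,
    seed: int = 0,
    lineage_map: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Noisy pseudo-IHC percentages per sample.

    IHC% = clamp(true lineage % + N(0, noise_sd), 0, 100) with CK7 from the
    epithelia lineage, VIM from stroma, CD45 from immune.
    """
    if noise_sd < 0:
        raise SpecError("noise_sd must be >= 0")
    lmap = dict(lineage_map) if lineage_map is not None else dict(LINEAGE_MAP)
    rng = np.random.default_rng(seed)
    comp = truth.composition
    out = {}
    for stain, lineage in (("CK7", "epithelia"), ("VIM", "stroma"), ("CD45", "immune")):
        members = [t for t in lmap.get(lineage, ()) if t in comp.columns]
        true_pct = comp[members].sum(axis=1) if members else pd.Series(0.0, index=comp.index)
        noisy = true_pct + rng.normal(0.0, noise_sd, size=len(comp)) if noise_sd > 0 else true_pct.astype(float)
        out[stain] = np.clip(noisy, 0.0, 100.0)
    return pd.DataFrame(out, index=comp.index)
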