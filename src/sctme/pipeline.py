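"""End-to-end pipeline orchestration from a single config.

Stage order: filter -> normalize -> hvg -> pca -> cluster -> taca ->
scores -> composition -> lr -> contrast. Each stage writes into its own
subdirectory of the run directory; a manifest records parameters, seeds
and per-stage shapes. Outputs carry no timestamps, so identical config +
inputs reproduce the run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import annotate, composition as comp_mod, lr as lr_mod, preprocess, synthetic
from .io import CellTable, GeneSignatureSet, LRDatabase, read_count_matrix, read_table

logger = logging.getLogger(__name__)

STAGES = (
    "filter", "normalize", "hvg", "pca", "cluster",
    "taca", "scores", "composition", "lr", "contrast",
)


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    min_genes: int = 400
    n_hvg: int = 500
    n_pcs: int = 16
    k_neighbors: int = 20
    resolution: float = 0.2
    r_min: float = 0.7
    n_bins: int = 24
    n_controls: int = 100
    tinf_threshold: float = 10.0
    n_perm: int = 200
    alpha: float = 0.05
    min_cells: int = 50
    p_adjust: str = "bh"
    stages: dict[str, bool] = field(default_factory=dict)
    # input block: either synthetic cohort parameters or file paths
    synthetic: dict[str, Any] | None = None
    input: dict[str, Any] | None = None

    def stage_enabled(self, name: str) -> bool:
        return bool(self.stages.get(name, True))

    def validate(self) -> None:
        if self.min_genes < 0 or self.n_hvg < 1 or self.n_pcs < 1:
            raise ValueError("invalid filtering/HVG/PCA parameters")
        if not (0 < self.r_min <= 1):
            raise ValueError("r_min must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.synthetic is None and self.input is None:
            raise ValueError("config needs a 'synthetic' or 'input' block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def stage_seeds(seed: int) -> dict[str, int]:
    """Named per-stage RNG streams derived from one global seed, so
    toggling a stage cannot shift another stage's randomness."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    # keep within C int range (leidenalg takes a signed 32-bit seed)
    return {
        name: int(child.generate_state(1)[0] & 0x7FFFFFFF)
        for name, child in zip(STAGES, children)
    }


def demo_cohort_spec(seed: int = 0) -> synthetic.CohortSpec:
    """Small packaged cohort: 6 canonical types, 4 samples, planted LR."""
    types = [
        synthetic.CellTypeSpec("epithelial", 25, 10.0),
        synthetic.CellTypeSpec("fibroblast", 25, 10.0),
        synthetic.CellTypeSpec("macrophage", 25, 10.0),
        synthetic.CellTypeSpec("T", 25, 10.0),
        synthetic.CellTypeSpec("endothelial", 25, 10.0),
        synthetic.CellTypeSpec("B", 25, 10.0),
    ]
    base = {"epithelial": 0.35, "fibroblast": 0.2, "macrophage": 0.12,
            "T": 0.15, "endothelial": 0.08, "B": 0.1}
    shifted = {"epithelial": 0.3, "fibroblast": 0.15, "macrophage": 0.12,
               "T": 0.25, "endothelial": 0.08, "B": 0.1}
    samples = [
        synthetic.SampleSpec("S1", "primary", "HGSOC", 700, base),
        synthetic.SampleSpec("S2", "metastatic", "HGSOC", 700, shifted),
        synthetic.SampleSpec("S3", "primary", "clear_cell", 700, base),
        synthetic.SampleSpec("S4", "metastatic", "clear_cell", 700, shifted),
    ]
    planted = [
        synthetic.PlantedLR("LIGA", "RECA", "epithelial", "fibroblast", 8.0),
        synthetic.PlantedLR("LIGB", "RECB", "T", "epithelial", 8.0),
    ]
    return synthetic.CohortSpec(
        n_genes=800,
        cell_types=types,
        samples=samples,
        planted_lr=planted,
        template_sample_id="S1",
        seed=seed,
    )


def _demo_signatures(truth: synthetic.CohortTruth) -> dict[str, GeneSignatureSet]:
    """Signature sets assembled from planted marker programs, standing in
    for cycle/subtype/outcome gene lists."""
    mk = truth.marker_genes
    tnames = sorted(mk)
    def take(i, sl): return mk[tnames[i % len(tnames)]][sl]
    cycle = GeneSignatureSet("cycle", {
        "G1/S": take(0, slice(0, 10)),
        "G2/M": take(1, slice(0, 10)),
        "M/G1": take(2, slice(0, 10)),
    })
    subtype = GeneSignatureSet("subtype", {
        "differentiated": take(0, slice(10, 20)),
        "immunoreactive": take(3, slice(10, 20)),
        "mesenchymal": take(1, slice(10, 20)),
        "proliferative": take(4, slice(10, 20)),
    })
    outcome = GeneSignatureSet("outcome", {
        "good": take(2, slice(10, 20)),
        "poor": take(5, slice(10, 20)),
    })
    return {"cycle_phase": cycle, "subtype": subtype, "outcome": outcome}


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        spec = _spec_from_mapping(config.synthetic, default_seed=config.seed)
        matrix, cells, truth = synthetic.generate_cohort(spec)
        template = synthetic.template_annotation(
            cells, truth, spec.template_sample_id or spec.samples[0].sample_id
        )
        signatures = _demo_signatures(truth)
        db = lr_mod.build_lr_db([
            pd.DataFrame({
                "ligand": [p.ligand_gene for p in truth.planted_lr] or ["G00000"],
                "receptor": [p.receptor_gene for p in truth.planted_lr] or ["G00001"],
                "source": "planted",
            })
        ])
        return matrix, cells, template, signatures, db, truth
    inp = config.input or {}
    matrix = read_count_matrix(
        inp["matrix"], format=inp.get("format", "mtx"),
        genes_path=inp.get("genes"), barcodes_path=inp.get("barcodes"),
        cells_are_rows=bool(inp.get("cells_are_rows", False)),
    )
    cells = read_table(inp["cell_table"], schema="cell_table")
    template_df = pd.read_csv(inp["template"])
    template = dict(zip(template_df["cell_id"], template_df["cell_type"]))
    signatures = {}
    for column, manifest in (inp.get("signatures") or {}).items():
        from .io import read_signature_manifest
        signatures[column] = read_signature_manifest(manifest)
    db = read_table(inp["lr_pairs"], schema="lr_pairs") if "lr_pairs" in inp else None
    return matrix, cells, template, signatures, db, None


def _spec_from_mapping(raw: Mapping[str, Any], default_seed: int) -> synthetic.CohortSpec:
    if raw.get("demo"):
        return demo_cohort_spec(seed=raw.get("seed", default_seed))
    kwargs = dict(raw)
    kwargs.pop("demo", None)
    kwargs.setdefault("seed", default_seed)
    kwargs["cell_types"] = [synthetic.CellTypeSpec(**t) for t in kwargs["cell_types"]]
    kwargs["samples"] = [synthetic.SampleSpec(**s) for s in kwargs["samples"]]
    kwargs["planted_lr"] = [
        synthetic.PlantedLR(**p) for p in kwargs.get("planted_lr", [])
    ]
    return synthetic.CohortSpec(**kwargs)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all enabled stages; returns the run directory."""
    config.validate()
    seeds = stage_seeds(config.seed)
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "stage_seeds": seeds,
        "stages": [],
    }

    def record(name: str, **info):
        manifest["stages"].append({"name": name, **info})

    def stage_dir(i: int, name: str) -> Path:
        d = run_dir / f"{i:02d}_{name}"
        d.mkdir(parents=True, exist_ok=True)
        return d

    matrix, cells, template, signatures, db, truth = _load_inputs(config)

    current = matrix
    try:
        # 1 filter -------------------------------------------------------
        if config.stage_enabled("filter"):
            d = stage_dir(1, "filter")
            current = preprocess.filter_cells(current, min_genes=config.min_genes)
            pd.Series(current.cell_ids).to_csv(
                d / "retained_cells.csv", index=False, header=["cell_id"]
            )
            record("filter", n_cells=current.n_cells, n_genes=current.n_genes)
        cells = cells.aligned_to(list(current.cell_ids))

        # 2 normalize ----------------------------------------------------
        nm = preprocess.lognormalize_tp10k(current)
        if config.stage_enabled("normalize"):
            d = stage_dir(2, "normalize")
            totals = np.expm1(nm.values).sum(axis=0)
            pd.DataFrame({"cell_id": nm.cell_ids, "tp10k_total": totals}).to_csv(
                d / "cell_totals.csv", index=False, float_format="%.4f"
            )
            record("normalize", n_cells=nm.n_cells)

        # 3 hvg ----------------------------------------------------------
        hvg = preprocess.select_hvg(nm, n_hvg=min(config.n_hvg, nm.n_genes))
        if config.stage_enabled("hvg"):
            d = stage_dir(3, "hvg")
            pd.Series(hvg).to_csv(d / "hvg.csv", index=False, header=["gene"])
            record("hvg", n_hvg=len(hvg))

        # 4 pca ----------------------------------------------------------
        scaled = preprocess.scale_center(nm, hvg)
        embedding = preprocess.pca_embed(scaled, n_pcs=config.n_pcs)
        if config.stage_enabled("pca"):
            d = stage_dir(4, "pca")
            pd.DataFrame(
                embedding, index=pd.Index(nm.cell_ids, name="cell_id"),
                columns=[f"PC{i+1}" for i in range(embedding.shape[1])],
            ).to_csv(d / "embedding.csv", float_format="%.6f")
            record("pca", n_pcs=config.n_pcs)

        # 5 cluster ------------------------------------------------------
        clusters = preprocess.snn_cluster(
            embedding, k_neighbors=config.k_neighbors,
            resolution=config.resolution, seed=seeds["cluster"],
            cell_ids=nm.cell_ids,
        )
        if config.stage_enabled("cluster"):
            d = stage_dir(5, "cluster")
            clusters.to_series().to_csv(d / "clusters.csv")
            record("cluster", n_clusters=len(set(clusters.labels.tolist())))

        # 6 taca ---------------------------------------------------------
        taca = annotate.taca_assign(clusters, template, r_min=config.r_min)
        cells.df["cluster"] = clusters.labels
        cells.df["cell_type"] = taca.cell_labels.to_numpy()
        if config.stage_enabled("taca"):
            d = stage_dir(6, "taca")
            taca.ratios.to_csv(d / "cluster_ratios.csv", float_format="%.6f")
            pd.Series(taca.cluster_labels, name="label").rename_axis("cluster").to_csv(
                d / "cluster_labels.csv"
            )
            taca.cell_labels.to_csv(d / "cell_types.csv")
            record("taca", n_undecided=int((taca.cell_labels == "undecided").sum()))

        # 7 scores -------------------------------------------------------
        if config.stage_enabled("scores") and signatures:
            d = stage_dir(7, "scores")
            labels = annotate.classify_cells(
                nm, signatures, n_bins=config.n_bins,
                n_controls=config.n_controls, seed=seeds["scores"],
            )
            for col in labels.columns:
                cells.df[col] = labels[col].to_numpy()
            labels.to_csv(d / "labels.csv")
            record("scores", columns=list(labels.columns))
        else:
            record("scores", skipped=True)

        # 8 composition --------------------------------------------------
        comp = comp_mod.build_composition(cells)
        if config.stage_enabled("composition"):
            d = stage_dir(8, "composition")
            tinf = comp_mod.classify_tinf(comp, threshold=config.tinf_threshold) \
                if "T" in comp.df.columns else None
            if tinf is not None:
                comp.df["tinf"] = tinf.to_numpy()
            comp.df.to_csv(d / "composition.csv", index=False, float_format="%.4f")
            comparisons = []
            if "site" in comp.df.columns and comp.df["site"].nunique() == 2:
                site_counts = comp.df["site"].value_counts()
                if (site_counts >= 2).all():
                    comparisons += comp_mod.compare_groups(comp, "site")
            if comparisons:
                pd.DataFrame([vars(c) for c in comparisons]).to_csv(
                    d / "group_comparisons.csv", index=False, float_format="%.6g"
                )
            if truth is not None:
                ihc = synthetic.pseudo_ihc(truth, noise_sd=5.0, seed=seeds["composition"])
                merged = comp.df.merge(
                    ihc, left_on="sample_id", right_index=True, how="left"
                )
                comp2 = comp_mod.CompositionTable(merged)
                corr = comp_mod.ihc_correlate(comp2, exclude=())
                pd.DataFrame([vars(c) for c in corr]).to_csv(
                    d / "ihc_correlations.csv", index=False, float_format="%.6g"
                )
            record("composition", n_samples=len(comp.df))
        else:
            record("composition", skipped=True)

        # 9 lr -----------------------------------------------------------
        sig_means: dict[str, pd.DataFrame] = {}
        if config.stage_enabled("lr") and db is not None and len(db):
            d = stage_dir(9, "lr")
            long_rows = []
            for sample_id, sub in cells.df.groupby("sample_id", sort=True):
                idx = sub.index.to_numpy()
                nm_s = nm.subset_cells(idx)
                labels_s = pd.Series(
                    sub["cell_type"].to_numpy(), index=sub["cell_id"].to_numpy()
                )
                res = lr_mod.lr_test_sample(
                    nm_s, labels_s, db, sample_id=sample_id,
                    n_perm=config.n_perm, seed=seeds["lr"],
                )
                M = lr_mod.significant_means(
                    res, alpha=config.alpha, min_cells=config.min_cells
                )
                sig_means[sample_id] = M
                t = res.table.assign(sample_id=sample_id)
                long_rows.append(t)
            long = pd.concat(long_rows, ignore_index=True) if long_rows else pd.DataFrame()
            if len(long):
                long.to_csv(d / "lr_tests.csv", index=False, float_format="%.6g")
            counts = {
                s: lr_mod.count_interactions(M, by="sample")
                for s, M in sig_means.items()
            }
            pd.Series(counts, name="n_interactions").rename_axis("sample_id").to_csv(
                d / "interaction_counts.csv"
            )
            record("lr", n_tests=int(len(long)))
        else:
            record("lr", skipped=True)

        # 10 contrast ----------------------------------------------------
        if config.stage_enabled("contrast") and sig_means:
            d = stage_dir(10, "contrast")
            rows = {
                s: (M.sum(axis=1) if len(M) else pd.Series(dtype=float))
                for s, M in sig_means.items()
            }
            M_by_sample = pd.DataFrame(rows).T.fillna(0.0).sort_index()
            M_by_sample.to_csv(d / "significant_means_by_sample.csv",
                               float_format="%.6g")
            group_col = "histotype" if "histotype" in cells.df.columns else None
            wrote = False
            if group_col:
                groups = cells.df.groupby("sample_id")[group_col].first()
                for g in sorted(groups.unique()):
                    n_in = int((groups == g).sum())
                    if n_in < 2 or len(groups) - n_in < 2:
                        continue
                    try:
                        fit = lr_mod.lr_contrast(
                            M_by_sample, groups, contrast=g,
                            alpha=config.alpha, p_adjust=config.p_adjust,
                        )
                    except ValueError as exc:
                        logger.warning("contrast %s skipped: %s", g, exc)
                        continue
                    fit.to_frame().to_csv(
                        d / f"contrast_{g}.csv", index=False, float_format="%.6g"
                    )
                    wrote = True
            record("contrast", wrote=wrote)
        else:
            record("contrast", skipped=True)
    except Exception as exc:
        stage = manifest["stages"][-1]["name"] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return run_dir
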