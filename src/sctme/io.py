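"""Core data types and readers/writers.

Internal matrix convention is genes x cells. Loaders transpose when told
that the on-disk orientation is cells-as-rows. Gene identifiers are
case-sensitive symbols; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

SITES = ("primary", "metastatic")
ENRICHMENTS = ("none", "cd45", "tumor", "non_tumor")

#: canonical major cell-type names used by composition tables
MAJOR_TYPES = (
    "epithelial",
    "ESC",
    "endothelial",
    "fibroblast",
    "MSC",
    "macrophage",
    "B",
    "plasma_B",
    "T",
)

#: lineage aggregates used for IHC comparison
LINEAGE_MAP: dict[str, tuple[str, ...]] = {
    "epithelia": ("epithelial", "ESC"),
    "stroma": ("endothelial", "fibroblast", "MSC"),
    "immune": ("macrophage", "B", "plasma_B", "T"),
}

#: IHC stain -> lineage aggregate it estimates
IHC_TO_LINEAGE = {"CK7": "epithelia", "VIM": "stroma", "CD45": "immune"}


class SchemaError(ValueError):
    """A table is missing required columns."""


class MatrixValidationError(ValueError):
    """A count matrix violates its invariants."""


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer UMI counts."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        self.values = self.values.tocsr()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise MatrixValidationError(
                f"gene_ids length {len(self.gene_ids)} != {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise MatrixValidationError(
                f"cell_ids length {len(self.cell_ids)} != {n_cells} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise MatrixValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise MatrixValidationError("duplicate cell ids")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise MatrixValidationError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise MatrixValidationError("non-integral counts")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[:, idx], self.gene_ids, self.cell_ids[idx]
        )

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in genes], dtype=int)
        return CountMatrix(self.values[idx, :], np.asarray(genes, dtype=object), self.cell_ids)


CELL_TABLE_REQUIRED = ("cell_id", "sample_id", "site")


@dataclass
class CellTable:
    """Per-cell metadata; one row per cell."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CELL_TABLE_REQUIRED if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cell table missing columns: {missing}")
        if self.df["cell_id"].duplicated().any():
            raise SchemaError("duplicate cell_id rows in cell table")
        bad_site = set(self.df["site"].dropna()) - set(SITES)
        if bad_site:
            raise SchemaError(f"invalid site values: {sorted(bad_site)}")
        if "enrichment" in self.df.columns:
            bad = set(self.df["enrichment"].dropna()) - set(ENRICHMENTS)
            if bad:
                raise SchemaError(f"invalid enrichment values: {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    def aligned_to(self, cell_ids: Sequence[str]) -> "CellTable":
        """Reorder (and subset) rows to match a matrix's cell ids."""
        indexed = self.df.set_index("cell_id")
        missing = [c for c in cell_ids if c not in indexed.index]
        if missing:
            raise SchemaError(f"{len(missing)} cells absent from cell table")
        out = indexed.loc[list(cell_ids)].reset_index()
        return CellTable(out)


@dataclass
class GeneSignatureSet:
    """Named collection of gene lists, e.g. cell-cycle phase markers."""

    name: str
    signatures: dict[str, list[str]]

    def __post_init__(self) -> None:
        for label, genes in self.signatures.items():
            if not genes:
                raise SchemaError(f"signature {label!r} is empty")
            if len(set(genes)) != len(genes):
                raise SchemaError(f"signature {label!r} has duplicate genes")

    @property
    def labels(self) -> list[str]:
        return list(self.signatures)


@dataclass
class LRDatabase:
    """Merged ligand-receptor pair list with provenance tags."""

    pairs: pd.DataFrame  # columns: ligand, receptor, source

    def __post_init__(self) -> None:
        for col in ("ligand", "receptor"):
            if col not in self.pairs.columns:
                raise SchemaError(f"LR table missing column {col!r}")
        if "source" not in self.pairs.columns:
            self.pairs = self.pairs.assign(source="unspecified")
        if self.pairs[["ligand", "receptor"]].isna().any().any():
            raise SchemaError("LR table has missing ligand/receptor entries")
        dups = self.pairs.duplicated(subset=["ligand", "receptor"])
        if dups.any():
            logger.warning("dropping %d duplicate LR pairs", int(dups.sum()))
            self.pairs = self.pairs[~dups]
        self.pairs = self.pairs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_tuples(self) -> list[tuple[str, str]]:
        return list(zip(self.pairs["ligand"], self.pairs["receptor"]))


@dataclass
class CompositionTable:
    """Per-sample cell counts and major-type percentages.

    Percentage columns are named after :data:`MAJOR_TYPES` entries (plus
    any extra types present in the data); optional IHC columns are CK7,
    VIM, CD45; derived columns are site and tinf.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.df.columns:
            raise SchemaError("composition table missing column 'sample_id'")
        types = self.type_columns()
        if not types:
            raise SchemaError("composition table has no cell-type columns")
        pct = self.df[types].fillna(0.0)
        if (pct.values < 0).any() or (pct.values > 100).any():
            raise SchemaError("percentages outside [0, 100]")
        totals = pct.sum(axis=1)
        if (totals > 100.5 + 1e-9).any():
            raise SchemaError("major-type percentages exceed 100 (+0.5 slack)")
        self.df = self.df.reset_index(drop=True)

    def type_columns(self) -> list[str]:
        known = set(MAJOR_TYPES)
        reserved = {"sample_id", "patient", "site", "tissue", "n_cells",
                    "tinf", "undecided", *IHC_TO_LINEAGE}
        cols = [c for c in self.df.columns if c in known]
        cols += [
            c for c in self.df.columns
            if c.startswith("pct_") and c not in reserved
        ]
        return cols

    def lineage_percent(self, lineage: str) -> pd.Series:
        members = [t for t in LINEAGE_MAP[lineage] if t in self.df.columns]
        if not members:
            raise SchemaError(f"no columns for lineage {lineage!r}")
        return self.df[members].sum(axis=1)


# ---------------------------------------------------------------------------
# count matrix IO


def read_count_matrix(
    path: str | Path,
    format: str = "mtx",
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    cells_are_rows: bool = False,
) -> CountMatrix:
    """Read a count matrix from MatrixMarket or dense CSV.

    For ``mtx``, sibling files ``genes.tsv`` and ``barcodes.tsv`` are used
    unless explicit paths are given. For ``csv``, row index = gene ids and
    header = cell ids (transposed if ``cells_are_rows``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        barcodes_path = (
            Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        )
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:  # scipy raises ValueError with line info
            raise SchemaError(f"malformed MatrixMarket file {path}: {exc}") from exc
        genes = _read_id_list(genes_path)
        cells = _read_id_list(barcodes_path)
        values = sp.csr_matrix(mat)
    elif format == "csv":
        df = pd.read_csv(path, index_col=0)
        genes = df.index.astype(str).to_numpy(dtype=object)
        cells = df.columns.astype(str).to_numpy(dtype=object)
        values = sp.csr_matrix(df.to_numpy())
    else:
        raise ValueError(f"unknown format {format!r}")
    if cells_are_rows:
        values = values.T.tocsr()
        genes, cells = cells, genes
    return CountMatrix(values, genes, cells)


def write_count_matrix(m: CountMatrix, path: str | Path, format: str = "mtx") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        coo = m.values.tocoo()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scipy.io.mmwrite(str(path), sp.coo_matrix(
                (coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape
            ))
        _write_id_list(path.parent / "genes.tsv", m.gene_ids)
        _write_id_list(path.parent / "barcodes.tsv", m.cell_ids)
    elif format == "csv":
        pd.DataFrame(
            m.dense().astype(np.int64), index=m.gene_ids, columns=m.cell_ids
        ).to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_id_list(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return np.asarray(ids, dtype=object)


def _write_id_list(path: Path, ids: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


# ---------------------------------------------------------------------------
# typed tables


def read_table(path: str | Path, schema: str):
    """Read a typed table: cell_table, signature_set, lr_pairs or composition."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if schema == "cell_table":
        return CellTable(df)
    if schema == "signature_set":
        for col in ("label", "gene"):
            if col not in df.columns:
                raise SchemaError(f"signature table missing column {col!r}")
        sigs = {
            label: list(dict.fromkeys(sub["gene"]))
            for label, sub in df.groupby("label", sort=False)
        }
        return GeneSignatureSet(name=path.stem, signatures=sigs)
    if schema == "lr_pairs":
        return LRDatabase(df)
    if schema == "composition":
        return CompositionTable(df)
    raise ValueError(f"unknown schema {schema!r}")


def read_signature_manifest(manifest_path: str | Path) -> GeneSignatureSet:
    """YAML manifest mapping label -> file of one gene symbol per line."""
    import yaml

    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        mapping: Mapping[str, str] = yaml.safe_load(fh)
    sigs = {}
    for label, rel in mapping.items():
        p = manifest_path.parent / rel
        with open(p) as fh:
            genes = [ln.strip() for ln in fh if ln.strip()]
        sigs[label] = list(dict.fromkeys(genes))
    return GeneSignatureSet(name=manifest_path.stem, signatures=sigs)
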