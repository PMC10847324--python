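"""Per-sample composition tables, T-cell infiltration classification,
group comparisons, and IHC-vs-annotation Pearson correlations."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io import IHC_TO_LINEAGE, LINEAGE_MAP, CellTable, CompositionTable

UNDECIDED = "undecided"

#: samples excluded from IHC correlation (CD45-enriched Drop-seq runs)
DEFAULT_IHC_EXCLUDE = ("P3-1", "P3-2", "P4-1")


@dataclass
class GroupComparison:
    cell_type: str
    grouping: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    testable: bool = True


@dataclass
class IhcCorrelation:
    lineage: str
    stain: str
    n: int
    r: float
    p_value: float


def build_composition(cells: CellTable) -> CompositionTable:
    """Per-sample percentage of each assigned type among all typed cells.

    "undecided" cells count in the denominator but are reported in their
    own column, not as a major type.
    """
    df = cells.df
    for col in ("sample_id", "cell_type"):
        if col not in df.columns:
            raise ValueError(f"cell table missing column {col!r}")
    if df["cell_type"].isna().any():
        raise ValueError("cells without an assigned type")
    rows = []
    types = sorted(t for t in df["cell_type"].unique() if t != UNDECIDED)
    for sample_id, sub in df.groupby("sample_id", sort=True):
        n = len(sub)
        counts = sub["cell_type"].value_counts()
        row: dict[str, object] = {"sample_id": sample_id, "n_cells": n}
        if "site" in sub.columns:
            row["site"] = sub["site"].iloc[0]
        if "histotype" in sub.columns:
            row["histotype"] = sub["histotype"].iloc[0]
        for t in types:
            row[t] = 100.0 * counts.get(t, 0) / n
        row[UNDECIDED] = 100.0 * counts.get(UNDECIDED, 0) / n
        rows.append(row)
    return CompositionTable(pd.DataFrame(rows))


def classify_tinf(
    comp: CompositionTable, threshold: float = 10.0, t_column: str = "T"
) -> pd.Series:
    """High when T-cell percentage strictly exceeds the threshold, else Low.

    A sample exactly at the threshold is Low (the rule is defined only by
    strict inequalities; the boundary is resolved downward).
    """
    if t_column not in comp.df.columns:
        raise ValueError(f"composition table has no column {t_column!r}")
    t_pct = comp.df[t_column]
    out = pd.Series(
        np.where(t_pct > threshold, "High", "Low"),
        index=comp.df["sample_id"],
        name="tinf",
    )
    return out


def compare_groups(
    comp: CompositionTable,
    grouping: str,
    level: str = "major",
    group_column: str | None = None,
) -> list[GroupComparison]:
    """Welch two-sided t-tests per cell type on per-sample percentages.

    ``grouping`` is "site" (primary vs metastatic) or "tinf" (High vs Low);
    ``group_column`` overrides the column name.
    """
    col = group_column or grouping
    if col not in comp.df.columns:
        raise ValueError(f"composition table has no grouping column {col!r}")
    groups = comp.df[col]
    levels = sorted(groups.dropna().unique().tolist())
    if len(levels) != 2:
        raise ValueError(f"grouping {col!r} must have exactly 2 levels, got {levels}")
    a_name, b_name = levels
    mask_a = (groups == a_name).to_numpy()
    mask_b = (groups == b_name).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    out = []
    cols = comp.type_columns() if level == "major" else [
        c for c in comp.df.columns if c.startswith("sub_")
    ]
    for t in cols:
        xa = comp.df.loc[mask_a, t].to_numpy(dtype=float)
        xb = comp.df.loc[mask_b, t].to_numpy(dtype=float)
        if (np.ptp(xa) == 0 and np.ptp(xb) == 0) and xa[0] == xb[0]:
            # identical constant groups: no difference, but Welch is 0/0
            out.append(GroupComparison(t, grouping, a_name, b_name,
                                       xa.mean(), xb.mean(), 0.0, 1.0))
            continue
        if np.ptp(xa) == 0 and np.ptp(xb) == 0:
            out.append(GroupComparison(t, grouping, a_name, b_name,
                                       xa.mean(), xb.mean(), np.nan, np.nan,
                                       testable=False))
            continue
        t_stat, p = scipy.stats.ttest_ind(xa, xb, equal_var=False)
        out.append(GroupComparison(t, grouping, a_name, b_name,
                                   float(xa.mean()), float(xb.mean()),
                                   float(t_stat), float(p)))
    return out


def ihc_correlate(
    comp: CompositionTable,
    mapping: Mapping[str, str] | None = None,
    exclude: Sequence[str] = DEFAULT_IHC_EXCLUDE,
) -> list[IhcCorrelation]:
    """Pearson correlations of annotated lineage percentages vs IHC stains.

    ``mapping`` maps stain column -> lineage aggregate (default CK7 ->
    epithelia, VIM -> stroma, CD45 -> immune). Samples in ``exclude`` and
    samples missing either value are dropped pairwise.
    """
    mapping = dict(mapping) if mapping is not None else dict(IHC_TO_LINEAGE)
    df = comp.df[~comp.df["sample_id"].isin(set(exclude))]
    out = []
    for stain, lineage in mapping.items():
        if stain not in df.columns:
            continue
        members = [t for t in LINEAGE_MAP[lineage] if t in df.columns]
        if not members:
            continue
        x = df[members].sum(axis=1).to_numpy(dtype=float)
        y = df[stain].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if len(x) < 3:
            raise ValueError(f"fewer than 3 paired samples for {stain}")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"constant vector for {stain}; correlation undefined")
        r, p = scipy.stats.pearsonr(x, y)
        out.append(IhcCorrelation(lineage, stain, len(x), float(r), float(p)))
    return out


def correlate_columns(
    comp: CompositionTable,
    type_columns: Sequence[str],
    stain: str,
    exclude: Sequence[str] = DEFAULT_IHC_EXCLUDE,
) -> IhcCorrelation:
    """Pearson correlation of an arbitrary type-column sum vs an IHC stain."""
    df = comp.df[~comp.df["sample_id"].isin(set(exclude))]
    x = df[list(type_columns)].sum(axis=1).to_numpy(dtype=float)
    y = df[stain].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("fewer than 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return IhcCorrelation("+".join(type_columns), stain, len(x), float(r), float(p))


def load_reference_composition() -> CompositionTable:
    """Packaged 21-sample reference composition table (percentages, IHC
    stains, site and published T-infiltration category)."""
    with resources.files("sctme.data").joinpath("table2.csv").open() as fh:
        df = pd.read_csv(fh)
    return CompositionTable(df)
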