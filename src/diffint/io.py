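"""Readers and writers for every external format the pipeline touches.

The pipeline joins three kinds of evidence on official gene symbols:
a phenotype-labeled expression matrix (genes x samples), a physical
protein-protein interaction network (BioGRID TAB), and per-protein
body-fluid abundance.  Clinical follow-up and docking-result tables
feed the downstream survival and target modules.  Symbols are matched
case-sensitively; no alias resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

PHENOTYPES = ("normal", "tumor")
FLUIDS = ("serum", "plasma", "saliva", "urine")


class FormatError(ValueError):
    """A file does not match the expected dialect (missing columns etc.)."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (duplicate keys etc.)."""


@dataclass
class ExpressionMatrix:
    """Gene-level expression, genes as rows, with one phenotype label per sample.

    Values must be finite and non-negative (normalized abundances); missing
    values are rejected because the binarization statistic downstream has no
    missing-data rule.
    """

    values: pd.DataFrame
    phenotype: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if v.isna().any().any():
            bad = v.columns[v.isna().any(axis=0)].tolist()
            raise ValidationError(f"missing expression values in samples: {bad}")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite expression values")
        if (arr < 0).any():
            raise ValidationError("negative expression values")
        missing = [s for s in v.columns if s not in self.phenotype.index]
        if missing:
            raise ValidationError(f"samples without phenotype label: {missing}")
        self.phenotype = self.phenotype.reindex(v.columns)
        bad_labels = set(self.phenotype.unique()) - set(PHENOTYPES)
        if bad_labels:
            raise ValidationError(f"unknown phenotype labels: {sorted(bad_labels)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, phenotype: str) -> list[str]:
        return list(self.phenotype.index[self.phenotype == phenotype])


# ---------------------------------------------------------------------------
# BioGRID network
# ---------------------------------------------------------------------------

#: column names accepted for each role, in priority order (TAB 2.0 / 3.0)
BIOGRID_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "symbol_a": ("Official Symbol Interactor A",),
    "symbol_b": ("Official Symbol Interactor B",),
    "system_type": ("Experimental System Type",),
    "organism_a": ("Organism ID Interactor A", "Organism Interactor A"),
    "organism_b": ("Organism ID Interactor B", "Organism Interactor B"),
}


def read_biogrid(
    path: str | Path,
    organism: str | int | None = None,
    physical_only: bool = True,
    columns: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Read a BioGRID TAB file into an undirected simple graph of gene symbols.

    Self-interactions are dropped and duplicate pairs (in either order)
    collapse to a single edge.  With ``physical_only`` rows whose
    experimental-system type is not "physical" are excluded.  ``organism``
    (NCBI taxonomy id, e.g. 9606) keeps only rows where both interactors
    match.  ``columns`` overrides the default column-name mapping for other
    dialects.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    colmap = _resolve_biogrid_columns(df.columns, columns)
    if physical_only:
        if "system_type" not in colmap:
            raise FormatError("physical_only requires an experimental-system-type column")
        df = df[df[colmap["system_type"]].str.lower() == "physical"]
    if organism is not None:
        org = str(organism)
        for role in ("organism_a", "organism_b"):
            if role in colmap:
                df = df[df[colmap[role]].astype(str) == org]
    net = nx.Graph()
    a = df[colmap["symbol_a"]]
    b = df[colmap["symbol_b"]]
    for x, y in zip(a, b):
        if pd.isna(x) or pd.isna(y) or x == y:
            continue
        net.add_edge(x, y)
    if net.number_of_edges() == 0:
        warnings.warn("BioGRID import produced an empty network", stacklevel=2)
    return net


def _resolve_biogrid_columns(
    present: Iterable[str], override: Mapping[str, str] | None
) -> dict[str, str]:
    present = list(present)
    colmap: dict[str, str] = {}
    for role, candidates in BIOGRID_COLUMNS.items():
        if override and role in override:
            candidates = (override[role],)
        for c in candidates:
            if c in present:
                colmap[role] = c
                break
    for required in ("symbol_a", "symbol_b"):
        if required not in colmap:
            raise FormatError(
                f"missing required BioGRID column for {required}; "
                f"accepted names: {BIOGRID_COLUMNS[required]}"
            )
    return colmap


def filter_network_to_expression(net: nx.Graph, expr: ExpressionMatrix) -> nx.Graph:
    """Edge-induced subgraph on edges whose both endpoints have expression data.

    The node set of the result is exactly the set of endpoints of surviving
    edges, so isolated nodes never appear.  Idempotent.
    """
    genes = set(expr.gene_ids)
    out = nx.Graph()
    out.add_edges_from((a, b) for a, b in net.edges if a in genes and b in genes)
    return out


# ---------------------------------------------------------------------------
# Network serialization (Cytoscape-friendly)
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "tsv")
DPPI_COLUMNS = ["protein_a", "protein_b", "f_N", "f_T", "q", "call"]


def write_network(obj: nx.Graph | pd.DataFrame, path: str | Path, format: str = "sif") -> None:
    """Write a network, or a dPPI table, to SIF, GraphML or TSV.

    A plain graph serializes as edges only; a dPPI table (DataFrame with
    ``protein_a``/``protein_b`` plus frequency columns) carries f_N, f_T,
    q and call as edge attributes where the format supports them.
    """
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        if fmt == "tsv":
            obj.to_csv(path, sep="\t", index=False, columns=[c for c in DPPI_COLUMNS if c in obj])
            return
        g = nx.Graph()
        for row in obj.itertuples(index=False):
            attrs = {
                k: getattr(row, k) for k in ("f_N", "f_T", "q", "call") if hasattr(row, k)
            }
            g.add_edge(row.protein_a, row.protein_b, **attrs)
        obj = g
    if fmt == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(map(sorted, obj.edges)):
                fh.write(f"{a}\tpp\t{b}\n")
            for n in sorted(nx.isolates(obj)):
                fh.write(f"{n}\n")
    elif fmt == "graphml":
        nx.write_graphml(obj, path)
    else:  # tsv
        with open(path, "w") as fh:
            fh.write("protein_a\tprotein_b\n")
            for a, b in sorted(map(sorted, obj.edges)):
                fh.write(f"{a}\t{b}\n")


def read_network(path: str | Path, format: str = "sif") -> nx.Graph:
    """Read a network previously written by :func:`write_network`."""
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    g = nx.Graph()
    if fmt == "sif":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    g.add_edge(parts[0], parts[2])
                elif parts[0]:
                    g.add_node(parts[0])
    elif fmt == "graphml":
        g = nx.Graph(nx.read_graphml(path))
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        g.add_edges_from(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return g


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_expression(expr_path: str | Path, phenotype_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a two-column (sample_id, label) sidecar."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    pheno = pd.read_csv(phenotype_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(values=values, phenotype=pheno)


def write_expression(expr: ExpressionMatrix, expr_path: str | Path, phenotype_path: str | Path) -> None:
    expr.values.to_csv(expr_path, sep="\t", index_label="gene")
    expr.phenotype.rename("phenotype").to_csv(phenotype_path, sep="\t", index_label="sample_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical follow-up table: index patient/sample id, columns time (days), event (0/1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"time", "event"} - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing columns: {sorted(missing)}")
    if df.index.has_duplicates:
        rows = (np.flatnonzero(df.index.duplicated()) + 2).tolist()
        raise ValidationError(f"duplicate patient ids at rows {rows}")
    bad = df.index[df["time"] < 0].tolist()
    if bad:
        raise ValidationError(f"negative follow-up time for patients {bad}")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])].tolist()
        raise ValidationError(f"non-binary event indicator for patients {bad}")
    return df[["time", "event"]].astype({"time": float, "event": int})


def read_secretion(path: str | Path) -> pd.DataFrame:
    """Body-fluid abundance table (ppm), one row per protein, columns serum/plasma/saliva/urine.

    Missing abundances stay NaN (protein not detected in that fluid).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = [c for c in FLUIDS if c in df.columns]
    if not cols:
        raise FormatError(f"secretion table has none of the fluid columns {FLUIDS}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate proteins in secretion table: {dups}")
    sub = df[cols]
    if (sub < 0).any().any():
        raise ValidationError("negative abundance in secretion table")
    return sub


def read_docking(path: str | Path) -> pd.DataFrame:
    """Docking-results table: ligand_id, affinity (kcal/mol, negative favorable), ligand_efficiency."""
    df = pd.read_csv(path, sep="\t")
    missing = {"ligand_id", "affinity", "ligand_efficiency"} - set(df.columns)
    if missing:
        raise FormatError(f"docking table missing columns: {sorted(missing)}")
    if not np.isfinite(df["affinity"]).all():
        rows = (np.flatnonzero(~np.isfinite(df["affinity"])) + 2).tolist()
        raise ValidationError(f"non-finite affinity at rows {rows}")
    if (df["ligand_efficiency"] <= 0).any():
        rows = (np.flatnonzero(df["ligand_efficiency"] <= 0) + 2).tolist()
        raise ValidationError(f"non-positive ligand efficiency at rows {rows}")
    return df[["ligand_id", "affinity", "ligand_efficiency"]]
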