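"""The differential-interactome statistic.

Expression is binarized into an active/inactive state per gene and sample
(default rule: strictly above the gene's median over all samples, both
phenotypes pooled).  An interaction is *observed* in a sample when both
partner genes are active.  Per phenotype P the observation frequency of an
edge is

    f_P = (# samples of P where the edge is observed) / (# samples of P)

and the relative observation frequency of the tumor phenotype is

    q = f_T / (f_N + f_T),

undefined when the edge is never observed.  Edges with q below ``q_low``
are called repressed in tumor, above ``q_high`` activated in tumor, in
both cases requiring max(f_N, f_T) strictly above ``min_freq`` so that
calls rest on interactions actually observed in at least one phenotype.
Ties at the q thresholds are not called (strict inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PHENOTYPES

CALLS = ("repressed", "activated", "not_differential", "unobserved")

BINARIZATION_RULES = ("gene-median", "gene-mean", "absolute", "quantile")


@dataclass(frozen=True)
class DiffIntParams:
    """Thresholds of the dPPI caller and the binarization rule.

    Defaults follow the published criteria: q < 0.10 repressed, q > 0.90
    activated, and a normalized observation frequency in either phenotype
    above 20%.
    """

    q_low: float = 0.10
    q_high: float = 0.90
    min_freq: float = 0.20
    binarize_rule: str = "gene-median"
    binarize_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.q_low < self.q_high <= 1):
            raise ValueError("require 0 <= q_low < q_high <= 1")
        if not (0 <= self.min_freq <= 1):
            raise ValueError("min_freq must lie in [0, 1]")
        if self.binarize_rule not in BINARIZATION_RULES:
            raise ValueError(
                f"unknown binarization rule {self.binarize_rule!r}; "
                f"choose from {BINARIZATION_RULES}"
            )


@dataclass
class BinarizedMatrix:
    """Boolean activity matrix (genes x samples) with the thresholds used."""

    active: pd.DataFrame
    thresholds: pd.Series
    phenotype: pd.Series

    def samples_of(self, phenotype: str) -> list[str]:
        return list(self.phenotype.index[self.phenotype == phenotype])


def binarize(
    expr: ExpressionMatrix, rule: str = "gene-median", **options
) -> BinarizedMatrix:
    """Binarize expression into active states with a per-gene threshold.

    Thresholds are computed over ALL samples, both phenotypes pooled, so
    that the activity state is phenotype-agnostic.  A gene is active in a
    sample iff its value strictly exceeds the threshold; a constant gene is
    therefore never active.

    Rules: ``gene-median`` (default), ``gene-mean``, ``absolute``
    (option ``cutoff``), ``quantile`` (option ``q`` in [0, 1]).
    """
    if expr.values.shape[1] < 2:
        raise ValueError("binarization needs at least 2 pooled samples")
    v = expr.values
    if rule == "gene-median":
        thresholds = v.median(axis=1)
    elif rule == "gene-mean":
        thresholds = v.mean(axis=1)
    elif rule == "absolute":
        if "cutoff" not in options:
            raise ValueError("absolute rule requires a 'cutoff' option")
        thresholds = pd.Series(float(options["cutoff"]), index=v.index)
    elif rule == "quantile":
        if "q" not in options:
            raise ValueError("quantile rule requires a 'q' option")
        thresholds = v.quantile(float(options["q"]), axis=1)
    else:
        raise ValueError(f"unknown binarization rule {rule!r}; choose from {BINARIZATION_RULES}")
    active = v.gt(thresholds, axis=0)
    if not active.to_numpy().any():
        warnings.warn("binarization produced an all-inactive matrix", stacklevel=2)
    return BinarizedMatrix(active=active, thresholds=thresholds, phenotype=expr.phenotype)


def observation_frequencies(bin: BinarizedMatrix, net: nx.Graph) -> pd.DataFrame:
    """Per-edge observation frequency in each phenotype.

    Returns a DataFrame with columns ``protein_a``, ``protein_b``, ``f_N``,
    ``f_T``; an edge is observed in a sample iff both endpoints are active.
    """
    gene_pos = {g: i for i, g in enumerate(bin.active.index)}
    edges = [tuple(sorted(e)) for e in net.edges]
    for a, b in edges:
        if a not in gene_pos or b not in gene_pos:
            raise KeyError(f"edge ({a}, {b}) has an endpoint missing from the expression matrix")
    masks = {}
    for ph in PHENOTYPES:
        mask = (bin.phenotype == ph).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"no samples with phenotype {ph!r}")
        masks[ph] = mask
    A = bin.active.to_numpy()
    ia = np.array([gene_pos[a] for a, _ in edges], dtype=int)
    ib = np.array([gene_pos[b] for _, b in edges], dtype=int)
    if len(edges) == 0:
        return pd.DataFrame(columns=["protein_a", "protein_b", "f_N", "f_T"])
    co = A[ia] & A[ib]
    f_n = co[:, masks["normal"]].mean(axis=1)
    f_t = co[:, masks["tumor"]].mean(axis=1)
    out = pd.DataFrame(
        {
            "protein_a": [a for a, _ in edges],
            "protein_b": [b for _, b in edges],
            "f_N": f_n,
            "f_T": f_t,
        }
    )
    return out.sort_values(["protein_a", "protein_b"], ignore_index=True)


def q_value(f_N: float, f_T: float) -> float:
    """Relative observation frequency of the tumor phenotype, NaN if unobserved."""
    total = f_N + f_T
    if total == 0:
        return float("nan")
    return f_T / total


def call_dppis(freqs: pd.DataFrame, params: DiffIntParams | None = None) -> pd.DataFrame:
    """Annotate every edge with q and its call; see module docstring for the rule.

    Returns the full audit table (one row per edge, columns ``protein_a``,
    ``protein_b``, ``f_N``, ``f_T``, ``q``, ``call``).  The dPPI network is
    the subset with call in {repressed, activated}; use :func:`dppi_subset`.
    """
    params = params or DiffIntParams()
    out = freqs.copy()
    f_n = out["f_N"].to_numpy(dtype=float)
    f_t = out["f_T"].to_numpy(dtype=float)
    total = f_n + f_t
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(total > 0, f_t / np.where(total > 0, total, 1.0), np.nan)
    gate = np.maximum(f_n, f_t) > params.min_freq
    call = np.full(len(out), "not_differential", dtype=object)
    call[(q < params.q_low) & gate] = "repressed"
    call[(q > params.q_high) & gate] = "activated"
    call[total == 0] = "unobserved"
    out["q"] = q
    out["call"] = call
    return out


def dppi_subset(audit: pd.DataFrame) -> pd.DataFrame:
    """The dPPI network: edges called repressed or activated in tumor."""
    return audit[audit["call"].isin(["repressed", "activated"])].reset_index(drop=True)


@dataclass
class DifferentialInteractome:
    """Result of the full pipeline: the dPPI set plus the per-edge audit table."""

    dppis: pd.DataFrame
    audit: pd.DataFrame
    binarized: BinarizedMatrix
    params: DiffIntParams


def differential_interactome(
    expr: ExpressionMatrix, net: nx.Graph, params: DiffIntParams | None = None
) -> DifferentialInteractome:
    """Run binarize -> observation_frequencies -> call_dppis on one subtype.

    Deterministic for fixed inputs and parameters; comparison is always
    pairwise normal-vs-tumor within the given expression matrix.
    """
    params = params or DiffIntParams()
    if net.number_of_edges() == 0:
        raise ValueError("interaction network has no edges")
    bm = binarize(expr, params.binarize_rule, **params.binarize_options)
    freqs = observation_frequencies(bm, net)
    audit = call_dppis(freqs, params)
    return DifferentialInteractome(
        dppis=dppi_subset(audit), audit=audit, binarized=bm, params=params
    )
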