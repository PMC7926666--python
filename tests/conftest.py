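"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import statistics

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from diffint.io import ExpressionMatrix


def make_expression(values, genes, samples, labels) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples, dtype=float),
        phenotype=pd.Series(labels, index=samples),
    )


def random_instance(seed: int, n_genes: int = 20, n_samples: int = 12, n_edges: int = 30):
    """Random continuous expression matrix plus a random simple graph on its genes."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    n_normal = n_samples // 2
    labels = ["normal"] * n_normal + ["tumor"] * (n_samples - n_normal)
    expr = make_expression(rng.gamma(2.0, 5.0, (n_genes, n_samples)), genes, samples, labels)
    all_pairs = [(genes[i], genes[j]) for i in range(n_genes) for j in range(i + 1, n_genes)]
    chosen = rng.choice(len(all_pairs), size=min(n_edges, len(all_pairs)), replace=False)
    net = nx.Graph()
    net.add_nodes_from(genes)
    net.add_edges_from(all_pairs[i] for i in chosen)
    return expr, net


def brute_force_calls(
    expr: ExpressionMatrix,
    edges,
    q_low: float = 0.10,
    q_high: float = 0.90,
    min_freq: float = 0.20,
) -> dict:
    """Plain-Python double loop over samples and edges, median via statistics.

    Returns {sorted edge: (f_N, f_T, q, call)}; q is None when unobserved.
    Deliberately shares no code with the vectorized implementation.
    """
    medians = {
        g: statistics.median(float(x) for x in expr.values.loc[g]) for g in expr.gene_ids
    }
    out = {}
    for a, b in edges:
        counts = {"normal": 0, "tumor": 0}
        totals = {"normal": 0, "tumor": 0}
        for s in expr.sample_ids:
            ph = expr.phenotype[s]
            totals[ph] += 1
            a_on = float(expr.values.loc[a, s]) > medians[a]
            b_on = float(expr.values.loc[b, s]) > medians[b]
            if a_on and b_on:
                counts[ph] += 1
        f_n = counts["normal"] / totals["normal"]
        f_t = counts["tumor"] / totals["tumor"]
        if f_n + f_t == 0:
            q, call = None, "unobserved"
        else:
            q = f_t / (f_n + f_t)
            if q < q_low and max(f_n, f_t) > min_freq:
                call = "repressed"
            elif q > q_high and max(f_n, f_t) > min_freq:
                call = "activated"
            else:
                call = "not_differential"
        out[tuple(sorted((a, b)))] = (f_n, f_t, q, call)
    return out


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """4 genes x 6 samples, 3 normal / 3 tumor, hand-enterable values."""
    values = [
        [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
        [1.0, 1.0, 9.0, 9.0, 1.0, 9.0],
        [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
    ]
    return make_expression(
        values,
        ["gA", "gB", "gC", "gD"],
        [f"s{i}" for i in range(6)],
        ["normal"] * 3 + ["tumor"] * 3,
    )
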