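"""Synthetic inputs with the statistical structure the analysis assumes.

The generator produces every input the pipeline consumes: a scale-free
interaction network, a two-phenotype log-scale expression matrix with
planted differential co-activity, a clinical table whose hazards follow a
planted linear risk score, a sparse body-fluid abundance table, and a
docking-result table.

Signal is planted at the level of joint-activity probability — the very
quantity the observation-frequency statistic measures — so expected f_N,
f_T and q values of planted edges are analytically computable.  Each gene's
latent activity is a per-sample Bernoulli indicator; expression is drawn
log-normally around a low or high log-mean according to that state.
Background genes are active independently at rate sqrt(background joint
probability), so an unplanted edge is co-active at the background rate in
both phenotypes and its q sits near 1/2.  A planted tumor-activated pair is
jointly active in a tumor sample with the signal probability s and jointly
inactive otherwise, while in normal samples its endpoints are independently
active at rate 1 - s; a planted repressed pair is the mirror image.  This
keeps every planted gene's pooled activity rate near one half, which the
default gene-median binarization assumes, and gives planted edges expected
frequencies f_favored ~ s and f_other ~ (1 - s)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import FLUIDS, ExpressionMatrix, write_expression


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a desk-scale two-phenotype RNA-seq comparison: 70
    samples per phenotype, a 300-gene scale-free interactome with 500
    physical interactions, and 10 planted tumor-activated plus 10 planted
    tumor-repressed interactions.
    """

    n_genes: int = 300
    n_normal: int = 70
    n_tumor: int = 70
    n_edges: int = 500
    n_planted_activated: int = 10
    n_planted_repressed: int = 10
    co_activation_prob_signal: float = 0.9
    co_activation_prob_background: float = 0.25
    log_mu_inactive: float = 1.5
    log_mu_active: float = 3.5
    log_sigma: float = 0.25  # log-normal noise scale; well below the mode separation
    survival_beta: tuple[float, ...] = (1.0, -1.0, 0.0, 0.0)
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censoring_rate: float = 1.0 / 2000.0  # independent exponential censoring
    secretion_prob: float = 0.25  # per protein per fluid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_activated + self.n_planted_repressed > self.n_edges:
            raise ValueError("cannot plant more edges than the network has")
        for p in (self.co_activation_prob_signal, self.co_activation_prob_background):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def _rng(config: SynthConfig, seed: int | None, salt: int) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng([base, salt])


def gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_network(config: SynthConfig, seed: int | None = None) -> nx.Graph:
    """Preferential-attachment network over synthetic symbols G0001...

    Built from a Barabasi-Albert core, then adjusted to the exact requested
    edge count: surplus edges are removed at random, missing ones added with
    degree-weighted endpoint sampling so the heavy tail is preserved.
    Deterministic for a fixed (config, seed).
    """
    n, m_edges = config.n_genes, config.n_edges
    if n < 10:
        raise ValueError("need at least 10 genes")
    if not (1 <= m_edges <= n * (n - 1) // 2):
        raise ValueError(f"infeasible edge count {m_edges} for {n} nodes")
    rng = _rng(config, seed, salt=1)
    m = max(1, min(n - 1, round(m_edges / n)))
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    edges = list(g.edges)
    if len(edges) > m_edges:
        keep = rng.choice(len(edges), size=m_edges, replace=False)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges[i] for i in sorted(keep))
    while g.number_of_edges() < m_edges:
        deg = np.array([g.degree(i) + 1 for i in range(n)], dtype=float)
        p = deg / deg.sum()
        a, b = rng.choice(n, size=2, replace=False, p=p)
        if not g.has_edge(a, b):
            g.add_edge(a, b)
    return nx.relabel_nodes(g, {i: gene_name(i) for i in range(n)})


def generate_expression(
    config: SynthConfig, net: nx.Graph, seed: int | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression matrix with planted differential co-activity, plus truth table.

    Planted edges are chosen vertex-disjoint among the network's edges so
    each signal gene carries exactly one planted interaction.  The truth
    table records (protein_a, protein_b, planted_call).
    """
    rng = _rng(config, seed, salt=2)
    n_n, n_t = config.n_normal, config.n_tumor
    genes = sorted(net.nodes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes, n_samples = len(genes), n_n + n_t
    s = config.co_activation_prob_signal
    bg_rate = float(np.sqrt(config.co_activation_prob_background))

    # vertex-disjoint planted edges, greedily from a shuffled edge list
    n_planted = config.n_planted_activated + config.n_planted_repressed
    edges = sorted(tuple(sorted(e)) for e in net.edges)
    order = rng.permutation(len(edges))
    used: set[str] = set()
    planted: list[tuple[str, str]] = []
    for i in order:
        if len(planted) == n_planted:
            break
        a, b = edges[i]
        if a not in used and b not in used:
            planted.append((a, b))
            used.update((a, b))
    if len(planted) < n_planted:
        raise ValueError("network too dense/small for vertex-disjoint planted edges")

    Z = rng.random((n_genes, n_samples)) < bg_rate
    normal_cols = slice(0, n_n)
    tumor_cols = slice(n_n, n_samples)
    truth_rows = []
    # Each planted gene's pooled activity is topped up to exactly half the
    # samples: the gene-median threshold marks the top half of a gene's
    # values active, so this makes binarization an unbiased read-out of the
    # latent state and the planted edge's favored-phenotype frequency is
    # exactly Binomial(n_favored, s) / n_favored.
    half = n_samples // 2
    for k, (a, b) in enumerate(planted):
        call = "activated" if k < config.n_planted_activated else "repressed"
        ia, ib = gene_pos[a], gene_pos[b]
        fav = tumor_cols if call == "activated" else normal_cols
        oth = normal_cols if call == "activated" else tumor_cols
        n_oth = n_n if call == "activated" else n_t
        joint = rng.random(n_t if call == "activated" else n_n) < s
        n_fill = int(np.clip(half - joint.sum(), 0, n_oth))
        for ig in (ia, ib):
            Z[ig, fav] = joint
            other = np.zeros(n_oth, dtype=bool)
            other[rng.choice(n_oth, size=n_fill, replace=False)] = True
            Z[ig, oth] = other
        truth_rows.append({"protein_a": a, "protein_b": b, "planted_call": call})

    mu = config.log_mu_inactive + (config.log_mu_active - config.log_mu_inactive) * Z
    values = np.exp(rng.normal(mu, config.log_sigma))
    samples = [f"N{i + 1:04d}" for i in range(n_n)] + [f"T{i + 1:04d}" for i in range(n_t)]
    phenotype = pd.Series(["normal"] * n_n + ["tumor"] * n_t, index=samples)
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), phenotype=phenotype
    )
    truth = pd.DataFrame(truth_rows, columns=["protein_a", "protein_b", "planted_call"])
    return expr, truth


def edge_ground_truth(net: nx.Graph, truth: pd.DataFrame) -> pd.DataFrame:
    """Classify every network edge by its generative role.

    ``planted`` edges carry the differential signal directly.  ``flanking``
    edges share an endpoint with a planted edge: because that endpoint's
    activity is genuinely phenotype-dependent, their co-observation
    frequency shifts as a side effect of the planting, so they are neither
    recovery targets nor null edges.  ``background`` edges have identical
    generative law in both phenotypes and are the reference set for
    false-positive rates.
    """
    planted = {
        tuple(sorted((r.protein_a, r.protein_b))): r.planted_call
        for r in truth.itertuples(index=False)
    }
    planted_genes = {g for e in planted for g in e}
    rows = []
    for e in net.edges:
        a, b = sorted(e)
        if (a, b) in planted:
            role, call = "planted", planted[(a, b)]
        elif a in planted_genes or b in planted_genes:
            role, call = "flanking", ""
        else:
            role, call = "background", ""
        rows.append({"protein_a": a, "protein_b": b, "role": role, "planted_call": call})
    return pd.DataFrame(rows).sort_values(
        ["protein_a", "protein_b"], ignore_index=True
    )


def generate_clinical(
    config: SynthConfig,
    expr: ExpressionMatrix,
    panel: list[str],
    seed: int | None = None,
    beta: np.ndarray | None = None,
) -> pd.DataFrame:
    """Clinical table for the tumor samples with a planted linear risk score.

    The hazard of patient j is baseline * exp(beta . x_j) where x_j are the
    z-scored log expression values of the panel genes.  Event times are
    exponential with that hazard; censoring is independent exponential at
    the configured rate.
    """
    rng = _rng(config, seed, salt=3)
    beta = np.asarray(config.survival_beta if beta is None else beta, dtype=float)
    if len(panel) != len(beta):
        raise ValueError(f"panel has {len(panel)} genes but beta has {len(beta)}")
    missing = [g for g in panel if g not in expr.values.index]
    if missing:
        raise ValueError(f"panel genes missing from expression: {missing}")
    tumor = expr.samples_of("tumor")
    X = np.log(expr.values.loc[panel, tumor].to_numpy() + 1.0).T
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    hazard = config.baseline_hazard * np.exp(X @ beta)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, size=len(tumor))
    else:
        t_cens = np.full(len(tumor), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=pd.Index(tumor, name="patient"))


def risk_covariates(expr: ExpressionMatrix, panel: list[str]) -> pd.DataFrame:
    """The samples x genes covariate matrix used by the clinical generator."""
    tumor = expr.samples_of("tumor")
    X = np.log(expr.values.loc[panel, tumor].to_numpy() + 1.0).T
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    return pd.DataFrame(X, index=tumor, columns=panel)


def generate_secretion(
    config: SynthConfig, proteins: list[str], seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Sparse fluid-abundance table (ppm) plus the truth flag per protein.

    Each protein is detectable in each fluid independently with the
    configured probability; detected abundances are log-uniform between
    0.1 and 1000 ppm, undetected cells are missing.
    """
    rng = _rng(config, seed, salt=4)
    detected = rng.random((len(proteins), len(FLUIDS))) < config.secretion_prob
    ppm = 10.0 ** rng.uniform(-1, 3, size=detected.shape)
    table = pd.DataFrame(
        np.where(detected, ppm, np.nan), index=pd.Index(proteins, name="protein"), columns=FLUIDS
    )
    truth = pd.Series(detected.any(axis=1), index=table.index, name="secreted")
    return table, truth


def generate_docking(
    config: SynthConfig, n_ligands: int = 50, seed: int | None = None
) -> pd.DataFrame:
    """Docking-result table with uniformly scattered affinities and efficiencies."""
    rng = _rng(config, seed, salt=5)
    return pd.DataFrame(
        {
            "ligand_id": [f"ZINCSYN{i + 1:05d}" for i in range(n_ligands)],
            "affinity": np.round(rng.uniform(-14.0, -8.0, n_ligands), 1),
            "ligand_efficiency": np.round(rng.uniform(0.25, 0.50, n_ligands), 2),
        }
    )


def write_synthetic_dataset(
    outdir: str | Path, config: SynthConfig, seed: int | None = None
) -> dict[str, Path]:
    """Generate one full synthetic study and write every pipeline input file.

    Writes expression.tsv + phenotype.tsv, network.tab (BioGRID-style TAB),
    clinical.tsv, secretion.tsv, docking.tsv and the planted-edge truth
    table; returns the path of each file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = generate_network(config, seed)
    expr, truth = generate_expression(config, net, seed)
    panel = sorted(net.nodes)[: len(config.survival_beta)]
    clinical = generate_clinical(config, expr, panel, seed)
    secretion, _ = generate_secretion(config, sorted(net.nodes), seed)
    docking = generate_docking(config, seed=seed)

    paths = {k: outdir / f"{k}.tsv" for k in ("phenotype", "clinical", "secretion", "docking", "truth")}
    paths["expression"] = outdir / "expression.tsv"
    paths["network"] = outdir / "network.tab"
    write_expression(expr, paths["expression"], paths["phenotype"])
    rows = [
        {
            "Official Symbol Interactor A": a,
            "Official Symbol Interactor B": b,
            "Experimental System Type": "physical",
            "Organism ID Interactor A": 9606,
            "Organism ID Interactor B": 9606,
        }
        for a, b in sorted(map(sorted, net.edges))
    ]
    pd.DataFrame(rows).to_csv(paths["network"], sep="\t", index=False)
    clinical.to_csv(paths["clinical"], sep="\t")
    secretion.to_csv(paths["secretion"], sep="\t")
    docking.to_csv(paths["docking"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
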