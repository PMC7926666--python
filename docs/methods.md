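# Methods

## The differential-interactome statistic

The pipeline asks, per physical protein interaction, whether the two
partner genes are *jointly expressed* in a different fraction of samples in
the tumor phenotype than in the normal phenotype.

**Binarization.** A gene is active in a sample when its expression strictly
exceeds a per-gene threshold computed over all samples, both phenotypes
pooled (so the activity state carries no phenotype information by
construction). The default threshold is the gene's median; alternatives
(`gene-mean`, a fixed `absolute` cutoff, an arbitrary per-gene `quantile`)
are selectable because the binarization rule is a modelling choice, not
part of the statistic. With the median rule and continuous data a gene is
active in exactly half the samples; a constant gene is never active (strict
inequality). Missing expression values are rejected outright — the
statistic has no missing-data rule, and silently imputing would bias the
observation counts.

**Frequencies and the q-value.** An edge is observed in a sample when both
endpoints are active; `f_P` is the fraction of phenotype-`P` samples where
it is observed, and

    q = f_T / (f_N + f_T)

is the tumor phenotype's share of the total observation frequency: q = 0
means the interaction is seen only in normal tissue, q = 1 only in tumor,
q = 1/2 equally in both. When f_N = f_T = 0 the edge is *unobserved* and q
is undefined (NaN), never coerced to a number. Calls use strict
inequalities: repressed when q < 0.10, activated when q > 0.90, both gated
on max(f_N, f_T) > 0.20 so that calls rest on interactions observed in at
least a fifth of one phenotype's samples; values exactly at a threshold are
not called. The gate applies to either phenotype's frequency (not only the
dominant one) — an interaction present in 25% of normal samples and absent
from tumor is exactly the kind of repression the method should report.

Two structural properties follow and are enforced by tests: swapping the
phenotype labels maps q to 1 − q and exchanges the activated and repressed
call sets exactly; and permuting samples or edges changes nothing. No
multiple-testing correction is applied: q is a descriptive relative
frequency, not a tail probability.

## DIPs, panels and secretion

A protein incident to at least `min_degree` dPPIs (default 1) is a DIP.
The two natural classes — all incident edges activated, or all repressed —
do not exhaust the possibilities, so a protein with both edge types is
reported as `mixed` rather than forced into either class. Across subtypes,
a DIP is *subtype-specific* (appears in exactly one subtype),
*common* (in all), or *shared-partial* (the remainder); the three
categories partition the union by construction. Degree rankings break ties
lexicographically on the symbol so exports are deterministic. A DIP is an
s-DIP when a secretion table reports abundance > 0 ppm in at least one of
serum, plasma, saliva, urine; proteins absent from the table are treated as
not secreted, the conservative choice for a fluid-based diagnostic panel.

## Survival machinery

`fit_cox` wraps a standard Cox proportional-hazards fit (lifelines, Efron
tie handling); the prognostic index is the model's linear predictor
PI = Σ βᵢxᵢ with no additional standardization beyond what the caller
applied to the covariates. Patients split at the median PI, ties going to
the low-risk group; an all-ties PI is a degenerate input and an error, not
a silent 100/0 split. The log-rank table uses the hypergeometric expected
counts (at each event time, group 1 expects deaths in proportion to its
share of the risk set); the test statistic is the classical approximation
χ² = (O₁−E₁)²/E₁ + (O₂−E₂)²/E₂ with 1 df — slightly conservative relative
to the variance-based statistic, and the form that matches the reported
hazard ratio

    HR = (O1/E1) / (O2/E2),

whose group 1 is fixed as the high-risk group. By construction
E₁ + E₂ = O₁ + O₂, HR inverts exactly under group relabeling, and HR is
reported as undefined when either group has no observed or expected deaths.
Kaplan–Meier curves come from the product-limit estimator and are checked
against hand-computed values on small instances.

PCA diagnostics z-scores each panel gene across the included samples (the
genes are on arbitrary expression scales), drops constant genes with a
warning, and reports the mean silhouette of the first two components under
the subtype labels as a scalar separation summary.

## Target selection and hit filtering

A candidate drug target is an activated-class DIP with at least 5
differential interactions (all incident dPPIs counted by default; a switch
restricts the count to activated ones, since either reading of "at least 5
interactions" is defensible). The docking filter keeps ligands with
binding free energy ≤ −12 kcal/mol (inclusive, as printed) and ligand
efficiency > 0.35 (exclusive); both cutoffs are monotone, so loosening
either never removes a hit.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
RNA-seq realism. Defaults: 300 genes, 500 interactions, 70 normal + 70
tumor samples, 10 planted tumor-activated and 10 tumor-repressed edges,
signal joint-activity probability 0.9, background joint-activity 0.25,
log-normal expression with log-means 1.5 (inactive) and 3.5 (active) and
σ = 0.25.

**Network.** Preferential attachment (Barabási–Albert core, adjusted to
the exact requested edge count with degree-weighted extra edges), matching
the heavy-tailed degree structure that makes hub DIPs meaningful.

**Expression.** Every gene has a latent per-sample activity indicator;
expression is drawn log-normally around a low or high log-mean according to
that state. Background genes are independently active at rate
√0.25 = 0.5, so background edges are co-active at rate 0.25 in both
phenotypes and their q concentrates near 1/2. A planted tumor-activated
pair is jointly active in each tumor sample with probability s = 0.9 and
jointly inactive otherwise; in normal samples each endpoint's activity is
an independent uniform subset sized to top the gene's pooled activity up to
exactly half the samples. Two properties were designed in deliberately:
the gene-median threshold marks exactly the top half of a gene's values, so
topping up to half makes binarization an unbiased read-out of the latent
state, and the favored-phenotype frequency of a planted edge is then
exactly Binomial(70, 0.9)/70; and the noise scale σ = 0.25 against a 2.0
log-mean separation keeps ranking errors at the activity boundary
negligible, so the planted probabilities — not the noise model — are the
ground truth the statistic sees. Expected planted-edge values:
f_favored ≈ 0.9, f_other ≈ 0.01, q ≈ 0.99 (activated) / 0.01 (repressed).

**What "background" means.** Planted edges are chosen vertex-disjoint, but
a planted gene usually has further network neighbors. Edges from a planted
gene to a background gene inherit a genuine frequency shift
(f_T ≈ 0.45 vs f_N ≈ 0.05 for an activated endpoint — their q sits at
0.9 in expectation) because the shared endpoint's activity really is
phenotype-dependent; this is unavoidable for any generator whose planted
genes have differential marginals. `edge_ground_truth` therefore classifies
edges as `planted`, `flanking` (sharing an endpoint with a planted edge;
differential as a side effect, neither a recovery target nor a null edge)
or `background` (generative law identical in both phenotypes). Recovery is
measured on planted edges, the false-positive rate on background edges; a
separate pure-null configuration (no planted edges at all) checks the
caller's false-positive behavior on a fully null network.

**Clinical.** For tumor samples, hazard = baseline · exp(β·x) with x the
z-scored log expression of a chosen panel (default planted
β = (1, −1, 0, 0), baseline 10⁻³ events/day); event times are exponential
with that hazard, censoring is independent exponential at 5 × 10⁻⁴/day
(roughly a third of patients censored). `risk_covariates` exposes exactly
the covariate matrix the generator used, so Cox recovery tests compare like
with like.

**Secretion and docking.** Each protein is detectable in each fluid
independently with probability 0.25; detected abundances are log-uniform on
[0.1, 1000] ppm. Docking tables scatter affinities uniformly on
[−14, −8] kcal/mol and efficiencies on [0.25, 0.50].

All generators are bit-reproducible given (config, seed); sub-streams are
salted per generator so adding one stage never shifts another's draws.

**What passing tests do not show.** The generator plants signal as clean
joint-activity shifts on a noiseless scale-free graph; real RNA-seq has
library-size and batch effects, count noise, correlated co-expression
modules and annotation mismatches between network and transcriptome, none
of which are modelled. Recovery rates here validate the statistic's
implementation, not its power on real cohorts.

## Problem sizes and numerical choices

Simulation-backed tests use the generator defaults (300 genes × 140
samples, 500 edges) with 20-replicate aggregates for recovery rates, 100
replicates for distribution-level checks, and n = 300 cohorts for Cox
recovery — sizes at which the targeted effects are comfortably resolvable
and the whole suite stays interactive. Brute-force oracles (plain Python
double loops, `statistics.median`) are kept to ≤ 100 edges × 40 samples.
Threshold comparisons are strict and unfuzzed; q is NaN (not 0 or 0.5)
for unobserved edges; degenerate inputs (empty networks, one-phenotype
cohorts, zero-event clinical tables, constant prognostic indices) raise
errors rather than propagating silent defaults.

## Known limitations

The binarization rule and the exact q formula are reconstructions of a
published method whose primitive definitions are stated elsewhere; both are
configurable for that reason. Published cohort-scale headline numbers
(e.g., hazard ratios from TCGA cohorts) depend on external datasets and
web-tool curation and are out of scope; the bundled reference tables cover
the printed panel lists and the docking screen only. The log-rank p-value
uses the (O−E)²/E approximation, which is conservative for very unbalanced
risk sets.
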