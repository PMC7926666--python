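# diffint

Differential protein-interactome analysis for two-phenotype (normal vs
tumor) transcriptome studies, with downstream biomarker-panel evaluation.
The package was built around the renal cell carcinoma setting — three
subtypes (clear cell, papillary, chromophobe), TCGA-style expression,
BioGRID physical interactions — but every stage is generic.

## What it computes

Tumors perturb coordinated protein groups rather than single genes, so the
unit of analysis here is the **interaction**, not the gene. Given gene
expression for both phenotypes and a physical protein–protein interaction
(PPI) network:

1. **Binarization.** Each gene is *active* in a sample when its expression
   strictly exceeds the gene's median over all samples (both phenotypes
   pooled). An interaction is *observed* in a sample when both partners are
   active.
2. **Observation frequencies.** For each edge and phenotype *P*,
   *f<sub>P</sub>* = (# samples of *P* where the edge is observed) / (#
   samples of *P*).
3. **Relative observation frequency (q).**
   *q* = *f<sub>T</sub>* / (*f<sub>N</sub>* + *f<sub>T</sub>*). An edge is a
   **differential PPI (dPPI)**: *repressed* in tumor when *q* < 0.10,
   *activated* when *q* > 0.90, in both cases requiring
   max(*f<sub>N</sub>*, *f<sub>T</sub>*) > 20%.
4. **DIPs.** Proteins incident to dPPIs are **differentially interacting
   proteins**; they are classified (activated / repressed / mixed), compared
   across subtypes (subtype-specific / common / shared-partial), ranked by
   degree, and filtered for detectability in serum, plasma, saliva or urine
   (**s-DIPs**) — panels accessible without surgery.
5. **Evaluation.** Diagnostic: PCA of tumor samples on an s-DIP panel with a
   silhouette separation score. Prognostic: Cox proportional hazards on the
   panel, prognostic index PI = Σ β<sub>i</sub>x<sub>i</sub>, median-PI
   split into high/low risk, Kaplan–Meier curves, log-rank test and hazard
   ratio HR = (O₁/E₁)/(O₂/E₂).
6. **Therapeutics.** Candidate drug targets are activated DIPs with ≥ 5
   differential interactions; virtual-screening tables are filtered for
   strong efficient binders (ΔG⁰ ≤ −12 kcal/mol, ligand efficiency > 0.35).

Two small published reference tables ship with the package (subtype DIP
panels with their body-fluid status; the MET docking screen) plus a
synthetic-data module that generates every pipeline input with planted,
analytically tractable signal.

## Worked example

```python
from diffint import synth, core, dips, survdiag

cfg = synth.SynthConfig()            # 70 + 70 samples, 300 genes, 500 PPIs,
net = synth.generate_network(cfg, seed=7)      # 10 + 10 planted dPPIs
expr, truth = synth.generate_expression(cfg, net, seed=7)

res = core.differential_interactome(expr, net)
print(len(res.dppis), res.dppis["call"].value_counts().to_dict())
# 96 {'activated': 59, 'repressed': 37}

dip_table = dips.extract_dips(res.dppis)
panel = sorted(net.nodes)[:4]
clin = synth.generate_clinical(cfg, expr, panel, seed=7)
X = synth.risk_covariates(expr, panel)
beta = survdiag.fit_cox(X, clin)
fit = survdiag.stratify_and_test(survdiag.prognostic_index(X, beta), clin)
print(round(fit.hr, 2), f"{fit.logrank_p:.2e}")
# 4.21 2.80e-06
```

The 96 dPPIs include all 20 planted edges with the correct direction; the
rest sit on edges that share an endpoint with a planted edge and genuinely
shift with it (see `docs/methods.md`). The hazard ratio 4.21 with log-rank
p = 2.8 × 10⁻⁶ says the median split on the fitted prognostic index
separates the synthetic cohort's survival about as sharply as the planted
risk score allows.

The same pipeline is available from the shell:

```sh
diffint synth --seed 3 --out data/
diffint run --expr data/expression.tsv --pheno data/phenotype.tsv \
            --net data/network.tab --out run/
diffint dips --dppis run/dppis.tsv --secretion data/secretion.tsv --out dips.tsv
diffint prognose --expr data/expression.tsv --clinical data/clinical.tsv \
                 --panel panel.txt --out prog/
```

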