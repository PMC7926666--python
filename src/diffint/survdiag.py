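"""Diagnostic and prognostic evaluation of biomarker panels.

Diagnostics: PCA on the tumor-sample expression of a panel (per-gene
z-scored), with a mean silhouette score over the first two components as an
auxiliary separation measure.

Prognostics: a Cox proportional-hazards fit on the panel yields per-patient
prognostic indices PI = sum_i beta_i * x_i (the linear predictor).  Patients
split at the median PI into high- and low-risk groups (ties to low risk);
survival in each group is summarized by Kaplan-Meier curves and the two
groups are compared with a log-rank test.  The hazard ratio is the ratio of
relative death rates, HR = (O1/E1) / (O2/E2), with group 1 the high-risk
group, O the observed and E the log-rank expected number of deaths.  The
log-rank p-value uses the chi-square approximation sum (O-E)^2 / E with one
degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x components
    labels: pd.Series
    silhouette: float | None


def pca_diagnostics(
    expr_tumor: pd.DataFrame,
    panel: list[str] | set[str],
    labels: pd.Series,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of tumor samples restricted to a panel of genes.

    ``expr_tumor`` is genes x samples; ``labels`` assigns each sample its
    subtype.  Genes are z-scored across samples before decomposition;
    constant genes are dropped with a warning.  When at least two label
    classes are present, the mean silhouette on the first two components is
    reported.
    """
    genes = [g for g in sorted(set(panel)) if g in expr_tumor.index]
    if not genes:
        raise ValueError("panel has no overlap with the expression matrix")
    if expr_tumor.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = expr_tumor.loc[genes]
    sd = X.std(axis=1, ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        warnings.warn(f"dropping constant genes from panel: {constant}", stacklevel=2)
        X = X.drop(index=constant)
        if X.empty:
            raise ValueError("all panel genes are constant")
    Z = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=0), axis=0)
    mat = Z.to_numpy().T  # samples x genes
    k = n_components or min(mat.shape)
    k = min(k, *mat.shape)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(mat)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    labels = labels.reindex(expr_tumor.columns)
    sil = None
    if scores.shape[1] >= 2 and labels.nunique() >= 2 and labels.value_counts().min() >= 2:
        sil = float(silhouette_score(scores[:, :2], labels.to_numpy()))
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr_tumor.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(pca.components_.T, index=Z.index, columns=comp_names),
        labels=labels,
        silhouette=sil,
    )


def fit_cox(
    expr_panel: pd.DataFrame, clinical: pd.DataFrame, tie_method: str = "Efron"
) -> pd.Series:
    """Cox proportional-hazards coefficients for panel genes.

    ``expr_panel`` is samples x genes (covariates), aligned on the clinical
    index (columns ``time``, ``event``).  Returns the fitted beta vector.
    """
    common = clinical.index.intersection(expr_panel.index)
    if len(common) == 0:
        raise ValueError("no overlap between expression samples and clinical table")
    clin = clinical.loc[common]
    if int(clin["event"].sum()) == 0:
        raise ValueError("Cox fit needs at least one observed event")
    df = expr_panel.loc[common].copy()
    df["time"] = clin["time"]
    df["event"] = clin["event"]
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = cph.params_.copy()
    beta.attrs["tie_method"] = tie_method
    return beta


def prognostic_index(expr_panel: pd.DataFrame, beta: pd.Series) -> pd.Series:
    """PI = sum_i beta_i x_i per patient; ``expr_panel`` is samples x genes."""
    missing = [g for g in beta.index if g not in expr_panel.columns]
    if missing:
        raise ValueError(f"coefficients without matching panel genes: {missing}")
    values = expr_panel[list(beta.index)].to_numpy() @ beta.to_numpy()
    return pd.Series(values, index=expr_panel.index, name="pi")


def logrank_oe(
    time: np.ndarray, event: np.ndarray, group1: np.ndarray
) -> tuple[float, float, float, float, float, float]:
    """Two-group log-rank observed/expected table.

    ``group1`` is a boolean mask.  Expected deaths per group come from the
    hypergeometric formulation: at each event time, E1 gains d * n1/n where
    d deaths occur among n at risk, n1 of them in group 1.  Returns
    (O1, E1, O2, E2, chi2, p) with chi2 = (O1-E1)^2/E1 + (O2-E2)^2/E2 and p
    from a 1-df chi-square.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group1 = np.asarray(group1, dtype=bool)
    o1 = float(event[group1].sum())
    o2 = float(event[~group1].sum())
    e1 = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group1).sum()
        d = int(event[time == t].sum())
        e1 += d * n1 / n
    e2 = (o1 + o2) - e1
    if e1 > 0 and e2 > 0:
        chi2 = (o1 - e1) ** 2 / e1 + (o2 - e2) ** 2 / e2
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = float("nan"), float("nan")
    return o1, e1, o2, e2, chi2, p


@dataclass
class SurvivalFit:
    """Risk stratification of a cohort with its survival comparison."""

    pi: pd.Series
    risk_group: pd.Series  # "high" / "low"
    km: dict  # group -> DataFrame(time, survival)
    O1: float
    E1: float
    O2: float
    E2: float
    chi2: float
    logrank_p: float
    hr: float | None
    significant: bool
    cut: float


def stratify_and_test(
    pi: pd.Series, clinical: pd.DataFrame, alpha: float = 0.05
) -> SurvivalFit:
    """Median-PI split into high/low risk, KM curves, log-rank test and HR.

    Patients with PI strictly above the median are high risk; ties go to the
    low-risk group.  HR = (O1/E1)/(O2/E2) with group 1 = high risk; it is
    None when either group has no observed or expected deaths.
    """
    common = clinical.index.intersection(pi.index)
    if len(common) < len(clinical):
        missing = clinical.index.difference(pi.index).tolist()
        raise ValueError(f"patients without a prognostic index: {missing}")
    pi = pi.loc[clinical.index]
    cut = float(pi.median())
    high = pi > cut
    if high.all() or (~high).all():
        raise ValueError("degenerate prognostic index: one risk group is empty")
    time = clinical["time"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)
    o1, e1, o2, e2, chi2, p = logrank_oe(time, event, high.to_numpy())
    hr = None
    if o1 > 0 and o2 > 0 and e1 > 0 and e2 > 0:
        hr = (o1 / e1) / (o2 / e2)
    km = {}
    for name, mask in (("high", high.to_numpy()), ("low", (~high).to_numpy())):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        km[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return SurvivalFit(
        pi=pi,
        risk_group=pd.Series(np.where(high, "high", "low"), index=pi.index),
        km=km,
        O1=o1,
        E1=e1,
        O2=o2,
        E2=e2,
        chi2=chi2,
        logrank_p=p,
        hr=hr,
        significant=bool(p < alpha) if np.isfinite(p) else False,
        cut=cut,
    )


def plot_km(fit: SurvivalFit, path: str) -> None:
    """Step plot of the two Kaplan-Meier curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in fit.km.items():
        ax.step(curve["time"], curve["survival"], where="post", label=f"{name} risk")
    hr = f"{fit.hr:.2f}" if fit.hr is not None else "NA"
    ax.set_xlabel("time (days)")
    ax.set_ylabel("S(t)")
    ax.set_title(f"HR = {hr}, log-rank p = {fit.logrank_p:.2g}")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca(res: PCAResult, path: str) -> None:
    """Scatter of the first two principal components colored by label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in res.labels.dropna().unique():
        mask = (res.labels == lab).to_numpy()
        ax.scatter(res.scores.iloc[mask, 0], res.scores.iloc[mask, 1], s=12, label=str(lab))
    evr = res.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
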