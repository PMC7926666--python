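"""Differentially interacting proteins (DIPs) and biomarker panel construction.

A DIP is a protein incident to differential interactions — a hub of the
differential network.  DIPs are classified by the direction of their edges
(activated / repressed in tumor, or mixed when both occur), compared across
subtypes into specificity sets, ranked by degree, and filtered for secretion
in body fluids (serum, plasma, saliva, urine) to give s-DIP panels usable
for non-invasive diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import FLUIDS

DIP_CLASSES = ("activated", "repressed", "mixed")
DIP_COLUMNS = ["protein", "degree", "n_activated", "n_repressed", "dip_class"]


def classify_dip(n_activated: int, n_repressed: int) -> str:
    """activated iff no repressed edges, repressed iff no activated, else mixed."""
    if n_activated + n_repressed == 0:
        raise ValueError("a DIP must have at least one differential interaction")
    if n_repressed == 0:
        return "activated"
    if n_activated == 0:
        return "repressed"
    return "mixed"


def extract_dips(dppis: pd.DataFrame, min_degree: int = 1) -> pd.DataFrame:
    """Tabulate per-protein dPPI incidence and keep proteins with degree >= min_degree.

    ``dppis`` is a dPPI table (columns protein_a, protein_b, call with values
    activated/repressed).  Returns a DataFrame with one row per DIP:
    protein, degree, n_activated, n_repressed, dip_class, sorted by degree
    descending then symbol.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    counts: dict[str, list[int]] = {}
    for row in dppis.itertuples(index=False):
        k = 0 if row.call == "activated" else 1
        if row.call not in ("activated", "repressed"):
            raise ValueError(f"unexpected call {row.call!r} in dPPI table")
        for p in (row.protein_a, row.protein_b):
            counts.setdefault(p, [0, 0])[k] += 1
    records = []
    for protein, (n_act, n_rep) in counts.items():
        degree = n_act + n_rep
        if degree >= min_degree:
            records.append(
                {
                    "protein": protein,
                    "degree": degree,
                    "n_activated": n_act,
                    "n_repressed": n_rep,
                    "dip_class": classify_dip(n_act, n_rep),
                }
            )
    out = pd.DataFrame(records, columns=DIP_COLUMNS)
    return out.sort_values(
        ["degree", "protein"], ascending=[False, True], ignore_index=True
    )


@dataclass
class SpecificityResult:
    """Partition of the union of subtype DIP sets into specific / common / shared-partial."""

    specific: dict[str, set[str]]
    common: set[str]
    shared_partial: set[str]

    def table(self) -> pd.DataFrame:
        rows = []
        for subtype, prots in self.specific.items():
            rows += [{"protein": p, "specificity": f"{subtype}-specific"} for p in sorted(prots)]
        rows += [{"protein": p, "specificity": "common"} for p in sorted(self.common)]
        rows += [{"protein": p, "specificity": "shared-partial"} for p in sorted(self.shared_partial)]
        return pd.DataFrame(rows, columns=["protein", "specificity"])


def specificity_sets(dip_sets: Mapping[str, Iterable[str]]) -> SpecificityResult:
    """Split DIPs by how many subtypes they appear in.

    specific(s): DIPs of subtype s present in no other subtype; common: DIPs
    present in every subtype; shared-partial: the rest.  The three categories
    partition the union of all sets.
    """
    sets = {k: set(v) for k, v in dip_sets.items()}
    if len(sets) < 2:
        raise ValueError("specificity needs at least 2 subtypes")
    union = set().union(*sets.values())
    common = set.intersection(*sets.values())
    specific = {
        s: sets[s] - set().union(*(sets[t] for t in sets if t != s)) for s in sets
    }
    assigned = common | set().union(*specific.values())
    return SpecificityResult(
        specific=specific, common=common, shared_partial=union - assigned
    )


def top_k_by_degree(dips: pd.DataFrame, k: int) -> pd.DataFrame:
    """First k DIPs by degree descending, ties broken by symbol ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = dips.sort_values(
        ["degree", "protein"], ascending=[False, True], ignore_index=True
    )
    return ordered.head(k)


def is_secreted(protein: str, secretion: pd.DataFrame) -> bool:
    """True iff the secretion table reports abundance > 0 in at least one fluid."""
    if protein not in secretion.index:
        return False
    row = secretion.loc[protein, [c for c in FLUIDS if c in secretion.columns]]
    return bool((row.fillna(0) > 0).any())


def filter_sdips(
    dips: pd.DataFrame | Iterable[str], secretion: pd.DataFrame
) -> tuple[set[str], set[str]]:
    """Split DIPs into secreted (s-DIPs) and non-secreted.

    A protein is an s-DIP iff it is detectable (ppm > 0) in at least one of
    serum, plasma, saliva or urine; proteins absent from the secretion table
    count as not secreted.
    """
    proteins = list(dips["protein"]) if isinstance(dips, pd.DataFrame) else list(dips)
    sdips = {p for p in proteins if is_secreted(p, secretion)}
    return sdips, set(proteins) - sdips


def annotate_dips(
    dips: pd.DataFrame,
    specificity: SpecificityResult | None = None,
    subtype: str | None = None,
    secretion: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Add specificity and secretion columns to a DIP table for export."""
    out = dips.copy()
    if specificity is not None:
        def spec_of(p: str) -> str:
            if p in specificity.common:
                return "common"
            if subtype is not None and p in specificity.specific.get(subtype, ()):
                return "subtype-specific"
            for s, prots in specificity.specific.items():
                if p in prots:
                    return "subtype-specific"
            return "shared-partial"

        out["specificity"] = [spec_of(p) for p in out["protein"]]
    if secretion is not None:
        out["secreted"] = [is_secreted(p, secretion) for p in out["protein"]]
        for fluid in FLUIDS:
            if fluid in secretion.columns:
                out[fluid] = [
                    secretion.loc[p, fluid] if p in secretion.index else float("nan")
                    for p in out["protein"]
                ]
    return out
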