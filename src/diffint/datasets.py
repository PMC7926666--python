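"""Bundled reference tables.

Two small published tables ship with the package: the subtype-specific DIP
panels for the three renal cell carcinoma subtypes (clear cell, papillary,
chromophobe), each protein flagged by whether its expression was observed
in at least one body fluid (serum, plasma, saliva, urine); and the
virtual-screening results for the MET receptor tyrosine kinase, listing
ZINC15 ligands with their Vina binding affinity (kcal/mol) and ligand
efficiency.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

SUBTYPES = ("ccRCC", "pRCC", "chRCC")


def _read(name: str) -> pd.DataFrame:
    with resources.files("diffint.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_dip_panels() -> pd.DataFrame:
    """Subtype-specific DIP panels: columns subtype, protein, secreted (0/1)."""
    return _read("rcc_subtype_dip_panels.tsv")


def load_panel(subtype: str, secreted_only: bool = False) -> list[str]:
    """Protein symbols of one subtype's panel, optionally only the s-DIPs."""
    df = load_dip_panels()
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}; choose from {SUBTYPES}")
    df = df[df["subtype"] == subtype]
    if secreted_only:
        df = df[df["secreted"] == 1]
    return df["protein"].tolist()


def load_met_docking() -> pd.DataFrame:
    """MET virtual-screening table: ligand_id, affinity, ligand_efficiency."""
    return _read("met_docking_results.tsv")
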