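"""Drug-target selection among DIPs and the virtual-screening hit filter.

A candidate drug target is a DIP whose interactions are activated in the
disease state and that has at least five differential interactions — the
rationale being that breaking interactions gained in tumor may revert the
disease phenotype.  Docking results (e.g., AutoDock Vina output exported as
a table) are filtered for strong, efficient binders: binding free energy
dG0 at or below -12 kcal/mol and ligand efficiency strictly above 0.35.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class TargetCriteria:
    """Selection rule for candidate targets among DIPs."""

    require_activated: bool = True
    min_interactions: int = 5
    #: count only activated dPPIs toward min_interactions instead of all
    count_activated_only: bool = False

    def __post_init__(self) -> None:
        if self.min_interactions < 1:
            raise ValueError("min_interactions must be >= 1")


def select_targets(dips: pd.DataFrame, criteria: TargetCriteria | None = None) -> pd.DataFrame:
    """DIPs passing the target criteria, sorted by degree descending then symbol.

    ``dips`` is a DIP table (columns protein, degree, n_activated,
    n_repressed, dip_class).
    """
    criteria = criteria or TargetCriteria()
    out = dips.copy()
    if criteria.require_activated:
        out = out[out["dip_class"] == "activated"]
    counted = out["n_activated"] if criteria.count_activated_only else out["degree"]
    out = out[counted >= criteria.min_interactions]
    return out.sort_values(
        ["degree", "protein"], ascending=[False, True], ignore_index=True
    )


@dataclass(frozen=True)
class HitFilter:
    """Cutoffs for virtual-screening hits: dG0 <= max_affinity, LE > min_le."""

    max_affinity: float = -12.0  # kcal/mol, inclusive
    min_le: float = 0.35  # per-heavy-atom, exclusive

    def __post_init__(self) -> None:
        if self.max_affinity >= 0:
            raise ValueError("max_affinity must be negative (favorable binding)")


def filter_hits(docking: pd.DataFrame, hit_filter: HitFilter | None = None) -> pd.DataFrame:
    """Rows with affinity <= max_affinity and ligand_efficiency > min_le.

    Sorted by affinity ascending (strongest binder first), then ligand
    efficiency descending, then ligand id.
    """
    f = hit_filter or HitFilter()
    keep = docking[
        (docking["affinity"] <= f.max_affinity) & (docking["ligand_efficiency"] > f.min_le)
    ]
    return keep.sort_values(
        ["affinity", "ligand_efficiency", "ligand_id"],
        ascending=[True, False, True],
        ignore_index=True,
    )
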