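"""Legume gene clade enumeration.

A legume gene clade is operationalised on the rooted tree's left-to-right
leaf listing: a maximal run of legume-species leaves, where in *permissive*
mode a single non-legume leaf flanked on both sides by legume leaves is
absorbed into the run (recorded as an intruder) instead of terminating it.
Two or more consecutive non-legume leaves always terminate a run, as does a
non-legume leaf at either end of the listing (it lacks a legume flank).
*Strict* mode absorbs nothing: clades are maximal legume-only runs.

Permissive mode may absorb several isolated singletons into one clade, each
individually flanked; ``max_intruders`` restricts how many (None = no cap),
allowing the stricter one-intruder-per-clade reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datamodel import GeneTree, SpeciesConfig, species_of_gene

__all__ = ["LegumeClade", "detect_legume_clades", "clade_count_table"]


@dataclass
class LegumeClade:
    """One legume gene clade: its 1-based index in leaf order, the ordered
    legume member leaves, any absorbed non-legume intruders, and the set of
    legume species present."""

    index: int
    members: list[str]
    intruders: list[str] = field(default_factory=list)
    species_present: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.members)


def detect_legume_clades(
    tree: GeneTree,
    config: SpeciesConfig,
    mode: str = "permissive",
    max_intruders: int | None = None,
) -> list[LegumeClade]:
    """Enumerate legume clades from the tree's leaf listing.

    Parameters
    ----------
    mode : {"permissive", "strict"}
        Whether a single flanked non-legume leaf may be absorbed.
    max_intruders : int, optional
        Cap on absorbed singletons per clade in permissive mode.

    Returns clades in leaf order; the clade count is the list length.
    """
    if mode not in ("permissive", "strict"):
        raise ValueError(f"mode must be 'permissive' or 'strict', got {mode!r}")
    if len(tree) == 0:
        raise ValueError(f"{tree.superfamily_id}: tree has no leaves")

    leaves = tree.leaf_order
    flags = [species_of_gene(lbl, config).is_legume for lbl in leaves]
    n = len(leaves)

    clades: list[LegumeClade] = []
    current: LegumeClade | None = None
    i = 0
    while i < n:
        if flags[i]:
            if current is None:
                current = LegumeClade(index=len(clades) + 1, members=[])
            current.members.append(leaves[i])
            current.species_present.add(species_of_gene(leaves[i], config).code)
            i += 1
            continue
        # non-legume leaf: absorbable iff permissive, inside an open run,
        # flanked by legume leaves on both sides, a singleton, and under cap
        absorbable = (
            mode == "permissive"
            and current is not None
            and 0 < i < n - 1
            and flags[i - 1]
            and flags[i + 1]
            and (max_intruders is None or len(current.intruders) < max_intruders)
        )
        if absorbable:
            current.intruders.append(leaves[i])
        elif current is not None:
            clades.append(current)
            current = None
        i += 1
    if current is not None:
        clades.append(current)
    return clades


def clade_count_table(
    trees: list[GeneTree],
    config: SpeciesConfig,
    mode: str = "permissive",
    max_intruders: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Clade counts per superfamily plus the derived roll-ups:
    ``n_multi`` (superfamilies with >= 2 clades) and ``n_six_plus``
    (with >= 6)."""
    rows = []
    for tree in trees:
        clades = detect_legume_clades(tree, config, mode, max_intruders)
        rows.append(
            {
                "superfamily_id": tree.superfamily_id,
                "mode": mode,
                "clade_count": len(clades),
            }
        )
    table = pd.DataFrame(
        rows, columns=["superfamily_id", "mode", "clade_count"]
    )
    summary = {
        "n_families": len(table),
        "n_multi": int((table["clade_count"] >= 2).sum()) if len(table) else 0,
        "n_six_plus": int((table["clade_count"] >= 6).sum()) if len(table) else 0,
    }
    return table, summary
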