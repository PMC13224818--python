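"""Positional classification of paralogs and duplication-origin inference.

Local duplicates are same-species paralogs within 1 Mb on the same
chromosome, subdivided into *tandem* (immediately adjacent by genome-wide
ordinal rank, i.e. no intervening annotated gene) and *proximal*
(non-adjacent within the window).  Everything else is *distal*.

A pair of legume clades sharing species is called *local* in origin when at
least ``min_local_species`` shared species have a cross-clade within-window
pair, and *segmental* (WGD-derived) otherwise.  An *ancient local
duplication* — one predating legume diversification — is flagged when at
least six species have within-window same-chromosome pairs spanning
different strict legume clades.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .clades import LegumeClade, detect_legume_clades
from .datamodel import GeneRecord, GeneTree, SpeciesConfig, species_of_gene

logger = logging.getLogger(__name__)

__all__ = [
    "ParalogPair",
    "CladePairCall",
    "AncientLocalCall",
    "local_paralog_pairs",
    "genes_with_local_paralog",
    "classify_clade_pair",
    "detect_ancient_local",
    "family_dup_summary",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 1_000_000  # bp; "within 1 Mb"

LOCAL_RELATIONS = frozenset({"tandem", "proximal"})


@dataclass(frozen=True)
class ParalogPair:
    """An unordered same-species gene pair with its positional relation.

    ``distance`` is |start_a - start_b| in bp, or None when the genes lie on
    different chromosomes.
    """

    gene_a: str
    gene_b: str
    species: str
    chromosome: str | None
    distance: int | None
    relation: str  # tandem | proximal | distal

    @property
    def is_local(self) -> bool:
        return self.relation in LOCAL_RELATIONS


@dataclass
class CladePairCall:
    """Origin call for a pair of legume clades with duplicated membership."""

    clade_a: int
    clade_b: int
    shared_species: set[str]
    local_support_species: set[str]
    call: str | None  # "segmental" | "local" | None (no shared species)


@dataclass
class AncientLocalCall:
    superfamily_id: str
    is_ancient: bool
    supporting_species: set[str]
    clade_pairs: list[tuple[int, int]] = field(default_factory=list)


def _classify(
    rec_a: GeneRecord,
    rec_b: GeneRecord,
    window: int,
    adjacency: str,
    family_ordinals: dict[tuple[str, str], list[int]] | None = None,
) -> ParalogPair:
    a, b = sorted((rec_a, rec_b), key=lambda r: r.gene_id)
    if a.chromosome != b.chromosome:
        return ParalogPair(a.gene_id, b.gene_id, a.species, None, None, "distal")
    distance = abs(a.start - b.start)
    if distance <= window:
        if adjacency == "genome":
            adjacent = (
                a.ordinal is not None
                and b.ordinal is not None
                and abs(a.ordinal - b.ordinal) == 1
            )
        else:  # within-family: no family gene strictly between the two
            ords = family_ordinals[(a.species, a.chromosome)]
            lo, hi = sorted((a.ordinal, b.ordinal))
            adjacent = not any(lo < o < hi for o in ords)
        relation = "tandem" if adjacent else "proximal"
    else:
        relation = "distal"
    return ParalogPair(
        a.gene_id, b.gene_id, a.species, a.chromosome, distance, relation
    )


def local_paralog_pairs(
    records: list[GeneRecord],
    window: int = DEFAULT_WINDOW,
    adjacency: str = "genome",
) -> list[ParalogPair]:
    """Classify every unordered same-species pair of one superfamily.

    ``adjacency`` controls what "immediately adjacent" means: ``"genome"``
    (default) requires a genome-wide ordinal difference of exactly 1 (no
    intervening annotated gene of any family); ``"within-family"`` requires
    only that no *family* gene lies between the two.  Distal pairs are
    retained, flagged by their relation.
    """
    if adjacency not in ("genome", "within-family"):
        raise ValueError(f"unknown adjacency mode {adjacency!r}")
    usable = []
    for rec in records:
        if rec.ordinal is None and adjacency == "genome":
            logger.warning(
                "gene %s has no ordinal; excluded from pair typing", rec.gene_id
            )
            continue
        usable.append(rec)
    family_ordinals: dict[tuple[str, str], list[int]] = {}
    for rec in usable:
        family_ordinals.setdefault((rec.species, rec.chromosome), []).append(
            rec.ordinal
        )
    by_species: dict[str, list[GeneRecord]] = {}
    for rec in usable:
        by_species.setdefault(rec.species, []).append(rec)
    pairs = []
    for recs in by_species.values():
        recs = sorted(recs, key=lambda r: r.gene_id)
        for a, b in itertools.combinations(recs, 2):
            pairs.append(_classify(a, b, window, adjacency, family_ordinals))
    return pairs


def genes_with_local_paralog(pairs: list[ParalogPair]) -> set[str]:
    """Genes appearing in at least one tandem or proximal pair."""
    out: set[str] = set()
    for p in pairs:
        if p.is_local:
            out.add(p.gene_a)
            out.add(p.gene_b)
    return out


def classify_clade_pair(
    clade_a: LegumeClade,
    clade_b: LegumeClade,
    records: dict[str, GeneRecord],
    config: SpeciesConfig,
    window: int = DEFAULT_WINDOW,
    min_local_species: int = 1,
) -> CladePairCall:
    """Call a clade pair local vs segmental from cross-clade proximity.

    For every species present in both clades, tests whether ANY cross-clade
    same-species pair lies within ``window`` bp on the same chromosome; the
    pair is *local* when at least ``min_local_species`` species show such
    support, *segmental* otherwise.
    """
    if not clade_a.members or not clade_b.members:
        raise ValueError("clades must be non-empty")
    shared = clade_a.species_present & clade_b.species_present
    if not shared:
        logger.warning(
            "clades %d and %d share no species; origin call undefined",
            clade_a.index, clade_b.index,
        )
        return CladePairCall(clade_a.index, clade_b.index, set(), set(), None)
    support: set[str] = set()
    for sp in shared:
        genes_a = [
            g for g in clade_a.members
            if species_of_gene(g, config).code == sp and g in records
        ]
        genes_b = [
            g for g in clade_b.members
            if species_of_gene(g, config).code == sp and g in records
        ]
        for ga, gb in itertools.product(genes_a, genes_b):
            ra, rb = records[ga], records[gb]
            if (
                ra.chromosome == rb.chromosome
                and abs(ra.start - rb.start) <= window
            ):
                support.add(sp)
                break
    call = "local" if len(support) >= min_local_species else "segmental"
    return CladePairCall(clade_a.index, clade_b.index, shared, support, call)


def detect_ancient_local(
    tree: GeneTree,
    records: dict[str, GeneRecord],
    config: SpeciesConfig,
    window: int = DEFAULT_WINDOW,
    min_species: int = 6,
    legume_only_support: bool = False,
) -> AncientLocalCall:
    """Flag a superfamily as carrying an ancient retained local duplication.

    Uses *strict* legume clades (legume-only runs bounded by non-legume
    sequences).  A species supports the call when it has at least one
    within-window same-chromosome pair whose two genes lie in different
    strict clades; the call is positive when at least ``min_species``
    species support it.  ``legume_only_support`` restricts supporting
    species to legumes.
    """
    clades = detect_legume_clades(tree, config, mode="strict")
    if len(clades) < 2:
        return AncientLocalCall(tree.superfamily_id, False, set())
    clade_of: dict[str, int] = {}
    for clade in clades:
        for g in clade.members:
            clade_of[g] = clade.index
    by_species: dict[str, list[str]] = {}
    for g in clade_of:
        if g not in records:
            continue
        sp = species_of_gene(g, config).code
        if legume_only_support and not config.is_legume(sp):
            continue
        by_species.setdefault(sp, []).append(g)
    supporting: set[str] = set()
    pairs: set[tuple[int, int]] = set()
    for sp, genes in by_species.items():
        for ga, gb in itertools.combinations(genes, 2):
            if clade_of[ga] == clade_of[gb]:
                continue
            ra, rb = records[ga], records[gb]
            if (
                ra.chromosome == rb.chromosome
                and abs(ra.start - rb.start) <= window
            ):
                supporting.add(sp)
                pairs.add(tuple(sorted((clade_of[ga], clade_of[gb]))))
    return AncientLocalCall(
        tree.superfamily_id,
        len(supporting) >= min_species,
        supporting,
        sorted(pairs),
    )


def family_dup_summary(
    trees: list[GeneTree],
    records_by_family: dict[str, list[GeneRecord]],
    config: SpeciesConfig,
    window: int = DEFAULT_WINDOW,
    min_species: int = 6,
    adjacency: str = "genome",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-superfamily duplication summary plus global roll-ups.

    Columns: n_genes, n_local_pairs, has_local, n_genes_with_local_paralog,
    is_ancient_local.  Roll-ups: n_families_with_local,
    total_genes_with_local_paralog, total_genes, n_ancient.
    """
    rows = []
    total_local_genes = 0
    total_genes = 0
    for tree in trees:
        records = records_by_family.get(tree.superfamily_id, [])
        if not records:
            logger.warning(
                "%s: no coordinates; local-duplication flags unavailable",
                tree.superfamily_id,
            )
        pairs = local_paralog_pairs(records, window, adjacency)
        local_genes = genes_with_local_paralog(pairs)
        n_local_pairs = sum(p.is_local for p in pairs)
        rec_map = {r.gene_id: r for r in records}
        ancient = detect_ancient_local(
            tree, rec_map, config, window, min_species
        )
        rows.append(
            {
                "superfamily_id": tree.superfamily_id,
                "n_genes": len(tree),
                "n_local_pairs": n_local_pairs,
                "has_local": n_local_pairs > 0,
                "n_genes_with_local_paralog": len(local_genes),
                "is_ancient_local": ancient.is_ancient,
            }
        )
        total_local_genes += len(local_genes)
        total_genes += len(tree)
    table = pd.DataFrame(
        rows,
        columns=[
            "superfamily_id", "n_genes", "n_local_pairs", "has_local",
            "n_genes_with_local_paralog", "is_ancient_local",
        ],
    )
    rollups = {
        "n_families": len(table),
        "n_families_with_local": int(table["has_local"].sum()) if len(table) else 0,
        "total_genes": total_genes,
        "total_genes_with_local_paralog": total_local_genes,
        "n_ancient": int(table["is_ancient_local"].sum()) if len(table) else 0,
    }
    return table, rollups
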