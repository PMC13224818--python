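"""Core domain types for the superfamily duplication/expression pipeline.

Genes are identified by ``<code>.<gene_id>`` leaf labels, where ``code`` is a
five-letter species abbreviation (three letters of the genus plus two of the
species epithet, e.g. ``lotja`` for *Lotus japonicus*).  Species belong to one
of six groups: the four legume subfamilies sampled here (Papilionoideae PAP,
Caesalpinioideae CAE, Detarioideae DET, Cercidoideae CER), the Rosales ROS,
and other outgroups OUT.  A species is a legume iff its group is one of the
four subfamilies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Strand",
    "SpeciesInfo",
    "SpeciesConfig",
    "GeneRecord",
    "GeneTree",
    "ExpressionMatrix",
    "TISSUES",
    "default_species_config",
    "species_of_gene",
]

#: The three tissues compared throughout: nodule, root and shoot.
TISSUES = ("nodule", "root", "shoot")

LEGUME_GROUPS = frozenset({"PAP", "CAE", "DET", "CER"})


class Group(str, enum.Enum):
    """Species group: legume subfamily, Rosales, or outgroup."""

    PAP = "PAP"
    CAE = "CAE"
    DET = "DET"
    CER = "CER"
    ROS = "ROS"
    OUT = "OUT"


class Strand(str, enum.Enum):
    PLUS = "+"
    MINUS = "-"
    UNKNOWN = "."


@dataclass(frozen=True)
class SpeciesInfo:
    """One sampled species.

    Parameters
    ----------
    code : str
        Five-letter lowercase abbreviation (3 genus + 2 species letters).
    group : Group
        Subfamily / outgroup assignment.
    nodulating : bool
        Whether the species forms root nodules.
    """

    code: str
    group: Group
    nodulating: bool = False

    def __post_init__(self) -> None:
        if len(self.code) != 5 or not self.code.islower():
            raise ValueError(
                f"species code must be 5 lowercase letters, got {self.code!r}"
            )

    @property
    def is_legume(self) -> bool:
        return self.group.value in LEGUME_GROUPS


@dataclass
class SpeciesConfig:
    """The set of configured species plus the PAP/CAE roles used for
    cross-species conservation categorisation.

    ``pap_set`` names the Papilionoideae species whose bias labels are
    compared (default Medicago, Glycine, Phaseolus); ``cae_code`` names the
    caesalpinioid reference (default *Chamaecrista fasciculata*).
    """

    species: dict[str, SpeciesInfo]
    pap_set: frozenset[str] = frozenset({"medtr", "glyma", "phavu"})
    cae_code: str = "chafa"

    def __post_init__(self) -> None:
        if isinstance(self.species, (list, tuple)):
            self.species = {s.code: s for s in self.species}
        self.pap_set = frozenset(self.pap_set)
        missing = self.pap_set - self.species.keys()
        if missing:
            raise ValueError(f"pap_set codes not configured: {sorted(missing)}")
        if self.cae_code not in self.species:
            raise ValueError(f"cae_code {self.cae_code!r} not configured")

    def __contains__(self, code: str) -> bool:
        return code in self.species

    def __getitem__(self, code: str) -> SpeciesInfo:
        return self.species[code]

    @property
    def codes(self) -> list[str]:
        return list(self.species)

    def is_legume(self, code: str) -> bool:
        return self.species[code].is_legume


#: (code, group, nodulating) for the 18 sampled species.  Five Papilionoideae,
#: three Caesalpinioideae, one Detarioideae, three Cercidoideae, three
#: Rosales, three outgroups.
_DEFAULT_SPECIES: tuple[tuple[str, str, bool], ...] = (
    ("glyma", "PAP", True),   # Glycine max
    ("medtr", "PAP", True),   # Medicago truncatula
    ("phavu", "PAP", True),   # Phaseolus vulgaris
    ("lotja", "PAP", True),   # Lotus japonicus
    ("aesev", "PAP", True),   # Aeschynomene evenia
    ("chafa", "CAE", True),   # Chamaecrista fasciculata
    ("sento", "CAE", True),   # Senna tora
    ("acacr", "CAE", True),   # Acacia crassicarpa
    ("singl", "DET", False),  # Sindora glabra
    ("cerca", "CER", False),  # Cercis canadensis
    ("bauva", "CER", False),  # Bauhinia variegata
    ("phach", "CER", False),  # Phanera championii
    ("quisa", "ROS", False),  # Quillaja saponaria
    ("treor", "ROS", False),  # Trema orientale
    ("paran", "ROS", True),   # Parasponia andersonii
    ("arath", "OUT", False),  # Arabidopsis thaliana
    ("prupe", "OUT", False),  # Prunus persica
    ("vitvi", "OUT", False),  # Vitis vinifera
)


def default_species_config() -> SpeciesConfig:
    """The 18-species configuration used throughout: 12 legumes across four
    subfamilies plus six non-legume relatives and outgroups."""
    return SpeciesConfig(
        species={
            code: SpeciesInfo(code, Group(group), nodulating)
            for code, group, nodulating in _DEFAULT_SPECIES
        }
    )


def species_of_gene(label: str, config: SpeciesConfig) -> SpeciesInfo:
    """Resolve a gene leaf label to its species.

    The species code is the prefix before the first ``"."``; if the label has
    no separator, its first five characters are tried against the configured
    codes.
    """
    if not label:
        raise ValueError("empty gene label")
    code = label.split(".", 1)[0] if "." in label else label[:5]
    try:
        return config[code]
    except KeyError:
        raise KeyError(
            f"gene label {label!r}: species code {code!r} is not configured"
        ) from None


@dataclass(frozen=True)
class GeneRecord:
    """Genomic position of one gene.

    Coordinates are 1-based inclusive (GFF3 convention).  ``ordinal`` is the
    gene's rank among all annotated genes on its chromosome, sorted by start —
    a genome-wide rank, not a rank within the superfamily.
    """

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: Strand = Strand.UNKNOWN
    ordinal: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: invalid coordinates "
                f"start={self.start} end={self.end} (need end >= start >= 1)"
            )
        if self.ordinal is not None and self.ordinal < 1:
            raise ValueError(f"{self.gene_id}: ordinal must be >= 1")


@dataclass
class GeneTree:
    """A rooted superfamily gene tree, as read from Newick.

    ``leaf_order`` is the left-to-right listing of leaf labels exactly as
    written in the source file; clade detection operates on this listing.
    ``support`` maps internal-node ids to support values where present.
    """

    superfamily_id: str
    leaf_order: list[str]
    newick: str = ""

    def __post_init__(self) -> None:
        if len(set(self.leaf_order)) != len(self.leaf_order):
            dupes = sorted(
                {x for x in self.leaf_order if self.leaf_order.count(x) > 1}
            )
            raise ValueError(
                f"{self.superfamily_id}: duplicate leaf labels {dupes}"
            )

    def __len__(self) -> int:
        return len(self.leaf_order)

    def species_codes(self, config: SpeciesConfig) -> list[str]:
        return [species_of_gene(lbl, config).code for lbl in self.leaf_order]


class ExpressionMatrix:
    """Non-negative expression values (genes x samples) for one species,
    with a sample -> tissue map over nodule/root/shoot.

    Values may be FPKM or TMM-normalised counts; downstream comparisons use
    only tissue means and relative (proportional) expression, so the unit
    cancels.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        sample_tissue: Mapping[str, str],
        species: str = "",
    ) -> None:
        values = values.astype(float)
        if (values.to_numpy() < 0).any():
            bad = values.index[(values < 0).any(axis=1)][0]
            raise ValueError(f"negative expression value for gene {bad!r}")
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicated gene id {dup!r} in expression matrix")
        unknown = set(sample_tissue.values()) - set(TISSUES)
        if unknown:
            raise ValueError(f"unknown tissues in sample map: {sorted(unknown)}")
        keep = [s for s in values.columns if s in sample_tissue]
        self.values = values[keep]
        self.sample_tissue = {s: sample_tissue[s] for s in keep}
        self.species = species

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples_for(self, tissue: str) -> list[str]:
        return [s for s, t in self.sample_tissue.items() if t == tissue]

    def tissues_present(self) -> list[str]:
        present = set(self.sample_tissue.values())
        return [t for t in TISSUES if t in present]

    def tissue_means(self) -> pd.DataFrame:
        """Per-gene mean expression per tissue (replicates averaged).

        Columns are the three tissues; a tissue with no mapped samples
        yields NaN.
        """
        out = {}
        for tissue in TISSUES:
            cols = self.samples_for(tissue)
            out[tissue] = (
                self.values[cols].mean(axis=1) if cols else np.nan
            )
        return pd.DataFrame(out, index=self.values.index)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix(species={self.species!r}, "
            f"genes={self.values.shape[0]}, samples={self.values.shape[1]})"
        )
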