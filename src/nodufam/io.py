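"""Readers and writers: Newick gene trees, gene position tables (GFF3 or
6-column TSV), expression matrices with sample->tissue maps, and the species
configuration file."""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
import yaml

from .datamodel import (
    ExpressionMatrix,
    GeneRecord,
    GeneTree,
    SpeciesConfig,
    SpeciesInfo,
    Group,
    Strand,
    species_of_gene,
)

logger = logging.getLogger(__name__)

TSV6_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "ordinal"]


# ---------------------------------------------------------------------------
# Gene trees


def read_gene_tree(
    path: str | Path,
    config: SpeciesConfig | None = None,
    superfamily_id: str | None = None,
) -> GeneTree:
    """Read a single rooted Newick tree, preserving the left-to-right leaf
    order as written.  Internal-node labels (support values) are kept in the
    stored Newick string but play no role downstream.
    """
    path = Path(path)
    text = path.read_text()
    if superfamily_id is None:
        superfamily_id = path.stem
    return parse_gene_tree(text, config, superfamily_id)


def parse_gene_tree(
    newick: str,
    config: SpeciesConfig | None = None,
    superfamily_id: str = "",
) -> GeneTree:
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        offset = getattr(exc, "col_num", None)
        where = f" near character {offset}" if offset is not None else ""
        raise ValueError(
            f"{superfamily_id or '<tree>'}: unparsable Newick{where}: {exc}"
        ) from exc
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if not leaves:
        raise ValueError(f"{superfamily_id or '<tree>'}: tree has no leaves")
    gt = GeneTree(
        superfamily_id=superfamily_id, leaf_order=leaves, newick=newick.strip()
    )
    if config is not None:
        for lbl in leaves:
            species_of_gene(lbl, config)  # raises on unknown code
    return gt


def read_gene_trees(
    directory: str | Path,
    config: SpeciesConfig | None = None,
    pattern: str = "*.nwk",
) -> list[GeneTree]:
    """Read every Newick file in a directory (sorted by filename; the stem is
    the superfamily id)."""
    return [
        read_gene_tree(p, config) for p in sorted(Path(directory).glob(pattern))
    ]


# ---------------------------------------------------------------------------
# Positions


def compute_ordinals(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Assign per-(species, chromosome) ordinal ranks by start position
    (ties broken by end, then gene_id) wherever ordinal is missing."""
    by_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
    for rec in records:
        by_chrom.setdefault((rec.species, rec.chromosome), []).append(rec)
    out: dict[str, GeneRecord] = {}
    for group in by_chrom.values():
        group.sort(key=lambda r: (r.start, r.end, r.gene_id))
        for rank, rec in enumerate(group, start=1):
            if rec.ordinal is None:
                rec = GeneRecord(
                    rec.gene_id, rec.species, rec.chromosome,
                    rec.start, rec.end, rec.strand, rank,
                )
            out[rec.gene_id] = rec
    return [out[r.gene_id] for r in records]


def _parse_strand(s: str) -> Strand:
    try:
        return Strand(s)
    except ValueError:
        return Strand.UNKNOWN


def read_positions(
    path: str | Path,
    dialect: str = "tsv6",
    species: str | None = None,
    config: SpeciesConfig | None = None,
) -> list[GeneRecord]:
    """Read gene coordinates from a tsv6 table or a GFF3 file.

    tsv6 columns: gene_id, chromosome, start, end, strand, ordinal (ordinal
    may be empty; it is then computed by sorting per chromosome by start).
    GFF3: only ``gene`` features are read; gene_id comes from the ID
    attribute.  All coordinates are 1-based inclusive.

    The species of each gene is taken from ``species`` if given, otherwise
    inferred from the gene_id prefix via ``config``.
    """
    path = Path(path)
    if dialect == "tsv6":
        records = _read_tsv6(path)
    elif dialect == "gff3":
        records = _read_gff3(path)
    else:
        raise ValueError(f"unknown positions dialect {dialect!r}")

    seen: set[str] = set()
    final: list[GeneRecord] = []
    for gene_id, chrom, start, end, strand, ordinal in records:
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        if species is not None:
            sp = species
        elif config is not None:
            sp = species_of_gene(gene_id, config).code
        else:
            sp = gene_id.split(".", 1)[0]
        final.append(
            GeneRecord(gene_id, sp, chrom, start, end, strand, ordinal)
        )
    if any(r.ordinal is None for r in final):
        final = compute_ordinals(final)
    return final


def _read_tsv6(path: Path):
    df = pd.read_csv(
        path, sep="\t", header=None, names=TSV6_COLUMNS, comment="#",
        dtype={"gene_id": str, "chromosome": str, "strand": str},
    )
    # a header row is tolerated
    if len(df) and str(df.iloc[0]["gene_id"]) == "gene_id":
        df = df.iloc[1:].reset_index(drop=True)
    for _, row in df.iterrows():
        ordinal = row["ordinal"]
        ordinal = None if pd.isna(ordinal) else int(ordinal)
        yield (
            row["gene_id"], row["chromosome"], int(row["start"]),
            int(row["end"]), _parse_strand(str(row["strand"])), ordinal,
        )


def _read_gff3(path: Path):
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name")
            if gene_id is None:
                raise ValueError(f"GFF3 gene feature without ID in {path}")
            yield (
                gene_id, fields[0], int(fields[3]), int(fields[4]),
                _parse_strand(fields[6]), None,
            )


def write_positions_tsv6(records: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        (r.gene_id, r.chromosome, r.start, r.end, r.strand.value, r.ordinal)
        for r in records
    ]
    pd.DataFrame(rows, columns=TSV6_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Expression


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample_id, tissue."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["sample_id", "tissue"],
        dtype=str, comment="#",
    )
    if len(df) and df.iloc[0]["sample_id"] == "sample_id":
        df = df.iloc[1:]
    return dict(zip(df["sample_id"], df["tissue"]))


def read_expression(
    path: str | Path,
    sample_map: str | Path | dict[str, str],
    species: str = "",
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene_id, header row of sample
    names).  Samples absent from the map are dropped with a warning."""
    if not isinstance(sample_map, dict):
        sample_map = read_sample_map(sample_map)
    df = pd.read_csv(path, sep="\t", index_col=0)
    dropped = [s for s in df.columns if s not in sample_map]
    if dropped:
        logger.warning(
            "%s: dropping %d unmapped sample(s): %s", path, len(dropped), dropped
        )
    return ExpressionMatrix(df, sample_map, species=species)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Species configuration


def read_species_config(path: str | Path) -> SpeciesConfig:
    """YAML with a ``species`` list of {code, group, nodulating} mappings and
    optional ``pap_set`` / ``cae_code`` keys."""
    data = yaml.safe_load(Path(path).read_text())
    species = {
        entry["code"]: SpeciesInfo(
            code=entry["code"],
            group=Group(entry["group"]),
            nodulating=bool(entry.get("nodulating", False)),
        )
        for entry in data["species"]
    }
    kwargs = {}
    if "pap_set" in data:
        kwargs["pap_set"] = frozenset(data["pap_set"])
    if "cae_code" in data:
        kwargs["cae_code"] = data["cae_code"]
    return SpeciesConfig(species=species, **kwargs)


def write_species_config(config: SpeciesConfig, path: str | Path) -> None:
    data = {
        "species": [
            {
                "code": s.code,
                "group": s.group.value,
                "nodulating": s.nodulating,
            }
            for s in config.species.values()
        ],
        "pap_set": sorted(config.pap_set),
        "cae_code": config.cae_code,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
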