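"""End-to-end orchestration: clade detection, duplication typing, expression
bias and conservation categories over a directory of superfamilies, merged
into one FamilySummary table with global roll-ups."""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clades import detect_legume_clades
from .datamodel import ExpressionMatrix, GeneRecord, GeneTree, SpeciesConfig
from .duplication import (
    DEFAULT_WINDOW,
    detect_ancient_local,
    genes_with_local_paralog,
    local_paralog_pairs,
)
from .expression import assign_category, bias_census, family_bias

logger = logging.getLogger(__name__)

__all__ = ["RunParams", "run_all", "summarize_family"]


@dataclass
class RunParams:
    window: int = DEFAULT_WINDOW
    fold: float = 2.0
    min_species: int = 6
    mode: str = "permissive"
    adjacency: str = "genome"
    max_intruders: int | None = None


@dataclass
class RunResult:
    summary: pd.DataFrame
    rollups: dict
    errors: list[tuple[str, str]] = field(default_factory=list)


def summarize_family(
    tree: GeneTree,
    records: list[GeneRecord],
    expression: dict[str, ExpressionMatrix],
    config: SpeciesConfig,
    params: RunParams,
) -> dict:
    """One FamilySummary row for one superfamily."""
    species = set(tree.species_codes(config))
    permissive = detect_legume_clades(
        tree, config, "permissive", params.max_intruders
    )
    strict = detect_legume_clades(tree, config, "strict")
    pairs = local_paralog_pairs(records, params.window, params.adjacency)
    local_genes = genes_with_local_paralog(pairs)
    ancient = detect_ancient_local(
        tree, {r.gene_id: r for r in records}, config,
        params.window, params.min_species,
    )
    row = {
        "superfamily_id": tree.superfamily_id,
        "n_species": len(species),
        "n_genes": len(tree),
        "clade_count_permissive": len(permissive),
        "clade_count_strict": len(strict),
        "n_local_pairs": sum(p.is_local for p in pairs),
        "has_local": any(p.is_local for p in pairs),
        "n_genes_with_local_paralog": len(local_genes),
        "is_ancient_local": ancient.is_ancient,
    }
    # per-species superfamily bias labels; missing expression -> NA
    labels: dict[str, str] = {}
    for sp in sorted(config.pap_set | {config.cae_code}):
        matrix = expression.get(sp)
        if matrix is None:
            labels[sp] = "NA"
        else:
            members = [g for g in tree.leaf_order if g.startswith(sp + ".")]
            labels[sp] = family_bias(matrix, members, params.fold)
        row[f"bias_{sp}"] = labels[sp]
    row["category"] = assign_category(labels, config)
    return row


def run_all(
    trees: list[GeneTree],
    records_by_family: dict[str, list[GeneRecord]],
    expression: dict[str, ExpressionMatrix],
    config: SpeciesConfig,
    params: RunParams | None = None,
) -> RunResult:
    """Run every stage on every superfamily.

    A family that fails to process is skipped and listed under ``errors``;
    the run continues.  Deterministic given inputs and parameters.
    """
    params = params or RunParams()
    rows = []
    errors: list[tuple[str, str]] = []
    fam_labels: dict[str, dict[str, str]] = {}
    for tree in trees:
        try:
            row = summarize_family(
                tree,
                records_by_family.get(tree.superfamily_id, []),
                expression,
                config,
                params,
            )
        except Exception as exc:
            logger.error("family %s failed: %s", tree.superfamily_id, exc)
            errors.append((tree.superfamily_id, str(exc)))
            continue
        rows.append(row)
        fam_labels[tree.superfamily_id] = {
            k.removeprefix("bias_"): v
            for k, v in row.items()
            if k.startswith("bias_")
        }
    summary = pd.DataFrame(rows)
    if len(summary):
        census = bias_census(fam_labels)
        rollups = {
            "n_families": len(summary),
            "n_multi": int((summary["clade_count_permissive"] >= 2).sum()),
            "n_six_plus": int((summary["clade_count_permissive"] >= 6).sum()),
            "n_families_with_local": int(summary["has_local"].sum()),
            "total_genes": int(summary["n_genes"].sum()),
            "total_genes_with_local_paralog": int(
                summary["n_genes_with_local_paralog"].sum()
            ),
            "n_ancient": int(summary["is_ancient_local"].sum()),
            "bias_census": {
                sp: census.loc[sp].to_dict() for sp in census.index
            },
        }
    else:
        rollups = {"n_families": 0}
    return RunResult(summary=summary, rollups=rollups, errors=errors)


def write_run_result(
    result: RunResult, out_dir: str | Path, params: RunParams
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (
        f"# nodufam {__version__} | window={params.window} "
        f"fold={params.fold} min_species={params.min_species} "
        f"mode={params.mode} adjacency={params.adjacency}\n"
    )
    with open(out / "family_summary.tsv", "w") as fh:
        fh.write(header)
        result.summary.to_csv(fh, sep="\t", index=False)
    (out / "rollups.json").write_text(json.dumps(result.rollups, indent=2))
    pd.DataFrame(result.errors, columns=["superfamily_id", "error"]).to_csv(
        out / "errors.tsv", sep="\t", index=False
    )
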