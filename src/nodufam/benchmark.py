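"""Recovery benchmarks on simulated ground truth.

These routines generate families and expression matrices with the bundled
simulator and measure how well each pipeline stage recovers the planted
events: the clade rule against a brute-force run-enumeration oracle,
tandem/proximal pair typing against the event log, segmental calls for
planted WGDs, the >= 6-species ancient-local rule, and the 2-fold bias
classifier under multiplicative noise.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .clades import detect_legume_clades
from .datamodel import GeneTree, SpeciesConfig, default_species_config, species_of_gene
from .duplication import classify_clade_pair, detect_ancient_local, local_paralog_pairs
from .expression import gene_bias, pca_variance, tissue_profile
from .simulate import ExpressionTruth, SimConfig, simulate_expression, simulate_family, truth_report
from .stats import epsilon_squared, kruskal_wallis, pairwise_wilcoxon_bh

__all__ = [
    "oracle_clade_counts",
    "clade_oracle_agreement",
    "benchmark_families",
    "duplication_recovery",
    "bias_recovery",
    "category_coverage",
    "stats_oracle",
    "pca_checks",
]


# ---------------------------------------------------------------------------
# 1. Clade rule vs brute-force oracle


def oracle_clade_counts(flags: str) -> tuple[int, int]:
    """Brute-force (permissive, strict) clade counts for a binary L/N leaf
    pattern: strict counts maximal runs of L; permissive first rewrites
    every isolated N flanked by L on both sides to L, then counts runs."""
    strict = sum(1 for run in flags.split("N") if run)
    chars = list(flags)
    for i in range(1, len(chars) - 1):
        if chars[i] == "N" and flags[i - 1] == "L" and flags[i + 1] == "L":
            chars[i] = "L"
    permissive = sum(1 for run in "".join(chars).split("N") if run)
    return permissive, strict


def _tree_from_flags(flags: str, config: SpeciesConfig) -> GeneTree:
    legumes = [c for c in config.codes if config.is_legume(c)]
    others = [c for c in config.codes if not config.is_legume(c)]
    leaves = [
        f"{(legumes if ch == 'L' else others)[i % 3]}.g{i:03d}"
        for i, ch in enumerate(flags)
    ]
    return GeneTree(superfamily_id="oracle", leaf_order=leaves)


def clade_oracle_agreement(
    seed: int, n_sequences: int = 200, max_len: int = 30
) -> dict[str, float]:
    """Fraction of random binary leaf sequences on which the clade detector
    matches the oracle in both modes, plus whether the permissive count
    stayed <= the strict count on every instance."""
    rng = np.random.default_rng(seed)
    config = default_species_config()
    agree = 0
    ordered = True
    for _ in range(n_sequences):
        length = int(rng.integers(1, max_len + 1))
        flags = "".join(rng.choice(["L", "N"], size=length))
        tree = _tree_from_flags(flags, config)
        n_perm = len(detect_legume_clades(tree, config, "permissive"))
        n_strict = len(detect_legume_clades(tree, config, "strict"))
        agree += (n_perm, n_strict) == oracle_clade_counts(flags)
        ordered &= n_perm <= n_strict
    return {
        "agreement": agree / n_sequences,
        "permissive_le_strict": float(ordered),
        "n": n_sequences,
    }


# ---------------------------------------------------------------------------
# 2. Duplication recovery on simulated families

#: ancient-local retention counts cycled over the benchmark families,
#: straddling the 6-species rule on both sides
_ANCIENT_RETENTION = (3, 5, 6, 7, 9)


def benchmark_families(seed: int, n_families: int = 50):
    """The standard loss-free benchmark: a mix of tandem/proximal regimes,
    fully retained pre-legume WGDs, and planted ancient local duplications
    with retention straddling the 6-species threshold."""
    fams = []
    for i in range(n_families):
        kind = i % 5
        kwargs = {}
        if kind == 0:
            kwargs = dict(tandem_rate=0.05)
        elif kind == 1:
            kwargs = dict(tandem_rate=0.03, proximal_rate=0.05)
        elif kind == 2:
            kwargs = dict(wgd_events={"nfnc": 1.0})
        elif kind == 3:
            m = _ANCIENT_RETENTION[(i // 5) % len(_ANCIENT_RETENTION)]
            kwargs = dict(ancient_local=("fabales", m))
        else:
            kwargs = dict(wgd_events={"eudicots": 1.0})
        rng = np.random.default_rng([seed, i])
        fams.append(
            (kind, kwargs, simulate_family(SimConfig(**kwargs), f"bench{i:03d}", rng=rng))
        )
    return fams


def duplication_recovery(seed: int, n_families: int = 50) -> dict[str, float]:
    """Precision/recall of tandem and proximal calls, the fraction of
    planted WGD clade pairs called segmental, and the accuracy of the
    ancient-local rule, over the standard benchmark."""
    config = default_species_config()
    metrics = {
        "tandem_recall": [], "tandem_precision": [],
        "proximal_recall": [], "proximal_precision": [],
    }
    wgd_calls, wgd_total = 0, 0
    ancient_correct, ancient_total = 0, 0
    for kind, kwargs, fam in benchmark_families(seed, n_families):
        pairs = local_paralog_pairs(fam.records)
        report = truth_report(fam, pairs)
        for key in metrics:
            metrics[key].append(report[key])
        if "wgd_events" in kwargs:
            clades = detect_legume_clades(fam.tree, config, "permissive")
            assert len(clades) == 2
            call = classify_clade_pair(
                clades[0], clades[1], fam.record_map, config
            )
            wgd_total += 1
            wgd_calls += call.call == "segmental"
        if "ancient_local" in kwargs:
            m = kwargs["ancient_local"][1]
            call = detect_ancient_local(fam.tree, fam.record_map, config)
            ancient_total += 1
            ancient_correct += call.is_ancient == (m >= 6)
    out = {k: float(min(v)) for k, v in metrics.items()}
    out["wgd_segmental_rate"] = wgd_calls / wgd_total if wgd_total else 1.0
    out["ancient_rule_accuracy"] = (
        ancient_correct / ancient_total if ancient_total else 1.0
    )
    out["n"] = n_families
    return out


# ---------------------------------------------------------------------------
# 3. Bias recovery


def bias_recovery(
    seed: int,
    n_genes: int = 1000,
    fold: float = 4.0,
    sigma: float = 0.25,
    replicates: int = 3,
) -> dict[str, float]:
    """Fraction of genes whose planted tissue label the 2-fold classifier
    recovers under multiplicative log-normal noise."""
    rng = np.random.default_rng(seed)
    genes = [f"medtr.b{i:05d}" for i in range(n_genes)]
    labels = ("nodule", "root", "shoot", "neutral")
    truth = {
        g: ExpressionTruth(
            label=labels[i % 4], fold=fold, sigma=sigma, replicates=replicates
        )
        for i, g in enumerate(genes)
    }
    matrix = simulate_expression(genes, truth, rng=rng)
    hits = sum(
        gene_bias(tissue_profile(matrix, g)) == truth[g].label for g in genes
    )
    return {"recovery": hits / n_genes, "n": n_genes}


# ---------------------------------------------------------------------------
# 4. Category exhaustiveness


def category_coverage() -> dict[str, float]:
    """Assign a conservation category to every combination of PAP x CAE
    labels; report how many combinations were valid and how many of the
    five categories were produced."""
    from .expression import BIAS_LABELS, assign_category

    config = default_species_config()
    pap = sorted(config.pap_set)
    seen = set()
    n_valid = 0
    for combo in itertools.product(BIAS_LABELS, repeat=4):
        labels = dict(zip(pap, combo[:3]))
        labels[config.cae_code] = combo[3]
        cat = assign_category(labels, config)
        if cat in {1, 2, 3, 4, 5}:
            n_valid += 1
        seen.add(cat)
    return {
        "n_combinations": 5**4,
        "n_valid": n_valid,
        "n_categories_seen": len(seen),
    }


# ---------------------------------------------------------------------------
# 5. Statistics oracle


def stats_oracle() -> dict[str, float]:
    H, df, p = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
    H0, _, _ = kruskal_wallis({"a": [5.0] * 4, "b": [5.0] * 4})
    rng = np.random.default_rng(0)
    groups = {k: rng.normal(loc=i * 0.4, size=15) for i, k in enumerate("abcde")}
    q = pairwise_wilcoxon_bh(groups)
    qvals = q.to_numpy()[np.triu_indices(5, 1)]
    return {
        "kruskal_H_123_456": H,
        "kruskal_H_identical": H0,
        "epsilon2_H3857_n6": epsilon_squared(H, 6),
        "bh_q_max": float(np.nanmax(qvals)),
    }


# ---------------------------------------------------------------------------
# 6. PCA sanity


def pca_checks(seed: int, n: int = 10_000, p: int = 12) -> dict[str, float]:
    rank1 = pd.DataFrame(np.outer(np.arange(1.0, 9.0), np.arange(1.0, p + 1.0)))
    pc1 = float(pca_variance(rank1)[0])
    rng = np.random.default_rng(seed)
    iso = pd.DataFrame(rng.normal(size=(n, p)))
    fractions = pca_variance(iso)
    return {
        "rank1_pc1_fraction": pc1,
        "isotropic_max_abs_dev": float(np.abs(fractions - 1 / p).max()),
        "n": n,
    }
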