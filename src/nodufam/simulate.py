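"""Synthetic gene-family evolution with a known event history.

Families evolve down a fixed 18-species tree (five Papilionoideae, three
Caesalpinioideae, one Detarioideae, three Cercidoideae, three Rosales, three
outgroups).  Events on species-tree branches:

* **WGD_copy** — a whole-genome-duplication copy of every extant lineage at a
  named internal node; the copy lands on a different chromosome at the same
  ordinal slot and is retained per descendant leaf with the configured
  retention probability.
* **tandem** — a copy at the immediately adjacent ordinal slot on the same
  chromosome (no intervening gene).
* **proximal** — a copy 3-11 slots away on the same chromosome (2-10
  intervening genes), within the 1 Mb window under the default spacing model.
* **loss** — a lineage terminates.

Positions live on an integer *slot* lattice per chromosome: every slot is one
annotated gene (family member or background gene), so genome-wide ordinal
rank equals the slot index.  Base-pair starts accumulate i.i.d. inter-gene
spacings (uniform 20-90 kb by default, so 11 slots stay under 1 Mb while
distinct ancestral loci, 10,000 slots apart, are distal).  The emitted gene
tree mirrors the true duplication/speciation history; its planar leaf order
is what clade detection consumes.

An optional *ancient local* planting inserts a tandem duplication on the
branch above a pre-legume node and retains the extra copy in exactly
``n_retained`` legume species (and all non-legume species, so the two copies
fall in different strict legume clades), giving a controllable ground truth
for the >= 6-species ancient-duplication rule.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    GeneRecord,
    GeneTree,
    SpeciesConfig,
    Strand,
    TISSUES,
    default_species_config,
)
from .duplication import DEFAULT_WINDOW, ParalogPair

__all__ = [
    "SpeciesTreeNode",
    "DEFAULT_SPECIES_TREE",
    "SimConfig",
    "SimEvent",
    "ExpressionTruth",
    "SimulatedFamily",
    "simulate_family",
    "simulate_expression",
    "replay_event_log",
    "truth_pairs",
    "truth_report",
]

MAX_GENES = 100_000  # runaway guard


# ---------------------------------------------------------------------------
# Species tree


@dataclass(frozen=True)
class SpeciesTreeNode:
    """Named node of the fixed species tree; leaves carry species codes."""

    name: str
    children: tuple["SpeciesTreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [lf for ch in self.children for lf in ch.leaves()]

    def find(self, name: str) -> "SpeciesTreeNode | None":
        if self.name == name:
            return self
        for ch in self.children:
            hit = ch.find(name)
            if hit is not None:
                return hit
        return None


def _n(name: str, *children: SpeciesTreeNode) -> SpeciesTreeNode:
    return SpeciesTreeNode(name, tuple(children))


def _leaf(code: str) -> SpeciesTreeNode:
    return SpeciesTreeNode(code)


#: 18-taxon species tree.  Outgroups ladder off first so that legume leaves
#: form one contiguous block at the end of the planar leaf order; named
#: internal nodes anchor WGD and ancient-duplication plantings ("root",
#: "nfnc" and "fabales" predate the legume crown "legumes").
DEFAULT_SPECIES_TREE: SpeciesTreeNode = _n(
    "root",
    _leaf("vitvi"),
    _n(
        "eudicots",
        _leaf("arath"),
        _n(
            "rosids",
            _leaf("prupe"),
            _n(
                "nfnc",
                _n("cannabaceae", _leaf("treor"), _leaf("paran")),
                _n(
                    "fabales",
                    _leaf("quisa"),
                    _n(
                        "legumes",
                        _n(
                            "cercidoideae",
                            _leaf("cerca"),
                            _n("bauhinieae", _leaf("bauva"), _leaf("phach")),
                        ),
                        _n(
                            "detpap",
                            _leaf("singl"),
                            _n(
                                "capa",
                                _n(
                                    "caesalpinioideae",
                                    _leaf("chafa"),
                                    _n("cassieae", _leaf("sento"), _leaf("acacr")),
                                ),
                                _n(
                                    "papilionoideae",
                                    _leaf("aesev"),
                                    _n(
                                        "pap2",
                                        _leaf("lotja"),
                                        _n(
                                            "pap3",
                                            _leaf("glyma"),
                                            _n("pap4", _leaf("phavu"), _leaf("medtr")),
                                        ),
                                    ),
                                ),
                            ),
                        ),
                    ),
                ),
            ),
        ),
    ),
)


# ---------------------------------------------------------------------------
# Configuration and truth containers


@dataclass
class SimConfig:
    """Simulation parameters; ``seed`` fixes all randomness.

    Rates are per-gene per-branch event probabilities.  ``wgd_events`` maps
    species-tree node names to per-descendant-leaf retention probabilities.
    ``ancient_local`` plants a tandem duplication above the named pre-legume
    node with the copy retained in exactly ``n`` legume species.
    """

    species_tree: SpeciesTreeNode = DEFAULT_SPECIES_TREE
    wgd_events: dict[str, float] = field(default_factory=dict)
    tandem_rate: float = 0.0
    proximal_rate: float = 0.0
    loss_rate: float = 0.0
    n_root_genes: int = 1
    n_chromosomes: int = 8
    spacing_bp: tuple[int, int] = (20_000, 90_000)
    ancient_local: tuple[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in [
            ("tandem_rate", self.tandem_rate),
            ("proximal_rate", self.proximal_rate),
            ("loss_rate", self.loss_rate),
        ]:
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        for node, ret in self.wgd_events.items():
            if not 0 <= ret <= 1:
                raise ValueError(f"WGD retention for {node!r} must be in [0, 1]")
            if self.species_tree.find(node) is None:
                raise ValueError(f"unknown species-tree node {node!r}")
        if self.ancient_local is not None:
            node, n = self.ancient_local
            if self.species_tree.find(node) is None:
                raise ValueError(f"unknown species-tree node {node!r}")
            if n < 0:
                raise ValueError("ancient_local retention count must be >= 0")


@dataclass(frozen=True)
class SimEvent:
    """One record of the event log: what happened, on which species-tree
    branch, to which lineage, and where the result was placed."""

    etype: str  # WGD_copy | tandem | proximal | loss | speciation | gene
    node: str  # species-tree node whose incoming branch carried the event
    parent: str  # parent lineage uid ("" for root lineages)
    child: str  # lineage uid created/affected, or gene_id for "gene"
    placement: tuple[str, int] | None = None  # (chromosome, slot)


@dataclass
class ExpressionTruth:
    """Planted expression regime for one gene."""

    label: str  # nodule | root | shoot | neutral
    fold: float = 2.0
    sigma: float = 0.25
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.label == "neutral":
            self.fold = 1.0
        if self.fold < 1:
            raise ValueError("planted fold must be >= 1")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class SimulatedFamily:
    """One simulated superfamily with its full ground truth."""

    superfamily_id: str
    tree: GeneTree
    records: list[GeneRecord]
    log: list[SimEvent]
    placements: dict[str, tuple[str, int]]  # gene_id -> (chromosome, slot)
    starts: dict[str, int]  # gene_id -> bp start
    wgd_side: dict[str, dict[str, int]]  # gene_id -> {wgd event uid: side}
    config: SimConfig

    @property
    def record_map(self) -> dict[str, GeneRecord]:
        return {r.gene_id: r for r in self.records}


# ---------------------------------------------------------------------------
# Internal lineage machinery


@dataclass
class _Lineage:
    uid: str
    chrom: str
    slot: int
    wgd_side: dict[str, int]
    retain_species: frozenset[str] | None = None  # ancient-local pruning
    wgd_retention: float = 1.0  # per-leaf retention for WGD copies


class _GTNode:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children=None):
        self.label = label
        self.children = children or []

    def newick(self) -> str:
        if self.label is not None:
            return self.label
        return "(" + ",".join(c.newick() for c in self.children) + ")"

    def leaves(self) -> list[str]:
        if self.label is not None:
            return [self.label]
        return [lf for c in self.children for lf in c.leaves()]


class _Simulator:
    def __init__(self, config: SimConfig, superfamily_id: str, rng):
        self.cfg = config
        self.fid = superfamily_id
        self.rng = rng
        self.log: list[SimEvent] = []
        self.used_slots: dict[str, set[int]] = {}
        self.lineage_counter = itertools.count()
        self.gene_counter: dict[str, "itertools.count"] = {}
        self.n_lineages = 0
        self.placements: dict[str, tuple[str, int]] = {}
        self.wgd_side: dict[str, dict[str, int]] = {}
        self.ancient_retain: frozenset[str] | None = None
        if config.ancient_local is not None:
            node, n = config.ancient_local
            # retain the copy in n legume species (chosen reproducibly) plus
            # every non-legume, so the copies land in different strict clades
            descendants = config.species_tree.find(node).leaves()
            legumes = [c for c in descendants if _is_legume_code(c)]
            non_leg = [c for c in descendants if not _is_legume_code(c)]
            chosen = list(self.rng.permutation(legumes)[: min(n, len(legumes))])
            self.ancient_retain = frozenset(chosen) | frozenset(non_leg)

    # -- slot allocation ---------------------------------------------------

    def _claim(self, chrom: str, slot: int) -> None:
        self.used_slots.setdefault(chrom, set()).add(slot)

    def _free(self, chrom: str, slot: int) -> bool:
        return slot not in self.used_slots.get(chrom, set())

    def _adjacent_slot(self, chrom: str, slot: int) -> int:
        for cand in (slot + 1, slot - 1):
            if self._free(chrom, cand):
                return cand
        step = 2
        while True:  # extend outward past an occupied tandem run
            for cand in (slot + step, slot - step):
                if self._free(chrom, cand):
                    return cand
            step += 1

    def _proximal_slot(self, chrom: str, slot: int) -> int:
        offsets = [o for o in range(3, 12)] + [-o for o in range(3, 12)]
        order = self.rng.permutation(len(offsets))
        for idx in order:
            cand = slot + offsets[idx]
            if self._free(chrom, cand):
                return cand
        # dense cluster: widen outward (still local, the cluster spans
        # far less than the window per extra slot)
        step = 12
        while True:
            for cand in (slot + step, slot - step):
                if self._free(chrom, cand):
                    return cand
            step += 1

    def _wgd_slot(self, chrom: str, slot: int) -> tuple[str, int]:
        k = self.cfg.n_chromosomes
        cur = int(chrom[3:])
        for off in range(1, k):
            cand_chrom = f"chr{(cur - 1 + off) % k + 1}"
            s = slot
            while not self._free(cand_chrom, s):
                s += 1
            return cand_chrom, s
        raise RuntimeError("need >= 2 chromosomes for WGD")  # pragma: no cover

    # -- lineages ----------------------------------------------------------

    def _new_uid(self) -> str:
        self.n_lineages += 1
        if self.n_lineages > MAX_GENES:
            raise RuntimeError(
                f"runaway simulation: more than {MAX_GENES} lineages"
            )
        return f"L{next(self.lineage_counter)}"

    def root_lineages(self) -> list[_Lineage]:
        out = []
        for i in range(self.cfg.n_root_genes):
            chrom = f"chr{i % self.cfg.n_chromosomes + 1}"
            # distinct ancestral loci sit 20,000 slots apart: unambiguously
            # distal under any realistic spacing
            slot = 20_000 * (i + 1) + 1
            self._claim(chrom, slot)
            lin = _Lineage(self._new_uid(), chrom, slot, {})
            out.append(lin)
        return out

    # -- evolution ---------------------------------------------------------

    def evolve(self, node: SpeciesTreeNode, lin: _Lineage, at_root: bool) -> _GTNode | None:
        cfg = self.cfg
        if not at_root:
            # stochastic loss on branch entry
            if cfg.loss_rate > 0 and self.rng.random() < cfg.loss_rate:
                self.log.append(SimEvent("loss", node.name, lin.uid, lin.uid))
                return None
        children_lineages: list[_Lineage] = [lin]
        gt_children: list[tuple[_Lineage, str]] = []

        def duplicate(kind: str, parent: _Lineage) -> _Lineage:
            if kind == "WGD_copy":
                chrom, slot = self._wgd_slot(parent.chrom, parent.slot)
            elif kind == "tandem":
                chrom, slot = parent.chrom, self._adjacent_slot(parent.chrom, parent.slot)
            else:
                chrom, slot = parent.chrom, self._proximal_slot(parent.chrom, parent.slot)
            self._claim(chrom, slot)
            uid = self._new_uid()
            child = _Lineage(uid, chrom, slot, dict(parent.wgd_side))
            self.log.append(
                SimEvent(kind, node.name, parent.uid, uid, (chrom, slot))
            )
            return child

        if not at_root:
            # planted ancient local duplication above this node
            if cfg.ancient_local is not None and node.name == cfg.ancient_local[0]:
                copy = duplicate("tandem", lin)
                copy.retain_species = self.ancient_retain
                children_lineages.append(copy)
            # WGD at this node
            if node.name in cfg.wgd_events:
                copy = duplicate("WGD_copy", lin)
                ev_uid = f"WGD@{node.name}"
                lin.wgd_side = {**lin.wgd_side, ev_uid: 0}
                copy.wgd_side = {**copy.wgd_side, ev_uid: 1}
                copy.wgd_retention = cfg.wgd_events[node.name]
                children_lineages.append(copy)
            # small-scale duplications
            extra = []
            for parent in children_lineages:
                if cfg.tandem_rate > 0 and self.rng.random() < cfg.tandem_rate:
                    extra.append(duplicate("tandem", parent))
                if cfg.proximal_rate > 0 and self.rng.random() < cfg.proximal_rate:
                    extra.append(duplicate("proximal", parent))
            children_lineages.extend(extra)

        gt_nodes: list[_GTNode] = []
        for cl in children_lineages:
            sub = self._descend(node, cl)
            if sub is not None:
                gt_nodes.append(sub)
        if not gt_nodes:
            return None
        if len(gt_nodes) == 1:
            return gt_nodes[0]
        return _GTNode(children=gt_nodes)

    def _descend(self, node: SpeciesTreeNode, lin: _Lineage) -> _GTNode | None:
        if node.is_leaf:
            code = node.name
            if lin.retain_species is not None and code not in lin.retain_species:
                self.log.append(SimEvent("loss", code, lin.uid, lin.uid))
                return None
            if lin.wgd_retention < 1 and self.rng.random() >= lin.wgd_retention:
                self.log.append(SimEvent("loss", code, lin.uid, lin.uid))
                return None
            counter = self.gene_counter.setdefault(code, itertools.count(1))
            gene_id = f"{code}.{self.fid}_g{next(counter):04d}"
            self.placements[gene_id] = (lin.chrom, lin.slot)
            self.wgd_side[gene_id] = dict(lin.wgd_side)
            self.log.append(
                SimEvent("gene", code, lin.uid, gene_id, (lin.chrom, lin.slot))
            )
            return _GTNode(label=gene_id)
        subs = []
        for child in node.children:
            child_lin = _Lineage(
                self._new_uid(), lin.chrom, lin.slot, dict(lin.wgd_side),
                lin.retain_species, lin.wgd_retention,
            )
            self.log.append(
                SimEvent("speciation", child.name, lin.uid, child_lin.uid,
                         (lin.chrom, lin.slot))
            )
            sub = self.evolve(child, child_lin, at_root=False)
            if sub is not None:
                subs.append(sub)
        if not subs:
            return None
        if len(subs) == 1:
            return subs[0]
        return _GTNode(children=subs)


def _is_legume_code(code: str) -> bool:
    return default_species_config()[code].is_legume


# ---------------------------------------------------------------------------
# Coordinates


def _assign_coordinates(
    placements: dict[str, tuple[str, int]],
    spacing_bp: tuple[int, int],
    rng,
) -> dict[str, int]:
    """Map (chromosome, slot) placements to bp starts.

    Consecutive slots are separated by i.i.d. uniform spacings; gaps wider
    than 100 slots use the mean spacing (they are distal at any draw)."""
    lo, hi = spacing_bp
    mean = (lo + hi) / 2
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene, (chrom, slot) in placements.items():
        by_chrom.setdefault(chrom, []).append((slot, gene))
    starts: dict[str, int] = {}
    for chrom in sorted(by_chrom):
        slots = sorted(by_chrom[chrom])
        prev_slot = None
        pos = 0
        for slot, gene in slots:
            if prev_slot is None:
                pos = slot * int(mean)
            else:
                gap = slot - prev_slot
                if gap > 100:
                    pos += int(gap * mean)
                else:
                    pos += int(rng.uniform(lo, hi, size=gap).sum())
            starts[gene] = pos
            prev_slot = slot
    return starts


# ---------------------------------------------------------------------------
# Public API


def simulate_family(
    config: SimConfig, superfamily_id: str = "simfam", rng=None
) -> SimulatedFamily:
    """Evolve one gene family down the species tree and emit its gene tree,
    position records, and event log (the ground truth)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sim = _Simulator(config, superfamily_id, rng)
    roots = sim.root_lineages()
    gt_nodes = []
    for lin in roots:
        sub = sim.evolve(config.species_tree, lin, at_root=True)
        if sub is not None:
            gt_nodes.append(sub)
    if not gt_nodes:
        raise RuntimeError(f"{superfamily_id}: all lineages lost")
    root = gt_nodes[0] if len(gt_nodes) == 1 else _GTNode(children=gt_nodes)
    newick = root.newick() + ";"
    tree = GeneTree(
        superfamily_id=superfamily_id,
        leaf_order=root.leaves(),
        newick=newick,
    )
    starts = _assign_coordinates(sim.placements, config.spacing_bp, rng)
    records = []
    for gene in tree.leaf_order:
        chrom, slot = sim.placements[gene]
        start = starts[gene]
        records.append(
            GeneRecord(
                gene_id=gene,
                species=gene.split(".", 1)[0],
                chromosome=chrom,
                start=start,
                end=start + 2_000,
                strand=Strand.PLUS,
                ordinal=slot,
            )
        )
    return SimulatedFamily(
        superfamily_id=superfamily_id,
        tree=tree,
        records=records,
        log=sim.log,
        placements=sim.placements,
        starts=starts,
        wgd_side=sim.wgd_side,
        config=config,
    )


def replay_event_log(log: list[SimEvent]) -> dict[str, tuple[str, int]]:
    """Re-execute an event log, returning gene_id -> (chromosome, slot).

    Speciation/duplication events create lineages, losses kill them, and
    ``gene`` events bind surviving lineages to leaf genes; inconsistencies
    (a gene emitted from a dead or unknown lineage, or at a placement that
    disagrees with its lineage) raise."""
    alive: dict[str, tuple[str, int] | None] = {}
    genes: dict[str, tuple[str, int]] = {}
    for ev in log:
        if ev.etype == "speciation":
            alive[ev.child] = ev.placement
        elif ev.etype in ("WGD_copy", "tandem", "proximal"):
            alive[ev.child] = ev.placement
        elif ev.etype == "loss":
            alive[ev.child] = None
        elif ev.etype == "gene":
            placement = alive.get(ev.parent, "missing")
            if placement is None:
                raise ValueError(f"gene {ev.child} emitted from lost lineage")
            if placement != "missing" and placement != ev.placement:
                raise ValueError(
                    f"gene {ev.child}: placement {ev.placement} disagrees "
                    f"with lineage {ev.parent} at {placement}"
                )
            genes[ev.child] = ev.placement
    return genes


def truth_pairs(
    family: SimulatedFamily, window: int = DEFAULT_WINDOW
) -> list[ParalogPair]:
    """Ground-truth positional relations for every same-species pair,
    derived from the simulator's internal slot lattice and realized
    coordinates (independently of the pipeline's table-driven classifier)."""
    by_species: dict[str, list[str]] = {}
    for gene in family.tree.leaf_order:
        by_species.setdefault(gene.split(".", 1)[0], []).append(gene)
    pairs = []
    for sp, genes in by_species.items():
        for ga, gb in itertools.combinations(sorted(genes), 2):
            ca, sa = family.placements[ga]
            cb, sb = family.placements[gb]
            if ca != cb:
                pairs.append(ParalogPair(ga, gb, sp, None, None, "distal"))
                continue
            dist = abs(family.starts[ga] - family.starts[gb])
            if dist <= window:
                rel = "tandem" if abs(sa - sb) == 1 else "proximal"
            else:
                rel = "distal"
            pairs.append(ParalogPair(ga, gb, sp, ca, dist, rel))
    return pairs


def truth_report(
    family: SimulatedFamily,
    called_pairs: list[ParalogPair],
    window: int = DEFAULT_WINDOW,
) -> dict[str, float]:
    """Precision/recall of tandem and proximal calls against the truth."""
    truth = truth_pairs(family, window)

    def key_set(pairs, relation):
        return {
            frozenset((p.gene_a, p.gene_b)) for p in pairs
            if p.relation == relation
        }

    out: dict[str, float] = {}
    for relation in ("tandem", "proximal"):
        t = key_set(truth, relation)
        c = key_set(called_pairs, relation)
        out[f"{relation}_recall"] = len(t & c) / len(t) if t else 1.0
        out[f"{relation}_precision"] = len(t & c) / len(c) if c else 1.0
    return out


def simulate_expression(
    genes: list[str],
    truth: dict[str, ExpressionTruth],
    rng=None,
    seed: int | None = None,
    species: str = "",
) -> ExpressionMatrix:
    """Generate replicate expression values with a planted tissue bias.

    Per replicate: value = base x fold^(tissue == planted label) x
    exp(N(0, sigma)), with base drawn log-uniform in [1, 100] per gene.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    missing = [g for g in genes if g not in truth]
    if missing:
        raise ValueError(f"no expression truth for genes {missing[:3]}...")
    n_rep = max(t.replicates for t in truth.values()) if truth else 3
    samples = [f"{t}_{r + 1}" for t in TISSUES for r in range(n_rep)]
    sample_map = {f"{t}_{r + 1}": t for t in TISSUES for r in range(n_rep)}
    data = np.zeros((len(genes), len(samples)))
    for i, gene in enumerate(genes):
        tr = truth[gene]
        base = 10 ** rng.uniform(0, 2)
        for j, sample in enumerate(samples):
            tissue = sample_map[sample]
            fold = tr.fold if tissue == tr.label else 1.0
            noise = math.exp(rng.normal(0, tr.sigma)) if tr.sigma > 0 else 1.0
            data[i, j] = base * fold * noise
    df = pd.DataFrame(data, index=genes, columns=samples)
    return ExpressionMatrix(df, sample_map, species=species)
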