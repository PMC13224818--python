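"""The synthetic gene-family generator: determinism, event-log replay,
placement semantics, and planted-truth recovery surfaces."""

import numpy as np
import pytest

from nodufam import (
    DEFAULT_SPECIES_TREE,
    ExpressionTruth,
    SimConfig,
    classify_clade_pair,
    default_species_config,
    detect_legume_clades,
    gene_bias,
    local_paralog_pairs,
    replay_event_log,
    simulate_expression,
    simulate_family,
    tissue_profile,
    truth_pairs,
    truth_report,
)


class TestSpeciesTree:
    def test_eighteen_leaves_matching_config(self, config):
        leaves = DEFAULT_SPECIES_TREE.leaves()
        assert len(leaves) == 18
        assert set(leaves) == set(config.codes)

    def test_legume_block_contiguous(self, config):
        flags = [config.is_legume(c) for c in DEFAULT_SPECIES_TREE.leaves()]
        # one switch from non-legume to legume, none back
        switches = sum(a != b for a, b in zip(flags, flags[1:]))
        assert switches == 1

    def test_named_nodes_resolve(self):
        for name in ("root", "nfnc", "fabales", "legumes", "papilionoideae"):
            assert DEFAULT_SPECIES_TREE.find(name) is not None


class TestSimulateFamily:
    def test_no_events_one_gene_per_species(self, config):
        fam = simulate_family(SimConfig(seed=1), "plain")
        assert len(fam.tree) == 18
        codes = [g.split(".")[0] for g in fam.tree.leaf_order]
        assert codes == DEFAULT_SPECIES_TREE.leaves()
        assert len(detect_legume_clades(fam.tree, config, "permissive")) == 1

    def test_fixed_seed_byte_identical(self):
        a = simulate_family(SimConfig(tandem_rate=0.1, loss_rate=0.1, seed=9), "d")
        b = simulate_family(SimConfig(tandem_rate=0.1, loss_rate=0.1, seed=9), "d")
        assert a.tree.newick == b.tree.newick
        assert a.records == b.records
        assert a.log == b.log

    def test_wgd_at_pap_ancestor(self, config):
        fam = simulate_family(
            SimConfig(wgd_events={"papilionoideae": 1.0}, seed=2), "pap"
        )
        pap = {"glyma", "medtr", "phavu", "lotja", "aesev"}
        by_sp = {}
        for rec in fam.records:
            by_sp.setdefault(rec.species, []).append(rec)
        for sp in pap:
            recs = by_sp[sp]
            assert len(recs) == 2
            assert recs[0].chromosome != recs[1].chromosome
        # non-papilionoid species keep a single copy
        assert all(len(by_sp[sp]) == 1 for sp in by_sp if sp not in pap)
        # the two WGD-derived groups classify as segmental
        from nodufam import LegumeClade, species_of_gene

        sides = {0: [], 1: []}
        for g in fam.tree.leaf_order:
            side = fam.wgd_side[g].get("WGD@papilionoideae")
            if side is not None:
                sides[side].append(g)
        clades = [
            LegumeClade(
                index=i + 1,
                members=m,
                species_present={species_of_gene(g, config).code for g in m},
            )
            for i, m in sides.items()
        ]
        call = classify_clade_pair(clades[0], clades[1], fam.record_map, config)
        assert call.call == "segmental"

    def test_pre_legume_wgd_yields_two_clades(self, wgd_family, config):
        clades = detect_legume_clades(wgd_family.tree, config, "permissive")
        assert len(clades) == 2
        # full retention: each clade carries all 12 legume species
        assert all(len(c.species_present) == 12 for c in clades)

    def test_partial_wgd_retention_drops_copies(self, config):
        fam = simulate_family(
            SimConfig(wgd_events={"nfnc": 0.5}, seed=13), "ret"
        )
        full = simulate_family(
            SimConfig(wgd_events={"nfnc": 1.0}, seed=13), "full"
        )
        assert len(fam.tree) < len(full.tree)
        assert any(e.etype == "loss" for e in fam.log)

    def test_tandem_copy_adjacent_same_chromosome(self):
        fam = simulate_family(SimConfig(tandem_rate=0.15, seed=4), "t")
        events = [e for e in fam.log if e.etype == "tandem"]
        assert events
        # child placed on the parent's chromosome at a neighbouring slot
        lineage_place = {
            e.child: e.placement for e in fam.log if e.placement is not None
        }
        for ev in events:
            chrom, slot = ev.placement
            assert any(
                p == (chrom, slot - 1) or p == (chrom, slot + 1)
                for p in lineage_place.values()
            )

    def test_runaway_guard(self):
        with pytest.raises(RuntimeError, match="runaway"):
            simulate_family(
                SimConfig(tandem_rate=1.0, proximal_rate=1.0, seed=1), "boom"
            )

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(tandem_rate=1.5)
        with pytest.raises(ValueError):
            SimConfig(wgd_events={"nosuchnode": 1.0})


class TestEventLogReplay:
    @pytest.mark.parametrize("kwargs", [
        dict(tandem_rate=0.1, proximal_rate=0.05),
        dict(wgd_events={"nfnc": 0.7}, loss_rate=0.1),
        dict(ancient_local=("fabales", 6)),
    ])
    def test_replay_reconstructs_gene_set(self, kwargs):
        fam = simulate_family(SimConfig(seed=17, **kwargs), "re")
        assert replay_event_log(fam.log) == fam.placements

    def test_inconsistent_log_detected(self):
        fam = simulate_family(SimConfig(seed=1), "bad")
        from nodufam.simulate import SimEvent

        gene_ev = next(e for e in fam.log if e.etype == "gene")
        corrupted = [
            SimEvent("loss", gene_ev.node, gene_ev.parent, gene_ev.parent)
            if e is gene_ev else e
            for e in fam.log
        ] + [gene_ev]
        with pytest.raises(ValueError, match="lost lineage"):
            replay_event_log(corrupted)


class TestTruthReport:
    def test_loss_free_recall_one(self):
        fam = simulate_family(
            SimConfig(tandem_rate=0.1, proximal_rate=0.05, seed=8), "tp"
        )
        report = truth_report(fam, local_paralog_pairs(fam.records))
        assert report["tandem_recall"] == 1.0
        assert report["tandem_precision"] == 1.0
        assert report["proximal_recall"] == 1.0
        assert report["proximal_precision"] == 1.0

    def test_empty_calls_zero_recall(self):
        fam = simulate_family(SimConfig(tandem_rate=0.15, seed=4), "t")
        assert any(p.relation == "tandem" for p in truth_pairs(fam))
        report = truth_report(fam, [])
        assert report["tandem_recall"] == 0.0

    def test_lossy_regime_recall_not_above_one(self):
        fam = simulate_family(
            SimConfig(tandem_rate=0.1, loss_rate=0.2, seed=19), "lossy"
        )
        report = truth_report(fam, local_paralog_pairs(fam.records))
        assert 0.0 <= report["tandem_recall"] <= 1.0


class TestSimulateExpression:
    def truth(self, genes, fold, sigma):
        labels = ["nodule", "root", "shoot", "neutral"]
        return {
            g: ExpressionTruth(label=labels[i % 4], fold=fold, sigma=sigma)
            for i, g in enumerate(genes)
        }

    def recovery(self, n, fold, sigma, seed):
        genes = [f"medtr.g{i:04d}" for i in range(n)]
        truth = self.truth(genes, fold, sigma)
        matrix = simulate_expression(
            genes, truth, rng=np.random.default_rng(seed)
        )
        hits = sum(
            gene_bias(tissue_profile(matrix, g)) == truth[g].label
            for g in genes
        )
        return hits / n

    def test_noise_free_recovery_exact(self):
        assert self.recovery(200, fold=4.0, sigma=0.0, seed=1) == 1.0

    def test_neutral_genes_stay_neutral_noise_free(self):
        genes = ["medtr.g1", "medtr.g2"]
        truth = {g: ExpressionTruth(label="neutral", sigma=0.0) for g in genes}
        matrix = simulate_expression(genes, truth, rng=np.random.default_rng(3))
        assert all(
            gene_bias(tissue_profile(matrix, g)) == "neutral" for g in genes
        )

    def test_recovery_monotone_in_noise_and_fold(self):
        # expected recovery falls with sigma and rises with planted fold
        r_low = self.recovery(300, fold=4.0, sigma=0.1, seed=5)
        r_high = self.recovery(300, fold=4.0, sigma=0.8, seed=5)
        assert r_low >= r_high
        r_weak = self.recovery(300, fold=2.0, sigma=0.4, seed=6)
        r_strong = self.recovery(300, fold=8.0, sigma=0.4, seed=6)
        assert r_strong >= r_weak

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTruth(label="nodule", sigma=-0.1)

    def test_missing_truth_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(["medtr.g1"], {})
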