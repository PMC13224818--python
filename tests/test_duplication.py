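"""Positional paralog typing, clade-pair origin calls, and the ancient
local-duplication rule."""

import pytest

from nodufam import (
    GeneRecord,
    GeneTree,
    LegumeClade,
    classify_clade_pair,
    detect_ancient_local,
    family_dup_summary,
    genes_with_local_paralog,
    local_paralog_pairs,
    SimConfig,
    simulate_family,
)
from nodufam.clades import detect_legume_clades


def rec(gene_id, chrom, start, ordinal, species="medtr"):
    return GeneRecord(gene_id, species, chrom, start, start + 1000, ordinal=ordinal)


class TestPairRelations:
    @pytest.mark.parametrize(
        "rec_b, expected",
        [
            (rec("g2", "chr1", 600_000, 11), "tandem"),  # adjacent, <=1 Mb
            (rec("g2", "chr1", 900_000, 14), "proximal"),  # <=1 Mb, not adjacent
            (rec("g2", "chr2", 150_000, 2), "distal"),  # different chromosome
            (rec("g2", "chr1", 1_100_001, 11), "distal"),  # adjacent but >1 Mb
        ],
    )
    def test_relation_rules(self, rec_b, expected):
        (pair,) = local_paralog_pairs([rec("g1", "chr1", 100_000, 10), rec_b])
        assert pair.relation == expected

    def test_exactly_one_relation_per_pair(self):
        records = [
            rec("g1", "chr1", 100_000, 10),
            rec("g2", "chr1", 150_000, 11),
            rec("g3", "chr1", 800_000, 20),
            rec("g4", "chr2", 100_000, 5),
        ]
        pairs = local_paralog_pairs(records)
        assert len(pairs) == 6  # every unordered same-species pair
        assert all(p.relation in {"tandem", "proximal", "distal"} for p in pairs)

    def test_cross_species_pairs_not_formed(self):
        records = [
            rec("medtr.g1", "chr1", 100_000, 1, "medtr"),
            rec("glyma.g1", "chr1", 120_000, 2, "glyma"),
        ]
        assert local_paralog_pairs(records) == []

    def test_within_family_adjacency_variant(self):
        # g1..g3 on one chromosome; g2 (another family member) sits between
        # g1 and g3 so genome-adjacency differs from family-adjacency
        records = [
            rec("g1", "chr1", 100_000, 10),
            rec("g3", "chr1", 200_000, 14),
        ]
        (genome_pair,) = local_paralog_pairs(records, adjacency="genome")
        assert genome_pair.relation == "proximal"
        (family_pair,) = local_paralog_pairs(records, adjacency="within-family")
        assert family_pair.relation == "tandem"

    def test_missing_ordinal_excluded_with_warning(self, caplog):
        records = [
            rec("g1", "chr1", 100_000, 10),
            GeneRecord("g2", "medtr", "chr1", 150_000, 151_000),
        ]
        with caplog.at_level("WARNING"):
            pairs = local_paralog_pairs(records)
        assert pairs == []
        assert "no ordinal" in caplog.text


class TestGenesWithLocalParalog:
    def test_local_only(self):
        records = [
            rec("g1", "chr1", 100_000, 10),
            rec("g2", "chr1", 150_000, 11),
            rec("g3", "chr2", 100_000, 1),
            rec("g4", "chr3", 100_000, 1),
        ]
        pairs = local_paralog_pairs(records)
        assert genes_with_local_paralog(pairs) == {"g1", "g2"}

    def test_symmetric_membership(self):
        pairs = local_paralog_pairs(
            [rec("g1", "chr1", 100_000, 1), rec("g2", "chr1", 200_000, 2)]
        )
        local = genes_with_local_paralog(pairs)
        assert {"g1", "g2"} <= local

    def test_empty(self):
        assert genes_with_local_paralog([]) == set()

    def test_planted_tandems_recovered_exactly(self, config):
        fam = simulate_family(
            SimConfig(tandem_rate=0.08, seed=11), "tandems"
        )
        tandem_events = [e for e in fam.log if e.etype == "tandem"]
        assert tandem_events  # regime sanity
        pairs = local_paralog_pairs(fam.records)
        local = genes_with_local_paralog(pairs)
        # loss-free: local genes are exactly those whose slot has a
        # within-window neighbour in the truth layout
        from nodufam import truth_pairs

        expected = genes_with_local_paralog(truth_pairs(fam))
        assert local == expected


def clade(index, members, config):
    from nodufam import species_of_gene

    return LegumeClade(
        index=index,
        members=list(members),
        species_present={species_of_gene(m, config).code for m in members},
    )


class TestCladePairCalls:
    def test_different_chromosomes_segmental(self, config):
        a = clade(1, ["medtr.a1", "glyma.a2"], config)
        b = clade(2, ["medtr.b1", "glyma.b2"], config)
        records = {
            "medtr.a1": rec("medtr.a1", "chr1", 100_000, 1, "medtr"),
            "medtr.b1": rec("medtr.b1", "chr2", 100_000, 1, "medtr"),
            "glyma.a2": rec("glyma.a2", "chr1", 100_000, 1, "glyma"),
            "glyma.b2": rec("glyma.b2", "chr3", 100_000, 1, "glyma"),
        }
        call = classify_clade_pair(a, b, records, config)
        assert call.call == "segmental"
        assert call.local_support_species == set()

    def test_single_within_window_pair_local(self, config):
        a = clade(1, ["medtr.a1"], config)
        b = clade(2, ["medtr.b1"], config)
        records = {
            "medtr.a1": rec("medtr.a1", "chr1", 100_000, 1, "medtr"),
            "medtr.b1": rec("medtr.b1", "chr1", 150_000, 2, "medtr"),
        }
        call = classify_clade_pair(a, b, records, config, min_local_species=1)
        assert call.call == "local"
        assert call.local_support_species == {"medtr"}

    def test_no_shared_species_undefined(self, config, caplog):
        a = clade(1, ["medtr.a1"], config)
        b = clade(2, ["glyma.b1"], config)
        with caplog.at_level("WARNING"):
            call = classify_clade_pair(a, b, {}, config)
        assert call.call is None
        assert call.shared_species == set()

    def test_planted_wgd_called_segmental(self, wgd_family, config):
        clades = detect_legume_clades(wgd_family.tree, config, "permissive")
        assert len(clades) == 2
        call = classify_clade_pair(
            clades[0], clades[1], wgd_family.record_map, config
        )
        assert call.call == "segmental"
        assert len(call.shared_species) == 12


class TestAncientLocal:
    def simulate(self, retained, seed=21):
        return simulate_family(
            SimConfig(ancient_local=("fabales", retained), seed=seed), "anc"
        )

    def test_retained_in_seven_species_is_ancient(self, config):
        fam = self.simulate(7)
        call = detect_ancient_local(fam.tree, fam.record_map, config)
        assert call.is_ancient
        assert len(call.supporting_species) == 7

    def test_retained_in_five_species_not_ancient(self, config):
        fam = self.simulate(5)
        call = detect_ancient_local(fam.tree, fam.record_map, config)
        assert not call.is_ancient
        assert len(call.supporting_species) == 5

    def test_monotone_in_min_species(self, config):
        fam = self.simulate(7)
        flags = [
            detect_ancient_local(
                fam.tree, fam.record_map, config, min_species=m
            ).is_ancient
            for m in range(1, 14)
        ]
        # once False, stays False as the threshold rises
        assert flags == sorted(flags, reverse=True)

    def test_fewer_than_two_strict_clades_negative(self, config):
        fam = simulate_family(SimConfig(seed=3), "plain")
        call = detect_ancient_local(fam.tree, fam.record_map, config)
        assert not call.is_ancient
        assert call.supporting_species == set()


class TestFamilyDupSummary:
    def test_rollups(self, config):
        fams = [
            simulate_family(SimConfig(tandem_rate=0.2, seed=s), f"f{s}")
            for s in (31, 32)
        ] + [simulate_family(SimConfig(seed=33), "f33")]
        trees = [f.tree for f in fams]
        recs = {f.superfamily_id: f.records for f in fams}
        table, rollups = family_dup_summary(trees, recs, config)
        assert rollups["n_families"] == 3
        assert rollups["n_families_with_local"] == int(table["has_local"].sum())
        assert rollups["total_genes"] == sum(len(t) for t in trees)
        # the event-free family has no local pairs
        assert not table.set_index("superfamily_id").loc["f33", "has_local"]

    def test_family_without_coordinates_flagged(self, config, caplog):
        fam = simulate_family(SimConfig(seed=5), "nocoord")
        with caplog.at_level("WARNING"):
            table, rollups = family_dup_summary([fam.tree], {}, config)
        assert not table.iloc[0]["has_local"]
        assert "no coordinates" in caplog.text
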