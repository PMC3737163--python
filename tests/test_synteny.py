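"""Gene-order synteny: breakpoints, reciprocal events, ancestry, arrays."""

import pytest

from ashcomp.io_formats import GeneModel
from ashcomp.simulate import derive_species, generate_ancestor
from ashcomp.synteny import (GeneOrder, build_gene_orders, classify_ancestry,
                             compare_arrays, count_events, find_breakpoints,
                             find_tandem_arrays)

from conftest import small_config


def genes_on(chrom, ids, start=100, spacing=1_000):
    out = []
    for i, gid in enumerate(ids):
        s = start + i * spacing
        out.append(GeneModel(gid, chrom, s, s + 500, "+", "CDS"))
    return out


def order_of(*chrom_ids):
    """GeneOrder from {chrom: [ids]} pairs."""
    chroms = {}
    for chrom, ids in chrom_ids:
        chroms[chrom] = [(g, "+") for g in ids]
    return GeneOrder("x", chroms)


def identity_mapping(*id_lists):
    ids = [g for lst in id_lists for g in lst]
    return {g: g for g in ids}


class TestBuildOrders:
    def test_identity(self):
        ann = genes_on("chr1", ["a", "b", "c"])
        rows = [("a", "a", None), ("b", "b", None), ("c", "c", None)]
        oa, ob, mapping = build_gene_orders(ann, ann, rows)
        assert oa.chromosomes == ob.chromosomes
        assert mapping == {"a": "a", "b": "b", "c": "c"}
        assert oa.flagged_unmapped == set()

    def test_unmapped_gene_flagged(self):
        ann = genes_on("chr1", ["a", "b", "c"])
        rows = [("a", "a", None), ("c", "c", None)]
        oa, _ob, mapping = build_gene_orders(ann, ann, rows)
        assert "b" in oa.flagged_unmapped
        assert "b" not in mapping

    def test_renamed_pair_handled_through_mapping(self):
        # swapped names on one side are purely a mapping concern
        a = genes_on("chr1", ["x1", "x2", "x3"])
        b = genes_on("chr1", ["y2", "y1", "y3"])
        rows = [("x1", "y2", None), ("x2", "y1", None), ("x3", "y3", None)]
        oa, ob, mapping = build_gene_orders(a, b, rows)
        bps = find_breakpoints(oa, ob, mapping)
        assert bps == []  # adjacency is preserved under the mapping

    def test_absent_gene_rejected(self):
        ann = genes_on("chr1", ["a"])
        with pytest.raises(ValueError, match="absent"):
            build_gene_orders(ann, ann, [("ghost", "a", None)])


class TestBreakpoints:
    def test_identical_orders_empty(self):
        o = order_of(("chr1", ["g1", "g2", "g3"]))
        assert find_breakpoints(o, o, identity_mapping(["g1", "g2", "g3"])) == []

    def test_reciprocal_exchange_two_breakpoints_one_event(self):
        # brute-force adjacency oracle for the constructed instance:
        # A: chr1=[g1..g5], chr2=[g6..g10]
        # B: chr1=[g1,g2,g8,g9,g10], chr2=[g6,g7,g3,g4,g5]
        a = order_of(("chr1", [f"g{i}" for i in range(1, 6)]),
                     ("chr2", [f"g{i}" for i in range(6, 11)]))
        b = order_of(("chr1", ["g1", "g2", "g8", "g9", "g10"]),
                     ("chr2", ["g6", "g7", "g3", "g4", "g5"]))
        mapping = identity_mapping([f"g{i}" for i in range(1, 11)])
        bps = find_breakpoints(a, b, mapping)
        flanks = {(bp.left_gene, bp.right_gene) for bp in bps}
        assert flanks == {("g2", "g3"), ("g7", "g8")}
        assert count_events(bps) == 1
        assert all(bp.type == "reciprocal" for bp in bps)

    def test_reversal_symmetry(self):
        a = order_of(("chr1", [f"g{i}" for i in range(1, 6)]),
                     ("chr2", [f"g{i}" for i in range(6, 11)]))
        b = order_of(("chr1", ["g1", "g2", "g8", "g9", "g10"]),
                     ("chr2", ["g6", "g7", "g3", "g4", "g5"]))
        mapping = identity_mapping([f"g{i}" for i in range(1, 11)])
        fwd = find_breakpoints(a, b, mapping)
        rev = find_breakpoints(b, a, {v: k for k, v in mapping.items()})
        assert count_events(fwd) == count_events(rev)

    def test_planted_translocations_recovered_20_replicates(self):
        """Every planted reciprocal flank pair is recovered exactly, across
        20 seeded simulated species pairs."""
        for seed in range(20):
            cfg = small_config(seed=100 + seed, n_chromosomes=3,
                               chrom_length=30_000,
                               tandem_events=[("famCWP1", 4, 4), ("famRAI1", 2, 1)])
            anc = generate_ancestor(cfg)
            species, truth = derive_species(anc, cfg)
            rows = [(g.gene_id, g.gene_id, None) for g in species.genes
                    if g.gene_id.startswith("g")]
            o_sp, o_anc, mapping = build_gene_orders(species.genes, anc.genes, rows)
            bps = find_breakpoints(o_sp, o_anc, mapping)
            called = {(bp.left_gene, bp.right_gene) for bp in bps}
            planted = {(bp[1], bp[2]) for bp in truth.breakpoints}
            assert called == planted, f"seed {100 + seed}"
            assert count_events(bps) == cfg.n_translocations


class TestAncestry:
    def _setup(self):
        a = order_of(("chr1", [f"g{i}" for i in range(1, 6)]),
                     ("chr2", [f"g{i}" for i in range(6, 11)]))
        b = order_of(("chr1", ["g1", "g2", "g8", "g9", "g10"]),
                     ("chr2", ["g6", "g7", "g3", "g4", "g5"]))
        mapping = identity_mapping([f"g{i}" for i in range(1, 11)])
        return a, b, mapping

    def test_outgroup_matches_a(self):
        a, b, mapping = self._setup()
        outgroup = order_of(("c1", [f"g{i}" for i in range(1, 6)]),
                            ("c2", [f"g{i}" for i in range(6, 11)]))
        bps = find_breakpoints(a, b, mapping)
        classify_ancestry(bps, a, b, mapping, outgroup, mapping)
        assert all(bp.ancestry == "A_ancestral" for bp in bps)

    def test_outgroup_matches_b(self):
        a, b, mapping = self._setup()
        outgroup = order_of(("c1", ["g1", "g2", "g8", "g9", "g10"]),
                            ("c2", ["g6", "g7", "g3", "g4", "g5"]))
        bps = find_breakpoints(a, b, mapping)
        classify_ancestry(bps, a, b, mapping, outgroup, mapping)
        assert all(bp.ancestry == "B_ancestral" for bp in bps)

    def test_missing_flanks_unclear(self):
        a, b, mapping = self._setup()
        outgroup = order_of(("c1", ["g1", "g10"]))
        og_map = {"g1": "g1", "g10": "g10"}
        bps = find_breakpoints(a, b, mapping)
        classify_ancestry(bps, a, b, mapping, outgroup, og_map)
        assert all(bp.ancestry == "unclear" for bp in bps)

    def test_simulated_ancestor_as_outgroup(self, ancestor, species_pair, sim_config):
        """With the untouched ancestor as outgroup, every planted event is
        labelled with the derived genome correct (the species derived)."""
        species, _truth = species_pair
        rows = [(g.gene_id, g.gene_id, None) for g in species.genes
                if g.gene_id.startswith("g")]
        o_sp, o_anc, mapping = build_gene_orders(species.genes, ancestor.genes, rows)
        bps = find_breakpoints(o_sp, o_anc, mapping)
        og = GeneOrder("outgroup", {c: [(g.gene_id, g.strand) for g in
                                        sorted((x for x in ancestor.genes
                                                if x.chromosome == c),
                                               key=lambda x: x.start)]
                                    for c in {g.chromosome for g in ancestor.genes}})
        og_map = {g.gene_id: g.gene_id for g in ancestor.genes}
        classify_ancestry(bps, o_sp, o_anc, mapping, og, og_map)
        # genome A here is the species: its adjacencies are derived, so the
        # outgroup supports B (the ancestor-like strain order)
        assert all(bp.ancestry == "B_ancestral" for bp in bps)


class TestTandemArrays:
    def test_four_adjacent_copies(self):
        ann = genes_on("chr1", ["n1", "f1", "f2", "f3", "f4", "n2"])
        fams = {"f1": "CWP1", "f2": "CWP1", "f3": "CWP1", "f4": "CWP1"}
        [arr] = find_tandem_arrays(ann, fams)
        assert arr.copy_count == 4
        assert arr.member_gene_ids == ["f1", "f2", "f3", "f4"]

    def test_no_duplications_empty(self):
        ann = genes_on("chr1", ["a", "b"])
        assert find_tandem_arrays(ann, {"a": "F1", "b": "F2"}) == []

    def test_intervening_gene_tolerated_but_not_two(self):
        ann = genes_on("chr1", ["f1", "x", "f2", "y", "z", "f3"])
        fams = {"f1": "F", "f2": "F", "f3": "F"}
        [arr] = find_tandem_arrays(ann, fams, max_intervening=1)
        assert arr.member_gene_ids == ["f1", "f2"]  # f3 is two genes away

    def test_array_maximality(self, ancestor, sim_config):
        fams = {g.gene_id: g.ortholog_label for g in ancestor.genes
                if g.ortholog_label and g.ortholog_label.startswith("fam")}
        arrays = find_tandem_arrays(ancestor.genes, fams, genome=ancestor)
        by_chrom = {}
        for g in sorted(ancestor.genes, key=lambda g: (g.chromosome, g.start)):
            by_chrom.setdefault(g.chromosome, []).append(g)
        for arr in arrays:
            genes = by_chrom[arr.chromosome]
            idx = [i for i, g in enumerate(genes)
                   if g.gene_id in arr.member_gene_ids]
            lo, hi = min(idx), max(idx)
            if lo > 0:
                assert fams.get(genes[lo - 1].gene_id) != arr.family_label
            if hi < len(genes) - 1:
                assert fams.get(genes[hi + 1].gene_id) != arr.family_label
            assert arr.min_pairwise_identity > 0.9

    def test_planted_copy_numbers_recovered(self, ancestor, species_pair, sim_config):
        species, _ = species_pair
        fams_a = {g.gene_id: g.ortholog_label for g in ancestor.genes
                  if g.ortholog_label and g.ortholog_label.startswith("fam")}
        fams_b = {g.gene_id: g.ortholog_label for g in species.genes
                  if g.ortholog_label and g.ortholog_label.startswith("fam")}
        arr_a = find_tandem_arrays(ancestor.genes, fams_a)
        arr_b = find_tandem_arrays(species.genes, fams_b)
        table = {fam: (ca, cb) for fam, ca, cb, _d in
                 compare_arrays(arr_a, arr_b, fams_a, fams_b)}
        for fam, ca, cb in sim_config.tandem_events:
            assert table[fam] == (ca, cb), fam

    def test_compare_arrays_differs_flag(self):
        a = genes_on("chr1", ["f1", "f2", "f3", "f4"])
        fams_a = {g.gene_id: "FAM" for g in a}
        arr_a = find_tandem_arrays(a, fams_a)
        table = compare_arrays(arr_a, [], fams_a, {})
        assert table == [("FAM", 4, 0, True)]
        same = compare_arrays(arr_a, arr_a, fams_a, fams_a)
        assert same == [("FAM", 4, 4, False)]
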