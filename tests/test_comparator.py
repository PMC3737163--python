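"""Genome comparison: alignment, variant calling, windows, introgression."""

import numpy as np
import pytest

from ashcomp.comparator import (align_genomes, align_pair, call_variants,
                                classify_coding, detect_introgression,
                                find_identical_segments, identity_track,
                                snp_class_of, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)
from ashcomp.io_formats import AnnotatedGenome, GeneModel, SeqRecord
from ashcomp.pipeline import score_variants
from ashcomp.simulate import random_dna


def genome_of(seq, name="G", chrom="chr1", genes=()):
    return AnnotatedGenome([SeqRecord(chrom, seq)], list(genes), name)


def nw_affine_score(a, b):
    """Independent Needleman-Wunsch with affine gaps: gap of length k costs
    GAP_OPEN + (k-1)*GAP_EXTEND; straightforward O(nm) three-state DP."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + GAP_OPEN, X[i - 1][j] + GAP_EXTEND,
                          Y[i - 1][j] + GAP_OPEN)
            Y[i][j] = max(M[i][j - 1] + GAP_OPEN, Y[i][j - 1] + GAP_EXTEND,
                          X[i][j - 1] + GAP_OPEN)
    return max(M[n][m], X[n][m], Y[n][m])


def alignment_score(ra, rb):
    score = 0.0
    in_gap = False
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            score += GAP_EXTEND if in_gap else GAP_OPEN
            in_gap = True
        else:
            score += MATCH if x == y else MISMATCH
            in_gap = False
    return score


class TestAlignPair:
    def test_identical(self):
        assert align_pair("ACGT", "ACGT") == ("ACGT", "ACGT")

    def test_single_snp_one_mismatch_column(self):
        ra, rb = align_pair("ACGTACGT", "ACGAACGT")
        assert "-" not in ra and "-" not in rb
        assert sum(1 for x, y in zip(ra, rb) if x != y) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_dp_oracle_on_random_spans(self, seed):
        """Production alignment scores equal an independent affine-gap DP."""
        rng = np.random.default_rng(seed)
        a = random_dna(rng, int(rng.integers(50, 200)), 0.5)
        b = list(a)
        # mutate: a few substitutions and a small indel
        for _ in range(5):
            i = int(rng.integers(0, len(b)))
            b[i] = "ACGT"[int(rng.integers(0, 4))]
        i = int(rng.integers(0, len(b) - 6))
        del b[i:i + int(rng.integers(1, 5))]
        b = "".join(b)
        ra, rb = align_pair(a, b)
        assert ra.replace("-", "") == a
        assert rb.replace("-", "") == b
        assert alignment_score(ra, rb) == nw_affine_score(a, b)


class TestAlignGenomes:
    def test_identical_genomes_single_clean_block(self, rng):
        seq = random_dna(rng, 10_000, 0.5)
        aln = align_genomes(genome_of(seq, "A"), genome_of(seq, "B"))
        [chrom] = aln.chromosomes
        assert chrom.unaligned == []
        total = sum(1 for b in chrom.blocks
                    for x, y in zip(b.a_aln, b.b_aln) if x == y)
        assert total == 10_000

    def test_no_anchors_reported_unaligned(self, rng):
        a = random_dna(rng, 2_000, 0.5)
        b = random_dna(np.random.default_rng(999), 2_000, 0.5)
        aln = align_genomes(genome_of(a, "A"), genome_of(b, "B"))
        assert aln.chromosomes[0].unaligned == [(1, 2_000)]


class TestCallVariants:
    def test_single_snp(self, rng):
        seq = random_dna(rng, 3_000, 0.5)
        alt = seq[:1500] + ("A" if seq[1500] != "A" else "C") + seq[1501:]
        aln = align_genomes(genome_of(seq, "A"), genome_of(alt, "B"))
        variants = call_variants(aln, genome_of(seq, "A"))
        assert len(variants) == 1
        v = variants[0]
        assert (v.position, v.type) == (1501, "SNP")
        assert v.ref_allele == seq[1500]

    def test_multibase_deletion_single_event(self, rng):
        seq = random_dna(rng, 3_000, 0.5)
        alt = seq[:1500] + seq[1504:]  # 4-base deletion in B
        aln = align_genomes(genome_of(seq, "A"), genome_of(alt, "B"))
        variants = call_variants(aln, genome_of(seq, "A"))
        assert len(variants) == 1
        assert variants[0].type == "deletion"
        assert variants[0].length == 4

    def test_identical_inputs_no_variants(self, rng):
        seq = random_dna(rng, 2_000, 0.5)
        aln = align_genomes(genome_of(seq, "A"), genome_of(seq, "B"))
        assert call_variants(aln) == []

    def test_transition_transversion_partition(self, strain_pair):
        strain_a, strain_b, _ = strain_pair
        aln = align_genomes(strain_a, strain_b)
        variants = call_variants(aln, strain_a)
        snps = [v for v in variants if v.type == "SNP"]
        ti = sum(1 for v in snps if v.snp_class == "transition")
        tv = sum(1 for v in snps if v.snp_class == "transversion")
        assert ti + tv == len(snps)
        assert ti > tv  # simulator substitutes with a transition bias

    def test_planted_variant_recovery_exact(self, strain_pair):
        """Criterion-level check on the session fixture: precision=recall=1."""
        strain_a, strain_b, truth = strain_pair
        aln = align_genomes(strain_a, strain_b)
        variants = call_variants(aln, strain_a)
        sp, sr, ip, ir = score_variants(variants, truth)
        assert (sp, sr, ip, ir) == (1.0, 1.0, 1.0, 1.0)


def nine_codon_gene(strand):
    """A constructed CDS on either strand for strand-aware classification."""
    # mRNA-sense CDS: ATG GCT GCA AAA CCC GGG TTT AGA TAA (9 codons)
    sense = "ATGGCTGCAAAACCCGGGTTTAGATAA"
    from ashcomp.io_formats import revcomp
    pad5, pad3 = "ACGTACGTAC", "TGCATGCATG"
    if strand == "+":
        seq = pad5 + sense + pad3
    else:
        seq = pad5 + revcomp(sense) + pad3
    gene = GeneModel("g1", "chr1", 11, 10 + len(sense), strand, "CDS")
    return seq, gene


class TestClassifyCoding:
    def _classify_one(self, seq, gene, pos, alt):
        from ashcomp.comparator import Variant
        g = genome_of(seq, genes=[gene])
        v = Variant("chr1", pos, seq[pos - 1], alt, "SNP")
        classify_coding([v], [gene], g)
        return v

    def test_synonymous_third_position(self):
        seq, gene = nine_codon_gene("+")
        # codon 2 GCT -> GCC  (Ala -> Ala); genomic position 11+5
        v = self._classify_one(seq, gene, 16, "C")
        assert v.coding_class == "synonymous"

    def test_nonsynonymous_second_position(self):
        seq, gene = nine_codon_gene("+")
        # codon 2 GCT -> GAT (Ala -> Asp)
        v = self._classify_one(seq, gene, 15, "A")
        assert v.coding_class == "nonsynonymous"

    def test_minus_strand_classified_in_mrna_sense(self):
        seq, gene = nine_codon_gene("-")
        # the gene occupies 11..37; mRNA codon 2 GCT third base maps to
        # genomic position 37 - 5 = 32 on the - strand; alt G (genomic)
        # reads C in mRNA: GCT -> GCC, synonymous
        v = self._classify_one(seq, gene, 32, "G")
        assert v.coding_class == "synonymous"

    def test_noncoding_and_frame_flag(self):
        seq, gene = nine_codon_gene("+")
        v = self._classify_one(seq, gene, 3, "A" if seq[2] != "A" else "C")
        assert v.coding_class == "noncoding"
        bad = GeneModel("g2", "chr1", 11, 14, "+", "CDS")  # length 4, not /3
        v2 = self._classify_one(seq, bad, 12, "A" if seq[11] != "A" else "C")
        assert v2.coding_class == "NA"

    def test_partition_identity_on_simulated_pair(self, strain_pair):
        strain_a, strain_b, _ = strain_pair
        aln = align_genomes(strain_a, strain_b)
        variants = call_variants(aln, strain_a)
        classify_coding(variants, strain_a.genes, strain_a)
        snps = [v for v in variants if v.type == "SNP"]
        counts = {}
        for v in snps:
            counts[v.coding_class] = counts.get(v.coding_class, 0) + 1
        assert sum(counts.values()) == len(snps)
        assert set(counts) <= {"synonymous", "nonsynonymous", "noncoding", "NA"}


class TestIdentityTrack:
    def test_identical_genomes_all_ones(self, rng):
        seq = random_dna(rng, 3_000, 0.5)
        aln = align_genomes(genome_of(seq, "A"), genome_of(seq, "B"))
        track = identity_track(aln, 1_000)
        assert all(w.identity == 1.0 for w in track)

    def test_one_snp_window_arithmetic(self, rng):
        seq = random_dna(rng, 2_000, 0.5)
        alt = seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:]
        aln = align_genomes(genome_of(seq, "A"), genome_of(alt, "B"))
        track = identity_track(aln, 1_000)
        assert track[0].identity == pytest.approx(0.999)
        assert track[1].identity == 1.0

    def test_window_conservation(self, strain_pair):
        strain_a, strain_b, _ = strain_pair
        aln = align_genomes(strain_a, strain_b)
        track = identity_track(aln, 1_000)
        win_matches = sum(w.matches for w in track)
        aln_matches = sum(1 for ch in aln.chromosomes for b in ch.blocks
                          for x, y in zip(b.a_aln, b.b_aln)
                          if x == y and x != "-")
        assert win_matches == aln_matches

    def test_background_identity_near_rate(self, strain_pair, sim_config):
        strain_a, strain_b, truth = strain_pair
        aln = align_genomes(strain_a, strain_b)
        track = identity_track(aln, 10_000)
        chrom, s, e = truth.introgression
        background = [w for w in track
                      if not (w.chromosome == chrom and w.start <= e and w.end >= s)]
        mean = np.mean([w.identity for w in background if w.identity is not None])
        assert 0.9985 <= mean <= 0.9999


class TestIntrogression:
    def test_rule_application_on_synthetic_track(self):
        from ashcomp.comparator import IdentityWindow
        windows = []
        idents = [0.999] * 10 + [0.92] * 5 + [0.999] * 10
        for i, ident in enumerate(idents):
            w = IdentityWindow("chr1", i * 1000 + 1, (i + 1) * 1000, 1000,
                               int(round(ident * 1000)))
            windows.append(w)
        segs = detect_introgression(windows)
        assert len(segs) == 1
        assert segs[0].start == 10_001 and segs[0].end == 15_000

    def test_all_windows_passing_empty(self):
        from ashcomp.comparator import IdentityWindow
        windows = [IdentityWindow("chr1", i * 1000 + 1, (i + 1) * 1000, 1000, 999)
                   for i in range(10)]
        assert detect_introgression(windows) == []

    def test_planted_block_recovered(self, strain_pair, sim_config):
        strain_a, strain_b, truth = strain_pair
        aln = align_genomes(strain_a, strain_b)
        variants = call_variants(aln, strain_a)
        classify_coding(variants, strain_a.genes, strain_a)
        track = identity_track(aln, 1_000)
        segs = detect_introgression(track, variants)
        chrom, s, e = truth.introgression
        match = [g for g in segs if g.chromosome == chrom]
        assert len(match) == 1
        seg = match[0]
        assert abs(seg.start - s) <= 1_000 and abs(seg.end - e) <= 1_000
        assert 0.88 <= seg.mean_identity <= 0.95
        io, syn, nsyn = seg.snp_breakdown
        assert io + syn + nsyn == seg.n_snps


class TestIdenticalSegments:
    def test_planted_cross_chromosome_copy(self, rng):
        block = random_dna(rng, 6_000, 0.5)
        c1 = random_dna(rng, 2_000, 0.5) + block
        c3 = block + random_dna(rng, 2_000, 0.5)
        g = AnnotatedGenome([SeqRecord("chr1", c1), SeqRecord("chr2", random_dna(rng, 3_000, 0.5)),
                             SeqRecord("chr3", c3)], [], "G")
        segs = find_identical_segments(g, min_length=5_000)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.length == 6_000
        assert (seg.chromosome_a, seg.chromosome_b) == ("chr1", "chr3")
        assert (seg.start_a, seg.start_b) == (2_001, 1)

    def test_internal_mismatch_splits_segment(self, rng):
        block = random_dna(rng, 12_000, 0.5)
        broken = block[:6_000] + ("A" if block[6_000] != "A" else "C") + block[6_001:]
        g = AnnotatedGenome([SeqRecord("chr1", block), SeqRecord("chr2", broken)], [], "G")
        segs = find_identical_segments(g, min_length=5_000)
        assert len(segs) == 2
        assert all(s.length < 12_000 for s in segs)
        assert {s.length for s in segs} == {6_000, 5_999}

    def test_no_repeats_empty(self, rng):
        g = AnnotatedGenome([SeqRecord("chr1", random_dna(rng, 5_000, 0.5)),
                             SeqRecord("chr2", random_dna(rng, 5_000, 0.5))], [], "G")
        assert find_identical_segments(g, min_length=1_000) == []


def test_snp_class_definition():
    assert snp_class_of("A", "G") == "transition"
    assert snp_class_of("C", "T") == "transition"
    assert snp_class_of("A", "C") == "transversion"
    assert snp_class_of("G", "T") == "transversion"
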