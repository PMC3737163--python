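"""Greedy assembler: packing, collapsing, overlap oracle, reconstruction."""

import numpy as np
import pytest

from ashcomp.assembler import (AssemblerConfig, PackedRead, assemble,
                               detect_branch_points, find_overlaps,
                               initial_contigs, join_contigs, pack_and_collapse,
                               pack_sequence, unpack_sequence, phred_to_class)
from ashcomp.io_formats import revcomp
from ashcomp.simulate import random_dna, stratified_reads


def packed(seq, quals=None):
    quals = quals if quals is not None else [3] * len(seq)
    return [(seq, quals)]


class TestPacking:
    @pytest.mark.parametrize("seq", ["A", "ACGT", "TTTTTTTT", "GATTACA"])
    def test_two_bit_round_trip(self, seq):
        assert unpack_sequence(pack_sequence(seq), len(seq)) == seq

    def test_identical_reads_collapse(self):
        out = pack_and_collapse([("ACGT", [3] * 4), ("ACGT", [3] * 4)])
        assert len(out) == 1
        assert out[0].multiplicity == 2

    def test_reverse_complements_collapse(self):
        out = pack_and_collapse([("ACGT", [3] * 4), (revcomp("ACGT"), [3] * 4)])
        assert len(out) == 1
        assert out[0].multiplicity == 2

    def test_low_quality_difference_merges_to_consensus(self):
        out = pack_and_collapse([("CACGT", [3, 3, 3, 3, 3]),
                                 ("CACGA", [3, 3, 3, 3, 0])])
        assert len(out) == 1
        assert out[0].multiplicity == 2
        assert out[0].sequence in ("CACGT", revcomp("CACGT"))

    def test_high_quality_difference_not_merged(self):
        out = pack_and_collapse([("CACGT", [3] * 5), ("CACGA", [3] * 5)])
        assert len(out) == 2

    def test_nonuniform_length_and_n_rejected(self):
        with pytest.raises(ValueError, match="non-uniform"):
            pack_and_collapse([("ACGT", [3] * 4), ("ACG", [3] * 3)])
        with pytest.raises(ValueError, match="N"):
            pack_and_collapse([("ACNT", [3] * 4)])


class TestOverlapOracle:
    def test_hash_overlaps_equal_brute_force(self, rng):
        """On 50 reads the hashed overlap set equals all-pairs comparison."""
        genome = random_dna(rng, 400, 0.5)
        R = 12
        reads = []
        for _ in range(50):
            s = int(rng.integers(0, len(genome) - R + 1))
            seq = genome[s:s + R]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append((seq, [3] * R))
        packed_reads = pack_and_collapse(reads)
        for L in (R - 1, R - 3, 6):
            hashed = find_overlaps(packed_reads, L)
            words = sorted({w for r in packed_reads
                            for w in (r.sequence, revcomp(r.sequence))})
            brute = {(a, b) for a in words for b in words
                     if a != b and a[-L:] == b[:L]}
            assert hashed == brute


class TestInitialContigs:
    def test_perfect_chain(self):
        reads = [(s, [3] * 6) for s in ("ACGGTC", "CGGTCA", "GGTCAT")]
        asm = initial_contigs(pack_and_collapse(reads), 6)
        assert len(asm.contigs) == 1
        c = asm.contigs[0].sequence
        assert c in ("ACGGTCAT", revcomp("ACGGTCAT"))

    def test_single_read(self):
        asm = initial_contigs(pack_and_collapse(packed("ACGGTC")), 6)
        assert len(asm.contigs) == 1
        assert asm.contigs[0].sequence in ("ACGGTC", revcomp("ACGGTC"))

    def test_empty_input(self):
        asm = initial_contigs([], 6)
        assert asm.contigs == []

    def test_two_haplotypes_branch(self):
        # two haplotypes diverging at one base, each x3 at high quality
        h1 = "AACGTGGATCAA"
        h2 = "AACGAGGATCAA"
        R = 6
        reads = []
        for h in (h1, h2):
            for s in range(len(h) - R + 1):
                for _ in range(3):
                    reads.append((h[s:s + R], [3] * R))
        asm = initial_contigs(pack_and_collapse(reads), R)
        assert len(asm.contigs) >= 2
        assert asm.branch_points, "divergence must be recorded"
        alleles = set()
        for bp in asm.branch_points:
            alleles |= set(bp.alleles)
        assert {"T", "A"} & alleles


class TestBranchPoints:
    def _asm(self, reads, R=6):
        pr = pack_and_collapse(reads)
        return initial_contigs(pr, R), pr

    def test_agreement_no_branch(self):
        reads = [("ACGGTC", [3] * 6)] * 5
        asm, pr = self._asm(reads)
        assert detect_branch_points(asm, pr) == []

    def test_support_threshold_boundary(self):
        base = "CCGGTATA"
        R = 6
        stem = [(base[s:s + R], [3] * R) for s in (0, 1, 2)]
        # extensions past the stem end diverge: T vs A
        ext_t = [("GTATAT", [3] * R)] * 3
        ext_a = [("GTATAA", [3] * R)] * 1  # support 1 < min_branch_support
        asm, pr = self._asm(stem * 3 + ext_t + ext_a)
        bps = detect_branch_points(asm, pr)
        assert bps == []
        # raise the minority support to 2 at high quality: branch appears
        asm2, pr2 = self._asm(stem * 3 + ext_t + ext_a * 2)
        assert detect_branch_points(asm2, pr2)

    def test_low_quality_support_ignored(self):
        base = "CCGGTATA"
        R = 6
        stem = [(base[s:s + R], [3] * R) for s in (0, 1, 2)]
        ext_t = [("GTATAT", [3] * R)] * 3
        ext_a = [("GTATAA", [3, 3, 3, 3, 3, 1])] * 3  # minority allele low quality
        asm, pr = self._asm(stem * 3 + ext_t + ext_a)
        assert detect_branch_points(asm, pr) == []


class TestJoining:
    def test_join_by_25_base_overlap(self, rng):
        genome = random_dna(rng, 200, 0.5)
        left, right = genome[:110], genome[85:]  # 25-base overlap
        asm = initial_contigs(pack_and_collapse(packed(left[:36])), 36)
        # construct an assembly with two synthetic contigs directly
        from ashcomp.assembler import Assembly, Contig
        asm = Assembly(
            contigs=[Contig("c1", min(left, revcomp(left)), 1, 4, 4 * 36),
                     Contig("c2", min(right, revcomp(right)), 1, 4, 4 * 36)],
            parameters=AssemblerConfig(read_length=36))
        joined = join_contigs(asm, overlap_floor=20)
        assert len(joined.contigs) == 1
        assert joined.contigs[0].sequence in (genome, revcomp(genome))

    def test_overlap_below_floor_not_joined(self, rng):
        from ashcomp.assembler import Assembly, Contig
        genome = random_dna(rng, 200, 0.5)
        left, right = genome[:110], genome[91:]  # 19-base overlap < floor
        asm = Assembly(
            contigs=[Contig("c1", min(left, revcomp(left)), 1, 4, 144),
                     Contig("c2", min(right, revcomp(right)), 1, 4, 144)],
            parameters=AssemblerConfig(read_length=36))
        joined = join_contigs(asm, overlap_floor=20)
        assert len(joined.contigs) == 2

    def test_ambiguous_partner_not_joined(self, rng):
        from ashcomp.assembler import Assembly, Contig
        stem = random_dna(rng, 80, 0.5)
        shared = random_dna(rng, 25, 0.5)
        a = stem + shared
        b = shared + random_dna(rng, 80, 0.5)
        c = shared + random_dna(rng, 80, 0.5)
        contigs = [Contig(f"c{i}", min(s, revcomp(s)), 1, 4, 144)
                   for i, s in enumerate((a, b, c))]
        asm = Assembly(contigs=contigs, parameters=AssemblerConfig(read_length=36))
        joined = join_contigs(asm, overlap_floor=20)
        assert len(joined.contigs) == 3

    def test_monotonicity_lower_floor_never_more_contigs(self, rng):
        genome = random_dna(rng, 4000, 0.5)
        reads = stratified_reads(genome, 36, 8, rng)  # sparse: leaves gaps
        pr = pack_and_collapse(reads)
        asm = initial_contigs(pr, 36)
        counts = []
        for floor in (34, 30, 25, 20):
            counts.append(len(join_contigs(asm, overlap_floor=floor).contigs))
        assert counts == sorted(counts, reverse=True) or \
            all(c2 <= c1 for c1, c2 in zip(counts, counts[1:]))


class TestAssembleEndToEnd:
    def test_perfect_reconstruction_5kb(self, rng):
        genome = random_dna(rng, 5_000, 0.5)
        reads = stratified_reads(genome, 36, 20, rng)
        asm = assemble(reads, AssemblerConfig(read_length=36))
        assert len(asm.contigs) == 1
        c = asm.contigs[0]
        assert c.sequence in (genome, revcomp(genome))
        assert c.depth >= 15

    def test_repeat_breaks_assembly_but_stays_sound(self, rng):
        repeat = random_dna(rng, 1_000, 0.5)
        genome = (random_dna(rng, 2_000, 0.5) + repeat +
                  random_dna(rng, 2_000, 0.5) + repeat +
                  random_dna(rng, 2_000, 0.5))
        reads = stratified_reads(genome, 36, 20, rng)
        asm = assemble(reads, AssemblerConfig(read_length=36))
        assert len(asm.contigs) > 1
        for c in asm.contigs:
            assert c.sequence in genome or revcomp(c.sequence) in genome

    def test_soundness_under_errors(self, rng):
        """With sequencing errors at the 4-class profile and uniform 35x
        sampling (the production coverage), every contig of >= 2 read lengths
        still matches the source at >= 99% identity."""
        from ashcomp.comparator import align_pair
        genome = random_dna(rng, 5_000, 0.5)
        raw = []
        for _ in range(int(35 * len(genome) / 36)):
            s = int(rng.integers(0, len(genome) - 36 + 1))
            seq = genome[s:s + 36]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            raw.append((seq, None))
        reads = []
        for seq, _q in raw:
            quals = [int(q) for q in rng.choice(4, size=36, p=[0.02, 0.06, 0.12, 0.8])]
            chars = list(seq)
            err = (0.2, 0.05, 0.005, 0.0005)
            for i, q in enumerate(quals):
                if rng.random() < err[q]:
                    chars[i] = "ACGT"[int(rng.integers(0, 4))]
            reads.append(("".join(chars), quals))
        asm = assemble(reads, AssemblerConfig(read_length=36))
        for c in asm.contigs:
            if len(c.sequence) < 72:
                continue
            best = 0.0
            for cand in (c.sequence, revcomp(c.sequence)):
                # locate by a shared 20-mer, then compare locally
                for off in range(0, len(cand) - 20, 37):
                    i = genome.find(cand[off:off + 20])
                    if i >= 0:
                        lo = max(i - off, 0)
                        window = genome[lo:lo + len(cand)]
                        ra, rb = align_pair(cand, window)
                        matches = sum(1 for x, y in zip(ra, rb)
                                      if x == y and x != "-")
                        best = max(best, matches / len(cand))
                        break
            assert best >= 0.99, f"contig of {len(c.sequence)} below 99% identity"

    def test_empty_reads(self):
        assert assemble([], AssemblerConfig()).contigs == []

    def test_depth_consistency(self, rng):
        genome = random_dna(rng, 4_000, 0.5)
        reads = stratified_reads(genome, 36, 15, rng)
        asm = assemble(reads, AssemblerConfig(read_length=36))
        total_in = len(reads) * 36
        total_assigned = sum(c.depth * len(c.sequence) for c in asm.contigs)
        assert total_assigned <= total_in + 1e-6


def test_phred_class_boundaries():
    assert phred_to_class([0, 9, 10, 19, 20, 29, 30, 40]) == [0, 0, 1, 1, 2, 2, 3, 3]
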