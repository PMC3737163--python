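"""Whole-genome comparison of two near-identical, collinear genomes.

Alignment is anchor-and-fill: 31-mers unique in both chromosomes are matched
and chained with a longest-increasing-subsequence pass; the short spans
between consecutive anchors are aligned by global dynamic programming with
affine gaps (match +1, mismatch -2, gap open -5, extend -1 per additional
base).  Spans longer than ``max_dp_span`` are reported unaligned.

From the alignment the module calls SNPs and indel events (one event per
maximal gap run, left-normalised), classifies SNPs as transition or
transversion and — given gene models — as synonymous / nonsynonymous /
noncoding, computes windowed identity tracks, detects introgression segments
as runs of low-identity windows, and finds maximal identical duplicated
segments between chromosomes of a single genome (gene-conversion candidates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .anchors import DEFAULT_K, lis_chain, unique_kmers
from .io_formats import AnnotatedGenome, GeneModel

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -5, -1


@dataclass
class AlignmentBlock:
    a_start: int  # 1-based inclusive on genome A
    a_end: int
    b_start: int
    b_end: int
    a_aln: str    # alignment rows with '-' gaps; equal length
    b_aln: str

    def __post_init__(self):
        assert len(self.a_aln) == len(self.b_aln)


@dataclass
class ChromosomeAlignment:
    chrom_a: str
    chrom_b: str
    a_length: int
    b_length: int
    blocks: list[AlignmentBlock] = field(default_factory=list)
    unaligned: list[tuple[int, int]] = field(default_factory=list)  # A coords


@dataclass
class CollinearAlignment:
    chromosomes: list[ChromosomeAlignment] = field(default_factory=list)


@dataclass
class Variant:
    chromosome: str
    position: int            # 1-based on genome A
    ref_allele: str
    alt_allele: str
    type: str                # SNP | insertion | deletion
    length: int = 1
    snp_class: str = "NA"    # transition | transversion | NA
    coding_class: str = "NA" # synonymous | nonsynonymous | noncoding | NA
    gene_id: Optional[str] = None


@dataclass
class IdentityWindow:
    chromosome: str
    start: int
    end: int
    aligned_columns: int
    matches: int

    @property
    def identity(self) -> Optional[float]:
        if self.aligned_columns == 0:
            return None
        return self.matches / self.aligned_columns


@dataclass
class IntrogressionSegment:
    chromosome: str
    start: int
    end: int
    mean_identity: float
    n_snps: int
    snp_breakdown: tuple[int, int, int]  # (inter_orf, synonymous, nonsynonymous)


@dataclass
class IdenticalSegment:
    chromosome_a: str
    chromosome_b: str
    start_a: int
    start_b: int
    length: int


def _aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "global"
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    return al


def align_pair(sa: str, sb: str) -> tuple[str, str]:
    """Globally align two sequences, returning gapped rows."""
    if sa == sb:
        return sa, sb
    if not sa:
        return "-" * len(sb), sb
    if not sb:
        return sa, "-" * len(sa)
    aln = _aligner().align(sa, sb)[0]
    rows_a, rows_b = [], []
    pa = pb = 0
    for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
        if a0 > pa:
            rows_a.append(sa[pa:a0])
            rows_b.append("-" * (a0 - pa))
        if b0 > pb:
            rows_a.append("-" * (b0 - pb))
            rows_b.append(sb[pb:b0])
        rows_a.append(sa[a0:a1])
        rows_b.append(sb[b0:b1])
        pa, pb = a1, b1
    if pa < len(sa):
        rows_a.append(sa[pa:])
        rows_b.append("-" * (len(sa) - pa))
    if pb < len(sb):
        rows_a.append("-" * (len(sb) - pb))
        rows_b.append(sb[pb:])
    return "".join(rows_a), "".join(rows_b)


def _pair_chromosomes(genome_a: AnnotatedGenome, genome_b: AnnotatedGenome
                      ) -> list[tuple[str, str]]:
    names_b = {r.id for r in genome_b.records}
    pairs = []
    for ra, rb in zip(genome_a.records, genome_b.records):
        if ra.id in names_b:
            pairs.append((ra.id, ra.id))
        else:
            pairs.append((ra.id, rb.id))
    return pairs


def align_genomes(genome_a: AnnotatedGenome, genome_b: AnnotatedGenome,
                  k: int = DEFAULT_K, max_dp_span: int = 20_000) -> CollinearAlignment:
    """Align two mostly-collinear genomes chromosome by chromosome."""
    out = CollinearAlignment()
    for ca, cb in _pair_chromosomes(genome_a, genome_b):
        sa = genome_a.record(ca).sequence
        sb = genome_b.record(cb).sequence
        chrom = ChromosomeAlignment(ca, cb, len(sa), len(sb))
        ua = unique_kmers(sa, k)
        ub = unique_kmers(sb, k)
        matches = [(pa, ub[kmer]) for kmer, pa in ua.items() if kmer in ub]
        chain = lis_chain(matches)
        # drop anchors overlapping their predecessor on either genome
        anchors: list[tuple[int, int]] = []
        for pa, pb in chain:
            if anchors and (pa < anchors[-1][0] + k or pb < anchors[-1][1] + k):
                continue
            anchors.append((pa, pb))
        if not anchors:
            chrom.unaligned.append((1, len(sa)))
            out.chromosomes.append(chrom)
            continue

        pieces_a: list[str] = []
        pieces_b: list[str] = []
        block_a_start = block_b_start = None
        cur_a = cur_b = 0  # 0-based cursors

        def flush(end_a: int, end_b: int):
            nonlocal block_a_start, block_b_start
            if pieces_a and block_a_start is not None:
                chrom.blocks.append(AlignmentBlock(
                    block_a_start + 1, end_a, block_b_start + 1, end_b,
                    "".join(pieces_a), "".join(pieces_b)))
            pieces_a.clear()
            pieces_b.clear()
            block_a_start = block_b_start = None

        for i, (pa, pb) in enumerate(anchors):
            gap_a = sa[cur_a:pa]
            gap_b = sb[cur_b:pb]
            if max(len(gap_a), len(gap_b)) > max_dp_span:
                flush(cur_a, cur_b)
                if gap_a:
                    chrom.unaligned.append((cur_a + 1, pa))
            else:
                if block_a_start is None:
                    block_a_start, block_b_start = cur_a, cur_b
                ra, rb = align_pair(gap_a, gap_b)
                pieces_a.append(ra)
                pieces_b.append(rb)
            if block_a_start is None:
                block_a_start, block_b_start = pa, pb
            pieces_a.append(sa[pa : pa + k])
            pieces_b.append(sb[pb : pb + k])
            cur_a, cur_b = pa + k, pb + k
        tail_a, tail_b = sa[cur_a:], sb[cur_b:]
        if max(len(tail_a), len(tail_b)) > max_dp_span:
            flush(cur_a, cur_b)
            if tail_a:
                chrom.unaligned.append((cur_a + 1, len(sa)))
        else:
            ra, rb = align_pair(tail_a, tail_b)
            pieces_a.append(ra)
            pieces_b.append(rb)
            cur_a, cur_b = len(sa), len(sb)
        flush(cur_a, cur_b)
        out.chromosomes.append(chrom)
    return out


# --- variant calling ---------------------------------------------------------

_PURINES = {"A", "G"}


def snp_class_of(ref: str, alt: str) -> str:
    if (ref in _PURINES) == (alt in _PURINES):
        return "transition"
    return "transversion"


def call_variants(alignment: CollinearAlignment,
                  genome_a: Optional[AnnotatedGenome] = None) -> list[Variant]:
    """Call SNPs and indel events from an alignment.

    Each mismatch column is one SNP; each maximal gap run is one insertion or
    deletion event of its full length.  Indels are left-normalised against
    genome A when its sequence is available.
    """
    out: list[Variant] = []
    for chrom in alignment.chromosomes:
        seq_a = genome_a.record(chrom.chrom_a).sequence if genome_a else None
        for block in chrom.blocks:
            a_pos = block.a_start - 1  # 0-based, next A position to consume
            aln_a, aln_b = block.a_aln, block.b_aln
            i = 0
            n = len(aln_a)
            while i < n:
                ca, cb = aln_a[i], aln_b[i]
                if ca != "-" and cb != "-":
                    if ca != cb:
                        out.append(Variant(chrom.chrom_a, a_pos + 1, ca, cb, "SNP",
                                           1, snp_class_of(ca, cb)))
                    a_pos += 1
                    i += 1
                elif cb == "-":
                    j = i
                    while j < n and aln_b[j] == "-":
                        j += 1
                    ref = aln_a[i:j]
                    pos = a_pos + 1
                    if seq_a is not None:
                        pos, ref, _ = _left_norm_del(seq_a, pos, ref)
                    out.append(Variant(chrom.chrom_a, pos, ref, "-", "deletion", len(ref)))
                    a_pos += j - i
                    i = j
                else:  # gap in A: insertion in B
                    j = i
                    while j < n and aln_a[j] == "-":
                        j += 1
                    alt = aln_b[i:j]
                    pos = a_pos  # base before the insertion (may be 0)
                    if seq_a is not None:
                        pos, alt = _left_norm_ins(seq_a, pos, alt)
                    out.append(Variant(chrom.chrom_a, pos, "-", alt, "insertion", len(alt)))
                    i = j
    out.sort(key=lambda v: (v.chromosome, v.position))
    return out


def _left_norm_del(seq: str, pos: int, ref: str):
    n = len(ref)
    while pos > 1 and seq[pos - 2] == seq[pos + n - 2]:
        pos -= 1
    return pos, seq[pos - 1 : pos - 1 + n], "-"


def _left_norm_ins(seq: str, pos: int, alt: str):
    while pos >= 1 and seq[pos - 1] == alt[-1]:
        alt = alt[-1] + alt[:-1]
        pos -= 1
    return pos, alt


# --- coding classification ---------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_coding(variants: list[Variant], genes: list[GeneModel],
                    genome_a: AnnotatedGenome) -> list[Variant]:
    """Annotate SNPs with synonymous/nonsynonymous/noncoding classes in place.

    Classification is strand-aware: the ref and alt codons are read in mRNA
    sense.  Indels are left NA (events, not site classes); SNPs in genes whose
    CDS length is not a multiple of 3 are NA and the gene is flagged.
    """
    exon_map: dict[str, list[tuple[int, int, GeneModel, int]]] = {}
    cds_cache: dict[str, str] = {}
    cds_len: dict[str, int] = {}
    for g in genes:
        if g.feature_type != "CDS":
            continue
        total = sum(e - s + 1 for s, e in g.exons)
        cds_len[g.gene_id] = total
        offset = 0
        for s, e in g.exons:
            exon_map.setdefault(g.chromosome, []).append((s, e, g, offset))
            offset += e - s + 1
    for lst in exon_map.values():
        lst.sort(key=lambda t: t[0])

    for v in variants:
        if v.type != "SNP":
            v.coding_class = "NA"
            continue
        hit = None
        for s, e, g, offset in exon_map.get(v.chromosome, []):
            if s <= v.position <= e:
                hit = (s, e, g, offset)
                break
            if s > v.position:
                break
        if hit is None:
            v.coding_class = "noncoding"
            continue
        s, e, g, offset = hit
        v.gene_id = g.gene_id
        total = cds_len[g.gene_id]
        if total % 3 != 0:
            v.coding_class = "NA"
            continue
        if g.gene_id not in cds_cache:
            cds_cache[g.gene_id] = genome_a.gene_sequence(g)
        cds = cds_cache[g.gene_id]
        if g.strand == "+":
            idx = offset + (v.position - s)
            alt_sense = v.alt_allele
        else:
            idx = (total - 1) - (offset + (v.position - s))
            alt_sense = v.alt_allele.translate(_COMPLEMENT)
        codon_start = (idx // 3) * 3
        within = idx % 3
        ref_codon = cds[codon_start : codon_start + 3]
        alt_codon = ref_codon[:within] + alt_sense + ref_codon[within + 1 :]
        v.coding_class = ("synonymous" if _translate(ref_codon) == _translate(alt_codon)
                          else "nonsynonymous")
    return variants


# --- identity windows and introgression --------------------------------------

def identity_track(alignment: CollinearAlignment, window_size: int
                   ) -> list[IdentityWindow]:
    """Non-overlapping identity windows on genome A coordinates.

    A column contributes when both genomes have a base there; windows with no
    aligned columns carry ``identity is None`` rather than 0.
    """
    if window_size < 100:
        raise ValueError("window_size must be >= 100")
    out: list[IdentityWindow] = []
    for chrom in alignment.chromosomes:
        n_windows = (chrom.a_length + window_size - 1) // window_size
        aligned = [0] * n_windows
        matched = [0] * n_windows
        for block in chrom.blocks:
            a_pos = block.a_start - 1
            for ca, cb in zip(block.a_aln, block.b_aln):
                if ca == "-":
                    continue
                if cb != "-":
                    w = a_pos // window_size
                    aligned[w] += 1
                    if ca == cb:
                        matched[w] += 1
                a_pos += 1
        for w in range(n_windows):
            start = w * window_size + 1
            end = min((w + 1) * window_size, chrom.a_length)
            out.append(IdentityWindow(chrom.chrom_a, start, end, aligned[w], matched[w]))
    return out


def detect_introgression(track: list[IdentityWindow],
                         variants: Optional[list[Variant]] = None,
                         threshold: float = 0.98,
                         min_windows: int = 3) -> list[IntrogressionSegment]:
    """Detect introgression segments: maximal runs of >= ``min_windows``
    windows below the identity threshold, runs separated by a single passing
    window merged, boundaries refined inward to the outermost variants."""
    by_chrom: dict[str, list[IdentityWindow]] = {}
    for w in track:
        by_chrom.setdefault(w.chromosome, []).append(w)
    segments: list[IntrogressionSegment] = []
    for chrom in sorted(by_chrom):
        windows = sorted(by_chrom[chrom], key=lambda w: w.start)
        fails = [w.identity is not None and w.identity < threshold for w in windows]
        runs: list[tuple[int, int]] = []
        i = 0
        while i < len(windows):
            if fails[i]:
                j = i
                while j + 1 < len(windows) and fails[j + 1]:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        merged: list[tuple[int, int]] = []
        for run in runs:
            if merged and run[0] - merged[-1][1] <= 2:  # <=1 passing window between
                merged[-1] = (merged[-1][0], run[1])
            else:
                merged.append(run)
        for i0, i1 in merged:
            if i1 - i0 + 1 < min_windows:
                continue
            start = windows[i0].start
            end = windows[i1].end
            seg_vars = [v for v in (variants or [])
                        if v.chromosome == chrom and start <= v.position <= end]
            if seg_vars:
                start = min(v.position for v in seg_vars)
                end = max(v.position for v in seg_vars)
            aligned = sum(w.aligned_columns for w in windows[i0 : i1 + 1])
            matches = sum(w.matches for w in windows[i0 : i1 + 1])
            snps = [v for v in seg_vars if v.type == "SNP"]
            breakdown = (
                sum(1 for v in snps if v.coding_class == "noncoding"),
                sum(1 for v in snps if v.coding_class == "synonymous"),
                sum(1 for v in snps if v.coding_class == "nonsynonymous"),
            )
            segments.append(IntrogressionSegment(
                chrom, start, end,
                matches / aligned if aligned else 0.0,
                len(snps), breakdown))
    return segments


# --- identical duplicated segments (gene-conversion candidates) --------------

def find_identical_segments(genome: AnnotatedGenome, min_length: int = 5_000,
                            k: int = DEFAULT_K, max_seed_occurrences: int = 20
                            ) -> list[IdenticalSegment]:
    """Maximal exact repeats >= ``min_length`` between *different* chromosomes
    of one genome, from shared k-mer seeding plus exact extension.

    Same-orientation matches only; each maximal segment is reported once,
    ordered by (chromosome_a, start_a).
    """
    occ: dict[str, list[tuple[str, int]]] = {}
    seqs = {r.id: r.sequence for r in genome.records}
    for name in sorted(seqs):
        seq = seqs[name]
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            lst = occ.get(kmer)
            if lst is None:
                occ[kmer] = [(name, i)]
            elif len(lst) <= max_seed_occurrences:
                lst.append((name, i))

    found: set[tuple[str, str, int, int, int]] = set()
    covered: dict[tuple[str, str, int], list[tuple[int, int]]] = {}
    for kmer in occ:
        locs = occ[kmer]
        if len(locs) < 2 or len(locs) > max_seed_occurrences:
            continue
        for i in range(len(locs)):
            for j in range(i + 1, len(locs)):
                (c1, p1), (c2, p2) = locs[i], locs[j]
                if c1 == c2:
                    continue
                if (c2, p2) < (c1, p1):
                    (c1, p1), (c2, p2) = (c2, p2), (c1, p1)
                diag = (c1, c2, p1 - p2)
                skip = False
                for s, e in covered.get(diag, []):
                    if s <= p1 <= e:
                        skip = True
                        break
                if skip:
                    continue
                s1, s2 = seqs[c1], seqs[c2]
                a, b = p1, p2
                while a > 0 and b > 0 and s1[a - 1] == s2[b - 1]:
                    a -= 1
                    b -= 1
                ea, eb = p1 + k, p2 + k
                while ea < len(s1) and eb < len(s2) and s1[ea] == s2[eb]:
                    ea += 1
                    eb += 1
                covered.setdefault(diag, []).append((a, ea - 1))
                length = ea - a
                if length >= min_length:
                    found.add((c1, c2, a + 1, b + 1, length))
    return [IdenticalSegment(*t) for t in sorted(found)]
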