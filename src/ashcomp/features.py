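"""Intron statistics, splice-site consensus matrices, ORF 3' overlaps.

Introns are the gaps between consecutive annotated exons.  Splice contexts
are read strand-aware (mRNA sense).  The branch-point search uses the
canonical budding-yeast heptamer TACTAAC with a one-mismatch tolerance.
Convergent overlaps are opposite-strand gene pairs whose coordinate spans
intersect around both genes' 3' ends — the arrangement that puts two
terminators in shared sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_formats import AnnotatedGenome, GeneModel, revcomp

BRANCH_QUERY = "TACTAAC"
DONOR_WINDOW = (-3, 6)    # positions around the 5' splice site (exon -3..-1, intron +1..+6)
ACCEPTOR_WINDOW = (-6, 3) # intron -6..-1, exon +1..+3


@dataclass
class IntronRecord:
    gene_id: str
    chromosome: str
    start: int               # genomic, 1-based inclusive
    end: int
    strand: str
    donor_site: str          # first 6 intron bases, mRNA sense
    branch_points: list[int] # genomic positions of branch motif starts
    acceptor_sites: list[int]  # genomic positions of the 3' splice site(s)
    location_class: str      # CDS | 5UTR | tRNA
    short_flag: bool = False # intron under 20 bases

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SpliceConsensus:
    donor_matrix: np.ndarray      # 4 x 9, rows A,C,G,T
    branch_matrix: np.ndarray     # 4 x 7
    acceptor_matrix: np.ndarray   # 4 x 9
    n_introns: int

    def consensus_string(self, which: str) -> str:
        m = {"donor": self.donor_matrix, "branch": self.branch_matrix,
             "acceptor": self.acceptor_matrix}[which]
        return "".join("ACGT"[int(i)] for i in m.argmax(axis=0))


@dataclass
class OverlapPair:
    gene_plus: str
    gene_minus: str
    overlap_length: int
    overlap_class: str  # 3prime_convergent | 5prime | other


_LOCATION_CLASS = {"CDS": "CDS", "tRNA": "tRNA", "5UTR_intron": "5UTR", "ncRNA": "CDS"}


def _sense_intron(genome: AnnotatedGenome, gene: GeneModel, start: int, end: int) -> str:
    seq = genome.record(gene.chromosome).slice(start, end)
    return seq if gene.strand == "+" else revcomp(seq)


def _find_branch(sense_intron: str, max_mismatch: int = 1) -> Optional[int]:
    """Best match offset (0-based, sense) of the branch heptamer, or None."""
    best = None
    q = BRANCH_QUERY
    for i in range(len(sense_intron) - len(q) + 1):
        mm = sum(1 for a, b in zip(sense_intron[i : i + len(q)], q) if a != b)
        if mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, i)
            if mm == 0:
                break
    return None if best is None else best[1]


def collect_introns(annotations: list[GeneModel], genome: AnnotatedGenome
                    ) -> list[IntronRecord]:
    """Extract intron records (exon gaps) with strand-aware splice contexts.

    Introns shorter than 20 bases are flagged, not dropped.
    """
    out = []
    for g in annotations:
        for start, end in g.introns():
            if end < start:
                continue
            sense = _sense_intron(genome, g, start, end)
            branch_off = _find_branch(sense)
            if g.strand == "+":
                branch_pos = [start + branch_off] if branch_off is not None else []
                acceptor = [end]
            else:
                branch_pos = [end - branch_off - (len(BRANCH_QUERY) - 1)] if branch_off is not None else []
                acceptor = [start]
            out.append(IntronRecord(
                g.gene_id, g.chromosome, start, end, g.strand,
                donor_site=sense[:6],
                branch_points=branch_pos,
                acceptor_sites=acceptor,
                location_class=_LOCATION_CLASS.get(g.feature_type, "CDS"),
                short_flag=(end - start + 1) < 20,
            ))
    return out


def intron_stats(introns: list[IntronRecord], hist_bin: int = 10) -> dict:
    """Counts per location class, mean CDS-intron length, length histogram."""
    if not introns:
        return {"count_by_class": {}, "mean_length": None, "length_histogram": {}}
    count_by_class: dict[str, int] = {}
    for rec in introns:
        count_by_class[rec.location_class] = count_by_class.get(rec.location_class, 0) + 1
    cds_lengths = [rec.length for rec in introns if rec.location_class == "CDS"]
    mean_length = sum(cds_lengths) / len(cds_lengths) if cds_lengths else None
    hist: dict[int, int] = {}
    for rec in introns:
        b = (rec.length // hist_bin) * hist_bin
        hist[b] = hist.get(b, 0) + 1
    return {"count_by_class": count_by_class, "mean_length": mean_length,
            "length_histogram": dict(sorted(hist.items()))}


_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


def _accumulate(matrix: np.ndarray, seq: str) -> None:
    for col, base in enumerate(seq):
        if base in _ROW:
            matrix[_ROW[base], col] += 1


def splice_consensus(introns: list[IntronRecord], genome: AnnotatedGenome
                     ) -> SpliceConsensus:
    """Position-frequency matrices around donor, branch and acceptor sites.

    Donor covers mRNA-sense positions -3..+6 around the 5' splice site,
    acceptor -6..+3 around the 3' site, branch the 7 heptamer positions.
    Columns are normalised to sum to 1.
    """
    if not introns:
        raise ValueError("need at least one intron")
    donor = np.zeros((4, 9))
    branch = np.zeros((4, 7))
    acceptor = np.zeros((4, 9))
    n = 0
    for rec in introns:
        chrom_seq = genome.record(rec.chromosome).sequence
        if rec.strand == "+":
            lo = rec.start - 1 - 3
            context = chrom_seq[lo : lo + 9]
            acc = chrom_seq[rec.end - 6 : rec.end + 3]
        else:
            context = revcomp(chrom_seq[rec.end - 6 : rec.end + 3])
            acc = revcomp(chrom_seq[rec.start - 1 - 3 : rec.start - 1 + 6])
        if len(context) == 9:
            _accumulate(donor, context)
        if len(acc) == 9:
            _accumulate(acceptor, acc)
        if rec.branch_points:
            intron_seq = chrom_seq[rec.start - 1 : rec.end]
            sense_intron = intron_seq if rec.strand == "+" else revcomp(intron_seq)
            off = _find_branch(sense_intron)
            if off is not None:
                _accumulate(branch, sense_intron[off : off + 7])
        n += 1
    for m in (donor, branch, acceptor):
        sums = m.sum(axis=0)
        nonzero = sums > 0
        m[:, nonzero] /= sums[nonzero]
    return SpliceConsensus(donor, branch, acceptor, n)


def find_convergent_overlaps(annotations: list[GeneModel]) -> list[OverlapPair]:
    """Opposite-strand gene pairs with intersecting spans, classified by which
    gene ends fall inside the intersection.

    3' convergent: the intersection contains the + gene's right end and the
    - gene's left end (both 3' ends).  5': it contains both 5' ends.
    """
    plus = [g for g in annotations if g.strand == "+"]
    minus = [g for g in annotations if g.strand == "-"]
    out = []
    for gp in plus:
        for gm in minus:
            if gp.chromosome != gm.chromosome:
                continue
            lo = max(gp.start, gm.start)
            hi = min(gp.end, gm.end)
            if lo > hi:
                continue
            length = hi - lo + 1
            has_p3 = lo <= gp.end <= hi       # + gene 3' end
            has_m3 = lo <= gm.start <= hi     # - gene 3' end
            has_p5 = lo <= gp.start <= hi
            has_m5 = lo <= gm.end <= hi
            if has_p3 and has_m3:
                cls = "3prime_convergent"
            elif has_p5 and has_m5:
                cls = "5prime"
            else:
                cls = "other"
            out.append(OverlapPair(gp.gene_id, gm.gene_id, length, cls))
    out.sort(key=lambda p: (p.gene_plus, p.gene_minus))
    return out
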