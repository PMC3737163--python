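"""Readers and writers for the external representations used across the toolkit.

All genomic coordinates are 1-based inclusive (GenBank convention).  The only
place the 0-based half-open convention appears is the BED-like writer, which
converts at the boundary.  FASTQ qualities are Phred+33 and nothing else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

STRANDS = ("+", "-")
FEATURE_TYPES = ("CDS", "tRNA", "ncRNA", "5UTR_intron")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class SeqRecord:
    """A named DNA sequence restricted to the {A,C,G,T,N} alphabet."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive subsequence."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(f"slice [{start},{end}] outside 1..{len(self.sequence)}")
        return self.sequence[start - 1 : end]


@dataclass
class GeneModel:
    """A gene feature with 1-based inclusive coordinates and ordered exons."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"
    exons: list[tuple[int, int]] = field(default_factory=list)
    ortholog_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class AnnotatedGenome:
    records: list[SeqRecord]
    genes: list[GeneModel]
    name: str = ""

    def __post_init__(self) -> None:
        by_id = {r.id: r for r in self.records}
        for g in self.genes:
            rec = by_id.get(g.chromosome)
            if rec is None:
                raise ValueError(f"{g.gene_id}: chromosome {g.chromosome} not in records")
            if g.end > len(rec):
                raise ValueError(f"{g.gene_id}: end {g.end} beyond chromosome length {len(rec)}")

    def record(self, chrom: str) -> SeqRecord:
        for r in self.records:
            if r.id == chrom:
                return r
        raise KeyError(chrom)

    def gene_sequence(self, gene: GeneModel) -> str:
        """Spliced, strand-oriented (mRNA-sense) sequence of a gene."""
        rec = self.record(gene.chromosome)
        seq = "".join(rec.slice(s, e) for s, e in gene.exons)
        if gene.strand == "-":
            seq = revcomp(seq)
        return seq


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    for i, c in enumerate(seq):
        if c not in VALID_BASES:
            raise FormatError(f"record {record_id}: illegal character {c!r} at position {i + 1}")
    return seq


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file; sequences are uppercased, U normalised to T, and any
    character outside {A,C,G,T,N} is rejected with its position reported."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = [
        SeqRecord(r.id, _clean_sequence(str(r.seq), r.id), r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    for r in records:
        if not r.sequence:
            raise FormatError(f"{path}: record {r.id} has empty sequence")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = r.id if not r.description or r.description == r.id else f"{r.id} {r.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[SeqRecord, list[int]]]:
    """Read 4-line Phred+33 FASTQ into (record, per-base quality) pairs.

    An empty file yields an empty list; truncated records and length
    mismatches between sequence and quality raise :class:`FormatError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out: list[tuple[SeqRecord, list[int]]] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            if not header.strip():
                continue
            seq_line = fh.readline()
            plus = fh.readline()
            qual_line = fh.readline()
            if not qual_line:
                raise FormatError(f"{path}: truncated FASTQ record at {header.strip()!r}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FormatError(f"{path}: malformed FASTQ record at {header.strip()!r}")
            name = header[1:].strip().split()[0]
            seq = seq_line.strip().upper()
            qual = qual_line.rstrip("\n")
            if len(seq) != len(qual):
                raise FormatError(f"{path}: record {name}: sequence/quality length mismatch")
            phred = [ord(c) - 33 for c in qual]
            if any(q < 0 or q > 93 for q in phred):
                raise FormatError(f"{path}: record {name}: quality outside Phred+33 range")
            out.append((SeqRecord(name, seq), phred))
    return out


def write_fastq(reads: Iterable[tuple[SeqRecord, list[int]]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec, phred in reads:
            if len(rec.sequence) != len(phred):
                raise ValueError(f"{rec.id}: sequence/quality length mismatch")
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n")
            fh.write("".join(chr(q + 33) for q in phred) + "\n")


# --- GFF3-style annotations -------------------------------------------------
#
# Dialect: one line per feature (type column = feature_type) carrying
# ID= and optional ortholog=; one `exon` line per exon with Parent=.
# Single-exon genes omit exon lines.

def write_annotations(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.ortholog_label:
                attrs += f";ortholog={g.ortholog_label}"
            fh.write(
                f"{g.chromosome}\t.\t{g.feature_type}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            if len(g.exons) > 1:
                for s, e in g.exons:
                    fh.write(
                        f"{g.chromosome}\t.\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                    )


def _parse_attrs(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotations(path: str | os.PathLike) -> list[GeneModel]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    genes: dict[str, GeneModel] = {}
    exon_lists: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-delimited columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cols
            start, end = int(start_s), int(end_s)
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_attrs(attrs_s)
            if ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: exon without Parent")
                exon_lists.setdefault(parent, []).append((start, end))
            else:
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: feature without ID")
                genes[gid] = GeneModel(
                    gid, chrom, start, end, strand, ftype,
                    exons=[], ortholog_label=attrs.get("ortholog"),
                )
                order.append(gid)
    out = []
    for gid in order:
        g = genes[gid]
        if gid in exon_lists:
            g = GeneModel(g.gene_id, g.chromosome, g.start, g.end, g.strand,
                          g.feature_type, exons=exon_lists[gid],
                          ortholog_label=g.ortholog_label)
        out.append(g)
    return out


def read_ortholog_table(path: str | os.PathLike) -> list[tuple[Optional[str], Optional[str], Optional[str]]]:
    """Read a TSV ortholog table (header row; columns gene_a, gene_b, family).

    Rows are deduplicated; a missing partner is encoded as None; two rows
    pairing the same genes under different family labels are an error.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    pairs: dict[tuple, Optional[str]] = {}
    order: list[tuple] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            a = cols[0] or None
            b = cols[1] if len(cols) > 1 and cols[1] else None
            fam = cols[2] if len(cols) > 2 and cols[2] else None
            key = (a, b)
            if key in pairs:
                if pairs[key] != fam:
                    raise FormatError(
                        f"{path}:{lineno}: conflicting family for pair {a}/{b}: "
                        f"{pairs[key]!r} vs {fam!r}"
                    )
                continue
            pairs[key] = fam
            order.append(key)
    return [(a, b, pairs[(a, b)]) for a, b in order]


def write_ortholog_table(rows: Iterable[tuple], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tfamily\n")
        for a, b, fam in rows:
            fh.write(f"{a or ''}\t{b or ''}\t{fam or ''}\n")


# --- minimal VCF-like and BED-like formats ----------------------------------

def write_variants(variants, path: str | os.PathLike) -> None:
    """Write variant records to a minimal VCF-like TSV (CHROM POS REF ALT TYPE)."""
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tREF\tALT\tTYPE\n")
        for v in variants:
            fh.write(f"{v.chromosome}\t{v.position}\t{v.ref_allele}\t{v.alt_allele}\t{v.type}\n")


def read_variants(path: str | os.PathLike) -> list[tuple[str, int, str, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, ref, alt, vtype = line.rstrip("\n").split("\t")
            out.append((chrom, int(pos), ref, alt, vtype))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | os.PathLike) -> None:
    """Write 1-based inclusive (chrom, start, end, name) intervals as BED
    (0-based half-open); the conversion happens here and only here."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
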