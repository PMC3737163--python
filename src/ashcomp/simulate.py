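"""Synthetic genome, strain, species and read simulator.

Generates an ancestral annotated genome shaped like a compact, low-repeat
filamentous-fungus genome (GC ~52%, dense single-intron genes, 24-base
telomeric terminal repeats) and derives from it:

* a strain pair: one genome identical to the ancestor, one carrying
  substitutions and 1-5 base indels at the configured pair rates plus a
  single introgressed block replaced by a diverged donor haplotype;
* a sibling species: genome-wide substitutions at ~10% plus reciprocal
  arm exchanges at inter-gene breakpoints and tandem copy-number changes;
* 36-base single-end reads and 58-base mate pairs with ~1.6 kb inserts,
  with a 4-class quality/error model.

Every planted event is logged in a :class:`TruthSet` so downstream modules
can be scored exactly.  All randomness flows from ``SimulationConfig.seed``;
identical configs give byte-identical outputs.

The strain pair is modelled one-sided: the configured substitution/indel
rates are *pair* rates applied entirely on strain B while strain A stays
identical to the ancestor.  This keeps the truth in reference coordinates
(0.001 pair rate -> 99.9% pairwise identity) and makes precision/recall
against the truth exact.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io_formats import AnnotatedGenome, GeneModel, SeqRecord, revcomp

TELOMERE_UNIT = "TGAGAGACCCATACACCACACCGC"  # 24-base terminal repeat

# splice motifs written into simulated introns (canonical budding-yeast style)
DONOR_MOTIF = "GTATGT"
BRANCH_MOTIF = "TACTAAC"
ACCEPTOR_MOTIF = "TTTCAG"

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS
)

# rng stream ids, so stages are independently re-runnable from one seed
_STREAM_ANCESTOR = 11
_STREAM_STRAIN_B = 13
_STREAM_SPECIES = 17
_STREAM_READS = 19


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 100_000
    gc_content: float = 0.52
    gene_density: float = 4.0          # genes per 10 kb
    intron_rate: float = 0.05          # fraction of genes with one intron
    strain_sub_rate: float = 0.001     # per-base pair rate between the two strains
    strain_indel_rate: float = 0.0001
    introgression_length: int = 5_000
    introgression_divergence: float = 0.08
    species_sub_rate: float = 0.10
    n_translocations: int = 2          # reciprocal events
    tandem_events: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("famCWP1", 4, 4),   # quadruplication shared by both genomes
            ("famBENZ", 4, 0),   # quadruplication absent from the species
            ("famDFG5", 3, 1),   # triplication reduced to a single copy
            ("famRAI1", 2, 1),   # duplication reduced to a single copy
            ("famRHO1", 2, 2),   # duplication shared
        ]
    )
    read_length: int = 36
    matepair_read_length: int = 58
    insert_mean: int = 1_600
    insert_sd: int = 150
    depth: float = 35.0
    mate_depth: float = 8.0
    mate_orientation: str = "outward"  # jumping-library convention; or "innie"
    seq_error_rate_by_quality_class: tuple[float, float, float, float] = (0.2, 0.05, 0.005, 0.0005)
    quality_class_probs: tuple[float, float, float, float] = (0.02, 0.06, 0.12, 0.80)
    quality_class_phred: tuple[int, int, int, int] = (5, 15, 25, 35)
    transition_fraction: float = 0.63  # purine<->purine / pyrimidine<->pyrimidine bias
    telomere_unit: str = TELOMERE_UNIT
    telomere_copies: int = 3

    def validate(self) -> None:
        rates = [
            self.strain_sub_rate, self.strain_indel_rate,
            self.introgression_divergence, self.species_sub_rate,
            self.intron_rate, *self.seq_error_rate_by_quality_class,
        ]
        for r in rates:
            if not (0 <= r < 1):
                raise ValueError(f"rate {r} outside [0,1)")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0,1)")
        for n in (self.n_chromosomes, self.chrom_length, self.read_length,
                  self.matepair_read_length, self.insert_mean, self.introgression_length):
            if n <= 0:
                raise ValueError("lengths/counts must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.mate_orientation not in ("outward", "innie"):
            raise ValueError(f"unknown mate orientation {self.mate_orientation!r}")
        if abs(sum(self.quality_class_probs) - 1.0) > 1e-9:
            raise ValueError("quality_class_probs must sum to 1")


@dataclass
class TruthSet:
    """Planted events, in reference (ancestor / strain A) coordinates."""

    variants: list[tuple[str, int, str, str, str]] = field(default_factory=list)
    introgression: Optional[tuple[str, int, int]] = None
    breakpoints: list[tuple[str, str, str, str, str]] = field(default_factory=list)
    tandem_arrays: list[tuple[str, str, str, int]] = field(default_factory=list)
    provenance_seed: int = 0

    def sort(self) -> None:
        self.variants.sort(key=lambda v: (v[0], v[1]))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)
    return arr.tobytes().decode()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ORF-like sequence: ATG + sense codons + TAA."""
    body = rng.choice(len(_SENSE_CODONS), size=max(n_codons - 2, 0))
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def _make_intron(rng: np.random.Generator, gc: float) -> str:
    """Canonical intron: GTATGT ... TACTAAC ... TTTCAG, length 64-150."""
    total = int(rng.integers(64, 151))
    tail_fill = int(rng.integers(10, 31))
    head_fill = total - len(DONOR_MOTIF) - len(BRANCH_MOTIF) - len(ACCEPTOR_MOTIF) - tail_fill
    return (DONOR_MOTIF + random_dna(rng, head_fill, gc)
            + BRANCH_MOTIF + random_dna(rng, tail_fill, gc) + ACCEPTOR_MOTIF)


class _GeneRequest:
    """One placement item: a single gene or a whole tandem array."""

    def __init__(self, segment: str, genes: list[tuple[str, int, int, str, list[tuple[int, int]], str]]):
        # genes: (gene_id, rel_start, rel_end, strand, rel_exons, family)
        self.segment = segment
        self.genes = genes


def _single_gene_request(rng: np.random.Generator, gene_id: str, family: str,
                         config: SimulationConfig) -> _GeneRequest:
    n_codons = int(rng.integers(150, 451))
    cds = _random_cds(rng, n_codons)
    strand = "+" if rng.random() < 0.5 else "-"
    has_intron = rng.random() < config.intron_rate
    if has_intron:
        intron = _make_intron(rng, config.gc_content)
        cut = int(rng.integers(30, len(cds) - 30))
        sense = cds[:cut] + intron + cds[cut:]
        m = len(sense)
        if strand == "+":
            exons = [(0, cut - 1), (cut + len(intron), m - 1)]
            segment = sense
        else:
            segment = revcomp(sense)
            # sense index i -> genomic offset m-1-i
            exons = [(0, m - 1 - (cut + len(intron))), (m - cut, m - 1)]
    else:
        sense = cds
        m = len(sense)
        exons = [(0, m - 1)]
        segment = sense if strand == "+" else revcomp(sense)
    return _GeneRequest(segment, [(gene_id, 0, m - 1, strand, exons, family)])


def _array_request(rng: np.random.Generator, family: str, copies: int,
                   config: SimulationConfig) -> _GeneRequest:
    """Tandem array: adjacent same-family copies, ~2% diverged between copies."""
    n_codons = 300
    base = _random_cds(rng, n_codons)
    strand = "+" if rng.random() < 0.5 else "-"
    spacer_len = 30
    parts: list[str] = []
    genes = []
    offset = 0
    for i in range(copies):
        seq = base
        if i > 0:
            chars = list(seq)
            nmut = max(1, int(round(0.02 * len(seq))))
            sites = rng.choice(len(seq), size=nmut, replace=False)
            for s in sorted(int(x) for x in sites):
                chars[s] = _mutate_base(rng, chars[s], 0.5)
            seq = "".join(chars)
        segment = seq if strand == "+" else revcomp(seq)
        parts.append(segment)
        genes.append((f"{family}_{i + 1}", offset, offset + len(segment) - 1, strand,
                      [(offset, offset + len(segment) - 1)], family))
        offset += len(segment)
        if i < copies - 1:
            spacer = random_dna(rng, spacer_len, config.gc_content)
            parts.append(spacer)
            offset += spacer_len
    return _GeneRequest("".join(parts), genes)


_PURINES = {"A", "G"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _mutate_base(rng: np.random.Generator, base: str, transition_fraction: float) -> str:
    """Substitute a base, transitions drawn at the configured fraction."""
    if rng.random() < transition_fraction:
        return _TRANSITION[base]
    # transversion: the two bases of the other chemical class
    tv = ["C", "T"] if base in _PURINES else ["A", "G"]
    return tv[int(rng.integers(0, 2))]


def generate_ancestor(config: SimulationConfig) -> AnnotatedGenome:
    """Generate the ancestral annotated genome.

    Chromosomes are i.i.d. bases at the configured GC content, flanked by
    >= ``telomere_copies`` copies of the telomeric unit (reverse-complemented
    at the right end), carrying non-overlapping ORF-like genes on both strands
    at ``gene_density`` plus the configured tandem arrays.  Deterministic
    given the seed.
    """
    config.validate()
    rng = _rng(config, _STREAM_ANCESTOR)
    tel_left = config.telomere_unit * config.telomere_copies
    tel_right = revcomp(config.telomere_unit) * config.telomere_copies
    margin = 60
    interior_len = config.chrom_length - len(tel_left) - len(tel_right) - 2 * margin
    if interior_len <= 0:
        raise ValueError("chrom_length too small for telomeres")

    n_regular = int(round(config.gene_density * config.chrom_length / 10_000))
    records: list[SeqRecord] = []
    genes: list[GeneModel] = []
    gene_counter = 1

    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        requests: list[_GeneRequest] = []
        # tandem arrays round-robin across chromosomes
        for idx, (fam, copies_a, _copies_b) in enumerate(config.tandem_events):
            if idx % config.n_chromosomes == c and copies_a >= 1:
                requests.append(_array_request(rng, fam, copies_a, config))
        for _ in range(n_regular):
            gid = f"g{gene_counter:04d}"
            requests.append(_single_gene_request(rng, gid, f"FAM{gene_counter:04d}", config))
            gene_counter += 1
        rng.shuffle(requests)

        total_gene_len = sum(len(r.segment) for r in requests)
        free = interior_len - total_gene_len
        min_gap = 50
        if free < (len(requests) + 1) * min_gap:
            raise ValueError(
                f"gene_density {config.gene_density} infeasible for chrom_length {config.chrom_length}"
            )
        extra = free - (len(requests) + 1) * min_gap
        gaps = rng.multinomial(extra, [1.0 / (len(requests) + 1)] * (len(requests) + 1))
        gaps = [int(g) + min_gap for g in gaps]

        parts = [tel_left, random_dna(rng, margin, config.gc_content)]
        pos = len(tel_left) + margin  # 0-based cursor
        for req, gap in zip(requests, gaps):
            parts.append(random_dna(rng, gap, config.gc_content))
            pos += gap
            parts.append(req.segment)
            for gid, rel_s, rel_e, strand, rel_exons, fam in req.genes:
                start = pos + rel_s + 1  # to 1-based
                end = pos + rel_e + 1
                exons = [(pos + s + 1, pos + e + 1) for s, e in rel_exons]
                genes.append(GeneModel(gid, chrom, start, end, strand, "CDS",
                                       exons=exons, ortholog_label=fam))
            pos += len(req.segment)
        parts.append(random_dna(rng, gaps[-1], config.gc_content))
        pos += gaps[-1]
        parts.append(random_dna(rng, margin, config.gc_content))
        parts.append(tel_right)
        seq = "".join(parts)
        assert len(seq) == config.chrom_length, (len(seq), config.chrom_length)
        records.append(SeqRecord(chrom, seq))

    genes.sort(key=lambda g: (g.chromosome, g.start))
    return AnnotatedGenome(records, genes, name="ancestor")


# --- variant application / normalisation ------------------------------------

def left_normalize(chrom_seq: str, pos: int, ref: str, alt: str, vtype: str
                   ) -> tuple[int, str, str]:
    """Shift an indel to its leftmost equivalent representation.

    ``pos`` is 1-based; deletions carry the deleted bases in ``ref`` (alt='-'),
    insertions the inserted bases in ``alt`` (ref='-', inserted *after* pos).
    """
    if vtype == "SNP":
        return pos, ref, alt
    if vtype == "del":
        n = len(ref)
        while pos > 1 and chrom_seq[pos - 2] == chrom_seq[pos + n - 2]:
            pos -= 1
        return pos, chrom_seq[pos - 1 : pos - 1 + n], alt
    if vtype == "ins":
        seq = alt
        while pos >= 1 and chrom_seq[pos - 1] == seq[-1]:
            seq = seq[-1] + seq[:-1]
            pos -= 1
        return pos, ref, seq
    raise ValueError(vtype)


def apply_variants(genome: AnnotatedGenome, variants: list[tuple[str, int, str, str, str]]
                   ) -> dict[str, str]:
    """Apply truth variants to a genome, returning chrom -> derived sequence.

    Events are applied right-to-left so stored 1-based reference coordinates
    stay valid throughout.
    """
    out = {}
    by_chrom: dict[str, list] = {}
    for v in variants:
        by_chrom.setdefault(v[0], []).append(v)
    for rec in genome.records:
        seq = rec.sequence
        events = sorted(by_chrom.get(rec.id, []), key=lambda v: v[1], reverse=True)
        for _chrom, pos, ref, alt, vtype in events:
            i = pos - 1
            if vtype == "SNP":
                assert seq[i] == ref, (pos, seq[i], ref)
                seq = seq[:i] + alt + seq[i + 1 :]
            elif vtype == "del":
                assert seq[i : i + len(ref)] == ref
                seq = seq[:i] + seq[i + len(ref) :]
            elif vtype == "ins":
                seq = seq[: i + 1] + alt + seq[i + 1 :]
            else:
                raise ValueError(vtype)
        out[rec.id] = seq
    return out


def _lift_genes(genes: list[GeneModel], variants, chrom_lengths) -> list[GeneModel]:
    """Lift gene models through indels (coordinate shifts; deletions clamp)."""
    shifts: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, pos, ref, alt, vtype in variants:
        if vtype == "ins":
            shifts.setdefault(chrom, []).append((pos, len(alt), 0))
        elif vtype == "del":
            shifts.setdefault(chrom, []).append((pos, -len(ref), len(ref)))
    for ch in shifts:
        shifts[ch].sort()

    def lift(chrom: str, c: int) -> int:
        delta = 0
        for pos, d, dlen in shifts.get(chrom, []):
            if vpos_before(pos, d, dlen, c):
                delta += d
            elif d < 0 and pos <= c < pos + dlen:
                # coordinate inside a deleted range: clamp to deletion start
                return pos + delta
        return c + delta

    def vpos_before(pos, d, dlen, c):
        if d > 0:   # insertion after pos
            return pos < c
        return pos + dlen <= c

    out = []
    for g in genes:
        s, e = lift(g.chromosome, g.start), lift(g.chromosome, g.end)
        exons = [(lift(g.chromosome, a), lift(g.chromosome, b)) for a, b in g.exons]
        exons = [(a, b) for a, b in exons if a <= b]
        if s > e or not exons:
            continue
        out.append(GeneModel(g.gene_id, g.chromosome, s, e, g.strand, g.feature_type,
                             exons=exons, ortholog_label=g.ortholog_label))
    return out


def _draw_event_positions(rng, seq_len: int, rate: float, forbidden_start: int,
                          forbidden_end: int, spacing: int,
                          taken: list[int]) -> list[int]:
    """Poisson-ish event positions (1-based) with a minimum spacing, keeping
    clear of chromosome ends and previously taken positions."""
    hits = np.flatnonzero(rng.random(seq_len) < rate) + 1
    out = []
    taken_sorted = sorted(taken)
    last = -10**9
    for p in hits:
        p = int(p)
        if p < forbidden_start or p > forbidden_end:
            continue
        if p - last < spacing:
            continue
        i = np.searchsorted(taken_sorted, p)
        near = []
        if i > 0:
            near.append(taken_sorted[i - 1])
        if i < len(taken_sorted):
            near.append(taken_sorted[i])
        if any(abs(p - t) < spacing for t in near):
            continue
        out.append(p)
        last = p
    return out


def derive_strain(ancestor: AnnotatedGenome, config: SimulationConfig, which: str
                  ) -> tuple[AnnotatedGenome, TruthSet]:
    """Derive one strain of the pair.

    Strain "A" is the reference lineage (identical to the ancestor); strain
    "B" carries the pair's substitutions and 1-5 base indels at the configured
    rates plus one introgressed block whose sequence is replaced by a donor
    haplotype diverged by ``introgression_divergence``.
    """
    config.validate()
    if which not in ("A", "B"):
        raise ValueError(f"which must be 'A' or 'B', got {which!r}")
    if which == "A":
        g = copy.deepcopy(ancestor)
        g.name = "strainA"
        return g, TruthSet(provenance_seed=config.seed)

    rng = _rng(config, _STREAM_STRAIN_B)
    tel_pad = len(config.telomere_unit) * config.telomere_copies + 50
    truth = TruthSet(provenance_seed=config.seed)
    all_variants: list[tuple[str, int, str, str, str]] = []

    # introgressed block on the first chromosome
    chrom0 = ancestor.records[0]
    lo = tel_pad + 1000
    hi = len(chrom0) - tel_pad - 1000 - config.introgression_length
    if hi <= lo:
        raise ValueError("introgression interval collides with chromosome end")
    intro_start = int(rng.integers(lo, hi))
    intro_end = intro_start + config.introgression_length - 1
    truth.introgression = (chrom0.id, intro_start, intro_end)

    for rec in ancestor.records:
        seq = rec.sequence
        taken: list[int] = []
        if rec.id == chrom0.id:
            # donor haplotype: independent substitutions at the divergence rate
            block_hits = np.flatnonzero(
                rng.random(config.introgression_length) < config.introgression_divergence
            )
            for off in block_hits:
                pos = intro_start + int(off)
                ref = seq[pos - 1]
                alt = _mutate_base(rng, ref, config.transition_fraction)
                all_variants.append((rec.id, pos, ref, alt, "SNP"))
                taken.append(pos)

        def in_block(p: int) -> bool:
            return rec.id == chrom0.id and intro_start - 20 <= p <= intro_end + 20

        sub_pos = _draw_event_positions(rng, len(seq), config.strain_sub_rate,
                                        tel_pad, len(seq) - tel_pad, 6, taken)
        for p in sub_pos:
            if in_block(p):
                continue
            ref = seq[p - 1]
            alt = _mutate_base(rng, ref, config.transition_fraction)
            all_variants.append((rec.id, p, ref, alt, "SNP"))
            taken.append(p)

        indel_pos = _draw_event_positions(rng, len(seq), config.strain_indel_rate,
                                          tel_pad, len(seq) - tel_pad - 10, 12, taken)
        for p in indel_pos:
            if in_block(p):
                continue
            length = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                ref = seq[p - 1 : p - 1 + length]
                p2, ref2, alt2 = left_normalize(seq, p, ref, "-", "del")
                all_variants.append((rec.id, p2, ref2, alt2, "del"))
            else:
                ins = random_dna(rng, length, config.gc_content)
                p2, ref2, alt2 = left_normalize(seq, p, "-", ins, "ins")
                all_variants.append((rec.id, p2, ref2, alt2, "ins"))

    truth.variants = all_variants
    truth.sort()
    derived = apply_variants(ancestor, truth.variants)
    genes = _lift_genes(ancestor.genes, truth.variants,
                        {r.id: len(r) for r in ancestor.records})
    records = [SeqRecord(r.id, derived[r.id]) for r in ancestor.records]
    return AnnotatedGenome(records, genes, name="strainB"), truth


# --- species derivation ------------------------------------------------------

def derive_species(ancestor: AnnotatedGenome, config: SimulationConfig
                   ) -> tuple[AnnotatedGenome, TruthSet]:
    """Derive the sibling species: tandem copy-number changes, reciprocal
    translocations at inter-gene breakpoints, then genome-wide substitutions.

    Truth breakpoints record the *novel* adjacencies created in the species
    genome: (species_chromosome, left_gene, right_gene,
    ancestral_chromosome_of_right_gene, "reciprocal").
    """
    config.validate()
    rng = _rng(config, _STREAM_SPECIES)
    seqs = {r.id: r.sequence for r in ancestor.records}
    genes = [copy.deepcopy(g) for g in ancestor.genes]
    truth = TruthSet(provenance_seed=config.seed)

    fam_of = {g.gene_id: g.ortholog_label for g in genes}
    home_chrom = {g.gene_id: g.chromosome for g in ancestor.genes}

    # 1. tandem copy-number adjustment (delete trailing copies / duplicate)
    for fam, copies_a, copies_b in config.tandem_events:
        members = sorted([g for g in genes if g.ortholog_label == fam],
                         key=lambda g: g.start)
        if not members:
            raise ValueError(f"tandem family {fam!r} absent from ancestor")
        chrom = members[0].chromosome
        if copies_b < copies_a:
            # rightmost first so earlier coordinates stay valid
            for victim in reversed(members[copies_b:]):
                seqs, genes = _delete_span(seqs, genes, victim.chromosome,
                                           victim.start, victim.end)
        elif copies_b > copies_a:
            template = members[-1]
            for i in range(copies_b - copies_a):
                seqs, genes = _duplicate_gene(seqs, genes, template,
                                              f"{fam}_{copies_a + i + 1}", rng, config)
    # 2. reciprocal translocations
    used_flanks: set[str] = set()
    chrom_names = [r.id for r in ancestor.records]
    for t in range(config.n_translocations):
        if len(chrom_names) < 2:
            raise ValueError("need >= 2 chromosomes for reciprocal translocations")
        cut_a = cut_b = None
        for _attempt in range(20):
            pair = rng.choice(len(chrom_names), size=2, replace=False)
            ca, cb = chrom_names[int(pair[0])], chrom_names[int(pair[1])]
            cut_a = _pick_cut(rng, genes, ca, used_flanks)
            cut_b = _pick_cut(rng, genes, cb, used_flanks)
            if cut_a is not None and cut_b is not None:
                break
        if cut_a is None or cut_b is None:
            raise ValueError("no feasible inter-gene breakpoint left")
        (pos_a, left_a, right_a) = cut_a
        (pos_b, left_b, right_b) = cut_b
        used_flanks.update({left_a, right_a, left_b, right_b})

        new_a = seqs[ca][:pos_a] + seqs[cb][pos_b:]
        new_b = seqs[cb][:pos_b] + seqs[ca][pos_a:]
        for g in genes:
            if g.chromosome == ca and g.start > pos_a:
                _shift_gene(g, cb, pos_b - pos_a)
            elif g.chromosome == cb and g.start > pos_b:
                _shift_gene(g, ca, pos_a - pos_b)
        # swap the tails' chromosome labels recorded above: genes moved from
        # ca tail now live on the chromosome that keeps name ca? No: head keeps
        # its name, so ca head + cb tail is chromosome ca.
        seqs[ca], seqs[cb] = new_a, new_b
        truth.breakpoints.append((ca, left_a, right_b, home_chrom[right_b], "reciprocal"))
        truth.breakpoints.append((cb, left_b, right_a, home_chrom[right_a], "reciprocal"))

    # 3. genome-wide substitutions (positions not recorded: species-level
    #    divergence is scored through identity, not per-variant recall)
    if config.species_sub_rate > 0:
        for chrom in sorted(seqs):
            arr = np.frombuffer(seqs[chrom].encode(), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(len(arr)) < config.species_sub_rate)
            for i in hits:
                base = chr(arr[i])
                arr[i] = ord(_mutate_base(rng, base, config.transition_fraction))
            seqs[chrom] = arr.tobytes().decode()

    # truth tandem arrays (per genome, post-editing)
    for fam, copies_a, copies_b in config.tandem_events:
        chrom = next(g.chromosome for g in ancestor.genes if g.ortholog_label == fam)
        truth.tandem_arrays.append((fam, "A", chrom, copies_a))
        sp_members = [g for g in genes if g.ortholog_label == fam]
        sp_chrom = sp_members[0].chromosome if sp_members else chrom
        truth.tandem_arrays.append((fam, "B", sp_chrom, copies_b))

    genes.sort(key=lambda g: (g.chromosome, g.start))
    records = [SeqRecord(cid, seqs[cid]) for cid in chrom_names]
    return AnnotatedGenome(records, genes, name="species"), truth


def _shift_gene(g: GeneModel, new_chrom: str, delta: int) -> None:
    g.chromosome = new_chrom
    g.start += delta
    g.end += delta
    g.exons = [(a + delta, b + delta) for a, b in g.exons]


def _pick_cut(rng, genes: list[GeneModel], chrom: str, used: set[str]
              ) -> Optional[tuple[int, str, str]]:
    """Pick an inter-gene cut on a chromosome between two 1:1-mapped regular
    genes (gene ids starting with 'g'), avoiding previously used flanks and
    chromosome ends.  Returns (0-based cut position, left_gene, right_gene)."""
    order = sorted([g for g in genes if g.chromosome == chrom], key=lambda g: g.start)
    candidates = []
    for i in range(len(order) - 1):
        g1, g2 = order[i], order[i + 1]
        if not (g1.gene_id.startswith("g") and g2.gene_id.startswith("g")):
            continue
        if g1.gene_id in used or g2.gene_id in used:
            continue
        if i < 2 or i > len(order) - 4:  # keep away from chromosome ends
            continue
        if g2.start - g1.end < 20:
            continue
        candidates.append((i, g1, g2))
    if not candidates:
        return None
    i, g1, g2 = candidates[int(rng.integers(0, len(candidates)))]
    cut = (g1.end + g2.start) // 2  # 0-based: sequence[:cut] keeps g1
    return cut, g1.gene_id, g2.gene_id


def _delete_span(seqs, genes, chrom, start, end):
    """Delete [start,end] (1-based inclusive) plus its gene; shift the rest."""
    seq = seqs[chrom]
    seqs = dict(seqs)
    seqs[chrom] = seq[: start - 1] + seq[end:]
    delta = -(end - start + 1)
    out = []
    for g in genes:
        if g.chromosome == chrom and g.start >= start and g.end <= end:
            continue
        if g.chromosome == chrom and g.start > end:
            g = copy.deepcopy(g)
            _shift_gene(g, chrom, delta)
            g.chromosome = chrom
        out.append(g)
    return seqs, out


def _duplicate_gene(seqs, genes, template: GeneModel, new_id: str, rng,
                    config: SimulationConfig):
    """Insert a slightly diverged copy of a gene immediately after it."""
    chrom = template.chromosome
    seq = seqs[chrom]
    gene_seq = seq[template.start - 1 : template.end]
    chars = list(gene_seq)
    nmut = max(1, int(round(0.02 * len(chars))))
    for s in sorted(int(x) for x in rng.choice(len(chars), size=nmut, replace=False)):
        chars[s] = _mutate_base(rng, chars[s], 0.5)
    spacer = random_dna(rng, 30, config.gc_content)
    insert = spacer + "".join(chars)
    ins_at = template.end  # 0-based index == insert after this 1-based pos
    seqs = dict(seqs)
    seqs[chrom] = seq[:ins_at] + insert + seq[ins_at:]
    delta = len(insert)
    out = []
    for g in genes:
        if g.chromosome == chrom and g.start > template.end:
            g = copy.deepcopy(g)
            _shift_gene(g, chrom, delta)
            g.chromosome = chrom
        out.append(g)
    new_start = template.end + len(spacer) + 1
    new_end = new_start + len(chars) - 1
    out.append(GeneModel(new_id, chrom, new_start, new_end, template.strand, "CDS",
                         exons=[(new_start, new_end)], ortholog_label=template.ortholog_label))
    return seqs, out


# --- read simulation ---------------------------------------------------------

def simulate_reads(genome: AnnotatedGenome, config: SimulationConfig,
                   stream: int = _STREAM_READS):
    """Simulate single-end reads and mate pairs from a genome.

    Returns ``(singles, mates1, mates2)``, each a list of
    ``(SeqRecord, phred_list)``.  Single reads are ``read_length`` bases drawn
    uniformly over positions and strands to the configured expected depth.
    Mate pairs are two ``matepair_read_length`` reads from the ends of a
    fragment whose span is Normal(insert_mean, insert_sd), emitted
    outward-facing by default (jumping-library convention).  Per-base quality
    classes are sampled from the 4-class profile and substitution errors
    injected at each class's rate.  Read names encode the true origin for
    debugging only.
    """
    config.validate()
    rng = _rng(config, stream)
    R = config.read_length
    M = config.matepair_read_length
    phred_of = config.quality_class_phred
    err_of = config.seq_error_rate_by_quality_class
    class_probs = list(config.quality_class_probs)

    singles: list = []
    mates1: list = []
    mates2: list = []

    def finish_read(name: str, seq: str):
        classes = rng.choice(4, size=len(seq), p=class_probs)
        chars = list(seq)
        for i, cl in enumerate(classes):
            if rng.random() < err_of[int(cl)]:
                chars[i] = _mutate_base(rng, chars[i], 1 / 3)
        phred = [phred_of[int(c)] for c in classes]
        return (SeqRecord(name, "".join(chars)), phred)

    for rec in genome.records:
        L = len(rec.sequence)
        if R > L:
            raise ValueError(f"read length {R} exceeds chromosome {rec.id} length {L}")
        n_single = int(round(config.depth * L / R))
        starts = rng.integers(0, L - R + 1, size=n_single)
        strands = rng.random(n_single) < 0.5
        for i in range(n_single):
            s = int(starts[i])
            frag = rec.sequence[s : s + R]
            if "N" in frag:
                continue
            strand = "-" if strands[i] else "+"
            if strand == "-":
                frag = revcomp(frag)
            singles.append(finish_read(f"sr{len(singles)}_{rec.id}_{s + 1}_{strand}", frag))

        if config.mate_depth > 0 and L > config.insert_mean + 4 * config.insert_sd:
            n_pairs = int(round(config.mate_depth * L / (2 * M)))
            spans = rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
            spans = np.clip(np.rint(spans), 2 * M + 10, L).astype(int)
            lefts = rng.integers(0, np.maximum(L - spans + 1, 1))
            for i in range(n_pairs):
                s, span = int(lefts[i]), int(spans[i])
                left_seq = rec.sequence[s : s + M]
                right_seq = rec.sequence[s + span - M : s + span]
                if "N" in left_seq or "N" in right_seq:
                    continue
                if config.mate_orientation == "outward":
                    r1, r2 = revcomp(left_seq), right_seq
                else:  # innie
                    r1, r2 = left_seq, revcomp(right_seq)
                name = f"mp{len(mates1)}_{rec.id}_{s + 1}_{s + span}"
                mates1.append(finish_read(name + "/1", r1))
                mates2.append(finish_read(name + "/2", r2))
    return singles, mates1, mates2


def stratified_reads(sequence: str, read_length: int, depth: float,
                     rng: np.random.Generator,
                     quality_class: int = 3) -> list[tuple[str, list[int]]]:
    """Error-free reads at ``depth`` with stratified (jittered-tiling) starts.

    The start axis is split into ``depth * L / R`` equal strata with one
    uniform start per stratum, so consecutive starts are never more than two
    strata apart and the terminal bases are always covered.  This is the
    even-coverage sampling mode used for assembler reconstruction work, where
    the interest is the algorithm rather than coverage fluctuation; the
    pipeline's ``simulate_reads`` keeps fully uniform sampling.

    Returns (sequence, quality classes) pairs ready for the assembler;
    strands alternate deterministically.
    """
    L = len(sequence)
    R = read_length
    if R > L:
        raise ValueError("read length exceeds sequence length")
    n = max(int(round(depth * L / R)), 2)
    edges = np.linspace(0, L - R, n + 1)
    reads: list[tuple[str, list[int]]] = []
    quals = [quality_class] * R
    for i in range(n):
        lo, hi = edges[i], edges[i + 1]
        s = int(lo + rng.random() * max(hi - lo, 1e-9))
        s = min(s, L - R)
        frag = sequence[s : s + R]
        if i % 2 == 1:
            frag = revcomp(frag)
        reads.append((frag, quals))
    # explicit terminal reads so the first and last base are always present
    reads.append((sequence[:R], quals))
    reads.append((sequence[L - R :], quals))
    return reads


def error_free(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with sequencing error switched off."""
    return replace(config, seq_error_rate_by_quality_class=(0.0, 0.0, 0.0, 0.0))


def write_ortholog_rows(genome_a: AnnotatedGenome, genome_b: AnnotatedGenome
                        ) -> list[tuple[str, str, str]]:
    """Identity ortholog rows for the 1:1 (regular) genes shared by two
    simulated genomes; tandem family members are left unmapped."""
    ids_b = {g.gene_id for g in genome_b.genes}
    rows = []
    for g in genome_a.genes:
        if g.gene_id.startswith("g") and g.gene_id in ids_b:
            rows.append((g.gene_id, g.gene_id, g.ortholog_label))
    return rows
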