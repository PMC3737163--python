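"""Reference-guided scaffolding with mate-pair confirmation.

Contigs are placed on a related reference genome by chaining unique 31-mer
anchors (longest increasing subsequence; orientation from the chain strand).
Mate pairs mapped onto the contigs link contig ends; a link needs
``min_links`` concordant pairs and estimates the gap as the median of
(insert_mean - the two within-contig spans).  Scaffold order follows the
reference, but pairing information wins where the reference placement is
ambiguous (repeat contigs with secondary placements).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Optional, Sequence

from .anchors import (DEFAULT_K, anchor_matches, anchor_matches_multi,
                      kmer_index, lis_chain, unique_kmer_index)
from .io_formats import SeqRecord, revcomp


@dataclass
class ScaffoldConfig:
    k: int = DEFAULT_K
    insert_mean: int = 1_600
    insert_sd: int = 150
    min_links: int = 3
    mate_orientation: str = "outward"
    secondary_fraction: float = 0.9  # chains within 10% of best get secondaries


@dataclass
class ContigPlacement:
    contig_id: str
    reference_chromosome: str
    reference_start: int      # 1-based
    orientation: str          # + | -
    anchor_count: int
    secondary_placements: list[tuple[str, int, str, int]] = field(default_factory=list)


@dataclass
class MatePairLink:
    contig_a: str
    end_a: str                # 5' (left) as "L" or 3' (right) as "R"
    contig_b: str
    end_b: str
    supporting_pairs: int
    implied_gap: int          # may be negative


@dataclass
class Scaffold:
    id: str
    items: list[tuple[str, str, int]]  # (contig_id, orientation, gap_after)
    unlinked_adjacencies: list[int] = field(default_factory=list)


def anchor_contigs(contigs: Sequence[SeqRecord], reference: Sequence[SeqRecord],
                   config: Optional[ScaffoldConfig] = None) -> list[ContigPlacement]:
    """Place contigs on the reference by unique-k-mer anchor chaining."""
    config = config or ScaffoldConfig()
    k = config.k
    ref_index = kmer_index({r.id: r.sequence for r in reference}, k)
    placements: list[ContigPlacement] = []
    for contig in contigs:
        if len(contig.sequence) < k:
            raise ValueError(f"contig {contig.id} shorter than k={k}")
        grouped = anchor_matches_multi(contig.sequence, ref_index, k)
        chains: list[tuple[int, str, int, str]] = []  # (score, chrom, start, orient)
        for (chrom, strand, _bucket), matches in sorted(grouped.items()):
            chain = lis_chain(matches)
            if not chain:
                continue
            qpos, tpos = chain[0]
            start = tpos - qpos + 1
            chains.append((len(chain), chrom, max(start, 1), strand))
        # chains split by a diagonal-bucket boundary describe one placement:
        # merge same-chromosome/strand chains whose starts nearly coincide
        chains.sort(key=lambda t: (t[1], t[3], t[2]))
        merged: list[tuple[int, str, int, str]] = []
        for score, chrom, start, strand in chains:
            if merged:
                ps, pc, pstart, pstrand = merged[-1]
                if (pc, pstrand) == (chrom, strand) and \
                        abs(start - pstart) < max(len(contig.sequence) // 2, 100):
                    merged[-1] = (ps + score, pc, min(pstart, start), pstrand)
                    continue
            merged.append((score, chrom, start, strand))
        chains = merged
        if not chains:
            continue
        chains.sort(key=lambda t: (-t[0], t[1], t[2]))
        best = chains[0]
        secondaries = [(c, s, o, n) for n, c, s, o in chains[1:]
                       if n >= config.secondary_fraction * best[0]]
        placements.append(ContigPlacement(contig.id, best[1], best[2], best[3],
                                          best[0], secondaries))
    return placements


def _map_read(seq: str, contig_index, k: int) -> Optional[tuple[str, int, str]]:
    """Map a read to (contig, 0-based start, strand) by its best anchor group."""
    grouped = anchor_matches(seq, contig_index, k)
    best = None
    for (contig, strand), matches in sorted(grouped.items()):
        if best is None or len(matches) > len(best[3]):
            best = (contig, strand, None, matches)
    if best is None:
        return None
    contig, strand, _, matches = best
    qpos, tpos = sorted(matches)[0]
    return contig, tpos - qpos, strand


def link_mate_pairs(mates1, mates2, contigs: Sequence[SeqRecord],
                    config: Optional[ScaffoldConfig] = None) -> list[MatePairLink]:
    """Build contig-end links from mate pairs mapped onto the contigs.

    Mate reads are placed with the same unique-k-mer anchoring used against
    the reference.  For each pair landing on two different contigs the
    fragment must exit each contig through a specific end; the within-contig
    span is the distance from the read's outer edge to that end.  Links with
    fewer than ``min_links`` concordant pairs, or spans incompatible with
    insert_mean + 3 insert_sd, are dropped.
    """
    config = config or ScaffoldConfig()
    k = config.k
    index = unique_kmer_index({c.id: c.sequence for c in contigs}, k)
    lengths = {c.id: len(c.sequence) for c in contigs}
    span_cap = config.insert_mean + 3 * config.insert_sd

    buckets: dict[tuple[str, str, str, str], list[int]] = {}
    for (r1, _q1), (r2, _q2) in zip(mates1, mates2):
        m1 = _map_read(r1.sequence, index, k)
        m2 = _map_read(r2.sequence, index, k)
        if m1 is None or m2 is None or m1[0] == m2[0]:
            continue
        sides = []
        ok = True
        for (contig, p, strand), read in ((m1, r1), (m2, r2)):
            read_len = len(read.sequence)
            if config.mate_orientation == "outward":
                interior_left = strand == "+"
            else:  # innie: reads point toward the interior
                interior_left = strand == "-"
            if interior_left:
                exit_end = "L"
                span = p + read_len
            else:
                exit_end = "R"
                span = lengths[contig] - p
            if span < 0 or span > span_cap:
                ok = False
            sides.append((contig, exit_end, span))
        if not ok:
            continue
        (ca, ea, sa), (cb, eb, sb) = sides
        if sa + sb > span_cap:
            continue
        if (cb, eb) < (ca, ea):
            (ca, ea, sa), (cb, eb, sb) = (cb, eb, sb), (ca, ea, sa)
        buckets.setdefault((ca, ea, cb, eb), []).append(config.insert_mean - sa - sb)

    links = []
    for (ca, ea, cb, eb), gaps in sorted(buckets.items()):
        if len(gaps) < config.min_links:
            continue
        links.append(MatePairLink(ca, ea, cb, eb, len(gaps), int(median(gaps))))
    return links


def _link_lookup(links: list[MatePairLink]) -> dict[tuple[str, str, str, str], MatePairLink]:
    table = {}
    for ln in links:
        table[(ln.contig_a, ln.end_a, ln.contig_b, ln.end_b)] = ln
        table[(ln.contig_b, ln.end_b, ln.contig_a, ln.end_a)] = ln
    return table


def _junction_ends(orient_left: str, orient_right: str) -> tuple[str, str]:
    """Contig ends facing each other for two adjacently placed contigs."""
    left_end = "R" if orient_left == "+" else "L"
    right_end = "L" if orient_right == "+" else "R"
    return left_end, right_end


def build_scaffolds(placements: list[ContigPlacement], links: list[MatePairLink],
                    reference: Sequence[SeqRecord], contigs: Sequence[SeqRecord],
                    config: Optional[ScaffoldConfig] = None) -> list[Scaffold]:
    """Order and orient contigs per reference chromosome into scaffolds.

    Multi-placement contigs are assigned to whichever candidate locus their
    mate-pair links support; gap sizes come from link estimates when present
    (floored at 1 N), otherwise from reference-implied distance.  Adjacencies
    without link support are kept (reference order) but flagged.
    """
    config = config or ScaffoldConfig()
    lengths = {c.id: len(c.sequence) for c in contigs}
    table = _link_lookup(links)
    linked_partners: dict[str, set[str]] = {}
    for ln in links:
        linked_partners.setdefault(ln.contig_a, set()).add(ln.contig_b)
        linked_partners.setdefault(ln.contig_b, set()).add(ln.contig_a)

    # resolve ambiguous contigs by link support at each candidate locus
    resolved: list[ContigPlacement] = []
    unambiguous = [p for p in placements if not p.secondary_placements]
    by_chrom_fixed: dict[str, list[ContigPlacement]] = {}
    for p in unambiguous:
        by_chrom_fixed.setdefault(p.reference_chromosome, []).append(p)
    for lst in by_chrom_fixed.values():
        lst.sort(key=lambda p: p.reference_start)

    for p in placements:
        if not p.secondary_placements:
            resolved.append(p)
            continue
        candidates = [(p.reference_chromosome, p.reference_start, p.orientation, p.anchor_count)]
        candidates += p.secondary_placements
        best = None
        for chrom, start, orient, count in candidates:
            neighbors = by_chrom_fixed.get(chrom, [])
            support = 0
            for q in neighbors:
                if abs(q.reference_start - start) <= 2 * config.insert_mean + lengths.get(q.contig_id, 0):
                    if q.contig_id in linked_partners.get(p.contig_id, set()):
                        support += 1
            key = (support, count)
            if best is None or key > best[0]:
                best = (key, (chrom, start, orient, count))
        chrom, start, orient, count = best[1]
        resolved.append(ContigPlacement(p.contig_id, chrom, start, orient, count,
                                        p.secondary_placements))

    by_chrom: dict[str, list[ContigPlacement]] = {}
    for p in resolved:
        by_chrom.setdefault(p.reference_chromosome, []).append(p)

    scaffolds = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda p: (p.reference_start, p.contig_id))
        items: list[tuple[str, str, int]] = []
        unlinked: list[int] = []
        for i, p in enumerate(ordered):
            gap_after = 0
            if i + 1 < len(ordered):
                q = ordered[i + 1]
                ea, eb = _junction_ends(p.orientation, q.orientation)
                link = table.get((p.contig_id, ea, q.contig_id, eb))
                if link is not None:
                    gap_after = max(link.implied_gap, 1)
                else:
                    implied = q.reference_start - (p.reference_start + lengths[p.contig_id])
                    gap_after = max(implied, 1)
                    unlinked.append(i)
            items.append((p.contig_id, p.orientation, gap_after))
        scaffolds.append(Scaffold(f"scaffold_{chrom}", items, unlinked))
    return scaffolds


def scaffold_sequence(scaffold: Scaffold, contigs: Sequence[SeqRecord]) -> SeqRecord:
    """Emit the scaffold sequence: oriented contigs separated by N runs."""
    by_id = {c.id: c.sequence for c in contigs}
    parts = []
    for i, (cid, orient, gap_after) in enumerate(scaffold.items):
        seq = by_id[cid]
        parts.append(seq if orient == "+" else revcomp(seq))
        if i + 1 < len(scaffold.items):
            parts.append("N" * max(gap_after, 1))
    return SeqRecord(scaffold.id, "".join(parts))


def write_agp(scaffolds: list[Scaffold], contigs: Sequence[SeqRecord], path) -> None:
    """AGP-like TSV: scaffold, start, end, component, orientation/gap."""
    by_id = {c.id: len(c.sequence) for c in contigs}
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tcomponent\torientation\n")
        for sc in scaffolds:
            pos = 1
            for i, (cid, orient, gap_after) in enumerate(sc.items):
                L = by_id[cid]
                fh.write(f"{sc.id}\t{pos}\t{pos + L - 1}\t{cid}\t{orient}\n")
                pos += L
                if i + 1 < len(sc.items):
                    g = max(gap_after, 1)
                    fh.write(f"{sc.id}\t{pos}\t{pos + g - 1}\tgap\t.\n")
                    pos += g
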