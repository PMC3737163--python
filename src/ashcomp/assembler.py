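"""Greedy hash-based short-read assembler.

The algorithm, built for uniform-length reads from a compact low-repeat
genome:

1. **pack_and_collapse** — each read is packed to 2 bits per base plus a
   2-bit quality class per base and stored in canonical orientation
   (lexicographically smaller of read / reverse complement).  Reads that are
   identical, or that differ only at positions where at least one of the two
   is in the lowest quality class, are combined with summed multiplicity.
2. **initial_contigs** — reads overlapping by exactly R-1 of R bases are
   chained into contigs (both orientations considered); a read end that can
   be extended by two different well-supported bases stays unjoined.
3. **detect_branch_points** — a divergence of multiple high-quality bases:
   >= 2 distinct next-bases each supported by >= ``min_branch_support``
   collapsed reads at quality class >= ``min_branch_quality``.
4. **join_contigs** — contigs are joined by decreasing end-overlap from R-1
   down to ``overlap_floor``; a join requires an exact, *unique* partner at
   both ends and neither end blocked by a branch point.
5. per-contig depth = total constituent read bases / contig length.

Read length is a parameter so toy instances (R=6) and 36-base production
reads share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_formats import revcomp

_BASE2BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS2BASE = "ACGT"


def pack_sequence(seq: str) -> int:
    """2-bit packing, first base in the highest-order slot."""
    v = 0
    for c in seq:
        v = (v << 2) | _BASE2BITS[c]
    return v


def unpack_sequence(v: int, length: int) -> str:
    out = []
    for i in range(length):
        out.append(_BITS2BASE[(v >> (2 * (length - 1 - i))) & 3])
    return "".join(out)


@dataclass
class PackedRead:
    """A collapsed read: 2-bit sequence, 2-bit quality classes, multiplicity."""

    bases: int
    quality_class: tuple[int, ...]
    length: int
    multiplicity: int = 1
    canonical: bool = True

    @property
    def sequence(self) -> str:
        return unpack_sequence(self.bases, self.length)

    def qual_at(self, i: int) -> int:
        return self.quality_class[i]


@dataclass
class BranchPoint:
    contig_id: str
    offset: int                      # 0-based position within the contig
    alleles: dict[str, int]          # base -> high-quality supporting reads

    def sort_key(self):
        return (self.contig_id, self.offset)


@dataclass
class Contig:
    id: str
    sequence: str
    depth: float = 0.0
    constituent_read_count: int = 0
    constituent_bases: int = 0
    blocked_left: bool = False
    blocked_right: bool = False
    # per-base quality classes, kept only while the contig is a single read
    # (oriented to ``sequence``); joins use it to trim uncorroborated
    # low-confidence overhang bases
    quality: tuple = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblerConfig:
    read_length: int = 36
    overlap_floor: int = 20
    min_branch_support: int = 2
    min_branch_quality: int = 2
    # contigs below this mean coverage after joining are uncorroborated
    # (chains of singleton, typically erroneous, reads) and are dropped
    min_contig_depth: float = 2.0
    # reads differing only at positions where either read is at or below
    # this class are combined (class 1 ~ phred 15, under the Q20 convention)
    low_quality_max_class: int = 1


@dataclass
class Assembly:
    contigs: list[Contig] = field(default_factory=list)
    branch_points: list[BranchPoint] = field(default_factory=list)
    parameters: Optional[AssemblerConfig] = None

    def contig_by_id(self, cid: str) -> Contig:
        for c in self.contigs:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def n50(self) -> int:
        lengths = sorted((len(c) for c in self.contigs), reverse=True)
        total = sum(lengths)
        acc = 0
        for L in lengths:
            acc += L
            if acc * 2 >= total:
                return L
        return 0


# --- packing and collapsing --------------------------------------------------

def _canonicalize(seq: str, quals: tuple[int, ...]) -> tuple[str, tuple[int, ...], bool]:
    rc = revcomp(seq)
    if rc < seq:
        return rc, tuple(reversed(quals)), False
    return seq, quals, True


def _quality_sum(read: PackedRead) -> int:
    return sum(read.quality_class) * read.multiplicity


def _mergeable(a: PackedRead, b: PackedRead, low_q: int = 1) -> bool:
    """Differ only at positions where at least one of the two reads is low
    quality (class <= ``low_q``)."""
    if a.bases == b.bases:
        return True
    sa, sb = a.sequence, b.sequence
    for i in range(a.length):
        if sa[i] != sb[i] and a.quality_class[i] > low_q and b.quality_class[i] > low_q:
            return False
    return True


def _merge(keep: PackedRead, other: PackedRead) -> PackedRead:
    """Merge ``other`` into ``keep`` (the higher-summed-quality variant);
    at each differing position the base comes from the higher-quality read."""
    sk, so = keep.sequence, other.sequence
    chars = list(sk)
    quals = list(keep.quality_class)
    for i in range(keep.length):
        if sk[i] != so[i] and other.quality_class[i] > keep.quality_class[i]:
            chars[i] = so[i]
        quals[i] = max(quals[i], other.quality_class[i])
    seq = "".join(chars)
    return PackedRead(pack_sequence(seq), tuple(quals), keep.length,
                      keep.multiplicity + other.multiplicity, keep.canonical)


def pack_and_collapse(reads: Iterable[tuple[str, Iterable[int]]],
                      low_quality_max_class: int = 1) -> list[PackedRead]:
    """Pack reads (sequence, per-base quality classes 0-3) and collapse
    duplicates and low-quality-only variants.

    Near-duplicate candidates are found by exact match on either read half
    (seed-and-verify), which catches any set of low-quality differences
    confined to one half.
    """
    packed: list[PackedRead] = []
    length: Optional[int] = None
    for seq, quals in reads:
        quals = tuple(int(q) for q in quals)
        if length is None:
            length = len(seq)
        if len(seq) != length or len(quals) != length:
            raise ValueError("non-uniform read length")
        if "N" in seq:
            raise ValueError("N base in read")
        cseq, cquals, canon = _canonicalize(seq, quals)
        packed.append(PackedRead(pack_sequence(cseq), cquals, length, 1, canon))
    if not packed:
        return []

    # exact collapse first
    by_seq: dict[int, PackedRead] = {}
    for r in packed:
        prev = by_seq.get(r.bases)
        by_seq[r.bases] = _merge(prev, r) if (
            prev is not None and _quality_sum(prev) >= _quality_sum(r)
        ) else (_merge(r, prev) if prev is not None else r)

    # near-duplicate collapse, highest summed quality first; candidates are
    # checked in both orientations of the incoming read because canonical
    # orientation can differ between near-duplicates
    entries = sorted(by_seq.values(), key=lambda r: (-_quality_sum(r), r.bases))
    half = length // 2
    survivors: list[PackedRead] = []
    left_index: dict[str, list[int]] = {}
    right_index: dict[str, list[int]] = {}

    for r in entries:
        variants = [r]
        rc_seq = revcomp(r.sequence)
        if rc_seq != r.sequence:
            variants.append(PackedRead(pack_sequence(rc_seq),
                                       tuple(reversed(r.quality_class)),
                                       r.length, r.multiplicity, not r.canonical))
        target = None
        oriented = None
        for cand in variants:
            seq = cand.sequence
            hits = set(left_index.get(seq[:half], [])) | set(right_index.get(seq[half:], []))
            for idx in sorted(hits):
                s = survivors[idx]
                if s is not None and _mergeable(s, cand, low_quality_max_class):
                    target, oriented = idx, cand
                    break
            if target is not None:
                break
        if target is None:
            idx = len(survivors)
            seq = r.sequence
            survivors.append(r)
            left_index.setdefault(seq[:half], []).append(idx)
            right_index.setdefault(seq[half:], []).append(idx)
        else:
            survivors[target] = _merge(survivors[target], oriented)

    out = [s for s in survivors if s is not None]
    # canonical orientation may have changed after consensus edits
    final = []
    for r in out:
        seq = r.sequence
        cseq, cquals, _ = _canonicalize(seq, r.quality_class)
        if cseq != seq:
            r = PackedRead(pack_sequence(cseq), cquals, r.length, r.multiplicity, r.canonical)
        final.append(r)
    final.sort(key=lambda r: r.bases)
    return final


# --- initial contigs (R-1 overlap chaining) ----------------------------------

def _oriented_words(read: PackedRead) -> list[tuple[str, tuple[int, ...]]]:
    seq = read.sequence
    return [(seq, read.quality_class),
            (revcomp(seq), tuple(reversed(read.quality_class)))]


def initial_contigs(packed_reads: list[PackedRead], read_length: int,
                    config: Optional[AssemblerConfig] = None) -> Assembly:
    """Chain reads with exact R-1 suffix/prefix overlaps into contigs.

    Equivalent to building unitigs of the graph whose nodes are the oriented
    read words and whose edges are exact (R-1)-base overlaps; extension stops
    where a word has more than one well-supported successor or predecessor
    (branch), or none.
    """
    config = config or AssemblerConfig(read_length=read_length)
    assembly = Assembly(parameters=config)
    if not packed_reads:
        return assembly
    R = read_length

    info: dict[str, PackedRead] = {}
    for r in packed_reads:
        for word, quals in _oriented_words(r):
            info[word] = r
    by_prefix: dict[str, list[str]] = {}
    for word in info:
        by_prefix.setdefault(word[: R - 1], []).append(word)
    for lst in by_prefix.values():
        lst.sort()

    def successors(word: str) -> list[str]:
        return [w for w in by_prefix.get(word[1:], []) if w != word]

    def predecessors(word: str) -> list[str]:
        # w precedes word iff w[1:] == word[:-1]; equivalently revcomp(w) is a
        # successor of revcomp(word), which the prefix index can answer.
        preds = []
        for w in by_prefix.get(revcomp(word)[1:], []):
            if w != revcomp(word):
                preds.append(revcomp(w))
        return sorted(preds)

    def _support(word: str, last_base: bool) -> int:
        """Collapsed-read support of a divergent word, counted only when the
        divergent base (first or last) is high quality."""
        r = info[word]
        seq = r.sequence
        if word == seq:
            quals = r.quality_class
        else:
            quals = tuple(reversed(r.quality_class))
        q = quals[-1] if last_base else quals[0]
        return r.multiplicity if q >= config.min_branch_quality else 0

    def _filtered(cands: list[str], last_base: bool) -> list[str]:
        """Resolve divergence: a lone well-supported candidate wins (weakly
        supported alternatives are noise, bypassed); two or more
        well-supported alternatives are a genuine branch (ambiguous)."""
        if len(cands) <= 1:
            return cands
        strong = [w for w in cands
                  if _support(w, last_base) >= config.min_branch_support]
        if len(strong) == 1:
            return strong
        return cands

    def unique_extension(word: str, forward: bool) -> Optional[str]:
        nxt = _filtered(successors(word), True) if forward \
            else _filtered(predecessors(word), False)
        if len(nxt) != 1:
            return None
        cand = nxt[0]
        back = _filtered(predecessors(cand), False) if forward \
            else _filtered(successors(cand), True)
        if back != [word]:
            return None
        return cand

    used: set[str] = set()
    contigs: list[Contig] = []
    blocked_info: list[tuple[int, bool, str]] = []  # (contig idx, right?, word at end)

    for r in packed_reads:
        start = r.sequence
        if start in used:
            continue
        # walk left to the start of the non-branching path
        left = start
        seen = {start, revcomp(start)}
        while True:
            prev = unique_extension(left, forward=False)
            if prev is None or prev in seen:
                break
            left = prev
            seen.add(left)
            seen.add(revcomp(left))
        # walk right collecting the path
        path = [left]
        seen = {left, revcomp(left)}
        while True:
            nxt = unique_extension(path[-1], forward=True)
            if nxt is None or nxt in seen:
                break
            path.append(nxt)
            seen.add(nxt)
            seen.add(revcomp(nxt))
        seq = path[0] + "".join(w[-1] for w in path[1:])
        if any(w in used for w in path):
            continue
        # terminal-base confidence trim: the chain overlap is R-1, so an
        # uncorroborated sequencing error can only sit on the very last base
        # contributed by an end word; drop it when that word is a singleton
        # and the base is below the top quality class
        if len(seq) > R:
            w = path[-1]
            r_end = info[w]
            q = r_end.quality_class if w == r_end.sequence \
                else tuple(reversed(r_end.quality_class))
            if q[-1] < 3:
                seq = seq[:-1]
            w = path[0]
            r0 = info[w]
            q = r0.quality_class if w == r0.sequence \
                else tuple(reversed(r0.quality_class))
            if q[0] < 3:
                seq = seq[1:]
        cseq = min(seq, revcomp(seq))
        for w in path:
            used.add(w)
            used.add(revcomp(w))
        n_reads = sum(info[w].multiplicity for w in path)
        quality = None
        if len(path) == 1:
            r = info[path[0]]
            q = r.quality_class if path[0] == r.sequence \
                else tuple(reversed(r.quality_class))
            quality = q if cseq == path[0] else tuple(reversed(q))
        contigs.append(Contig(
            id="", sequence=cseq,
            constituent_read_count=n_reads,
            constituent_bases=n_reads * R,
            quality=quality,
        ))

    contigs.sort(key=lambda c: c.sequence)
    for i, c in enumerate(contigs):
        c.id = f"ctg{i + 1:05d}"
        c.depth = c.constituent_bases / len(c)

    assembly.contigs = contigs
    assembly.branch_points = detect_branch_points(assembly, packed_reads, config)
    _apply_blocking(assembly)
    return assembly


def detect_branch_points(assembly: Assembly, packed_reads: list[PackedRead],
                         config: Optional[AssemblerConfig] = None) -> list[BranchPoint]:
    """Find contig ends whose single-base extensions diverge into >= 2 alleles
    each supported by >= min_branch_support reads at class >= min_branch_quality.

    The branch point is recorded at the terminal base of the contig whose
    extension it blocks.
    """
    config = config or assembly.parameters or AssemblerConfig()
    if not assembly.contigs or not packed_reads:
        return []
    R = packed_reads[0].length
    # index read words by their (R-1)-prefix, remembering the final base + quality
    ext: dict[str, list[tuple[str, int, int]]] = {}
    for r in packed_reads:
        for word, quals in _oriented_words(r):
            ext.setdefault(word[: R - 1], []).append((word[-1], quals[-1], r.multiplicity))

    out: list[BranchPoint] = []
    for contig in assembly.contigs:
        for right_end in (True, False):
            seq = contig.sequence if right_end else revcomp(contig.sequence)
            if len(seq) < R - 1:
                continue
            key = seq[-(R - 1):]
            support: dict[str, int] = {}
            for base, qual, mult in ext.get(key, []):
                if qual >= config.min_branch_quality:
                    support[base] = support.get(base, 0) + mult
            alleles = {b: n for b, n in support.items() if n >= config.min_branch_support}
            if len(alleles) >= 2:
                offset = len(contig) - 1 if right_end else 0
                out.append(BranchPoint(contig.id, offset, dict(sorted(alleles.items()))))
    out.sort(key=BranchPoint.sort_key)
    return out


def _apply_blocking(assembly: Assembly) -> None:
    by_id = {c.id: c for c in assembly.contigs}
    for bp in assembly.branch_points:
        c = by_id[bp.contig_id]
        if bp.offset == 0:
            c.blocked_left = True
        else:
            c.blocked_right = True


# --- joining -----------------------------------------------------------------

def join_contigs(assembly: Assembly, overlap_floor: Optional[int] = None) -> Assembly:
    """Join contigs by decreasing end-overlap from R-1 down to the floor.

    A join at overlap length L requires the L-base end words to match exactly,
    each end to have exactly one partner at that L (ambiguity skipped, not
    guessed), and neither involved end to be blocked by a branch point.
    Repeats at each L until a fixpoint.
    """
    config = assembly.parameters or AssemblerConfig()
    if overlap_floor is None:
        overlap_floor = config.overlap_floor
    R = config.read_length
    contigs = [Contig(c.id, c.sequence, c.depth, c.constituent_read_count,
                      c.constituent_bases, c.blocked_left, c.blocked_right,
                      c.quality)
               for c in assembly.contigs]

    for L in range(R - 1, overlap_floor - 1, -1):
        while True:
            joined = _join_pass(contigs, L)
            if not joined:
                break

    contigs.sort(key=lambda c: c.sequence)
    for i, c in enumerate(contigs):
        c.id = f"ctg{i + 1:05d}"
        c.depth = c.constituent_bases / len(c)
    # branch points live on the old contig ids; keep only parameters + contigs
    out = Assembly(contigs=contigs, branch_points=assembly.branch_points,
                   parameters=config)
    return out


def _join_pass(contigs: list[Contig], L: int) -> bool:
    """One batched merge pass at overlap length L.

    Builds the end-word index once, computes the unique joinable partner of
    every contig end, then performs all mutually-unique, unblocked joins whose
    contigs are not already consumed this pass.  Chains of joinable contigs
    collapse over O(log n) passes.  Returns True if any join happened.
    """
    index: dict[str, list[tuple[int, str]]] = {}
    for i, c in enumerate(contigs):
        if len(c) < L + 1:
            continue
        index.setdefault(c.sequence[:L], []).append((i, "L"))
        index.setdefault(c.sequence[-L:], []).append((i, "R"))

    def partners(i: int, side: str) -> list[tuple[int, str, bool]]:
        c = contigs[i]
        word = c.sequence[:L] if side == "L" else c.sequence[-L:]
        # a left end joins a right end carrying the same word (same strand);
        # same-kind ends join after reverse-complementing one contig
        valid = []
        for j, jside in index.get(word, []):
            if j != i and {side, jside} == {"L", "R"}:
                valid.append((j, jside, False))
        for j, jside in index.get(revcomp(word), []):
            if j != i and side == jside:
                valid.append((j, jside, True))
        if len(valid) > 1:
            # a lone corroborated partner beats uncorroborated single-read
            # contigs competing for the same end (noise tolerance; mirrors
            # the branch rule used during initial contig extension)
            solid = [p for p in valid if contigs[p[0]].constituent_read_count > 1]
            if len(solid) == 1:
                return solid
        return valid

    def blocked(i: int, side: str) -> bool:
        c = contigs[i]
        return c.blocked_right if side == "R" else c.blocked_left

    any_join = False
    consumed: set[int] = set()
    replacements: list[Contig] = []
    order = sorted(range(len(contigs)), key=lambda i: contigs[i].sequence)
    for i in order:
        if i in consumed or len(contigs[i]) < L + 1:
            continue
        for side in ("R", "L"):
            if i in consumed:
                break
            if blocked(i, side):
                continue
            cand = partners(i, side)
            if len(cand) != 1:
                continue
            j, jside, flipped = cand[0]
            if j in consumed or blocked(j, jside):
                continue
            if len(partners(j, jside)) != 1:
                continue
            merged = _merge_contigs(contigs[i], side, contigs[j], jside, flipped, L)
            if merged is None:
                continue
            consumed.add(i)
            consumed.add(j)
            replacements.append(merged)
            any_join = True
    if any_join:
        live = [c for k, c in enumerate(contigs) if k not in consumed]
        live.extend(replacements)
        contigs.clear()
        contigs.extend(live)
    return any_join


def _trusted_extension(seq: str, quality, L: int, overlap_right: bool):
    """For a single-word contig taking part in a join, the bases it may
    contribute beyond the overlap: scanning outward from the overlap
    boundary, extension stops at the first sub-top-quality base (an
    uncorroborated low-confidence call is never built into a longer contig).
    Returns the kept outer portion (possibly empty)."""
    if overlap_right:          # overlap is seq[-L:]; outer part to the left
        outer = seq[:-L] if L else seq
        if quality is None:
            return outer
        qs = quality[: len(outer)]
        for i in range(len(outer) - 1, -1, -1):
            if qs[i] < 3:
                return outer[i + 1:]
        return outer
    outer = seq[L:]            # overlap is seq[:L]; outer part to the right
    if quality is None:
        return outer
    qs = quality[L:]
    for i, q in enumerate(qs):
        if q < 3:
            return outer[:i]
    return outer


def _merge_contigs(c: Contig, cside: str, d: Contig, dside: str,
                   flipped: bool, L: int) -> Optional[Contig]:
    cs, ds = c.sequence, d.sequence
    cq, dq = c.quality, d.quality
    if flipped:
        ds = revcomp(ds)
        dq = tuple(reversed(dq)) if dq is not None else None
        dside = "L" if dside == "R" else "R"
        d_bl, d_br = d.blocked_right, d.blocked_left
    else:
        d_bl, d_br = d.blocked_left, d.blocked_right
    if cside == "R" and dside == "L":
        if cs[-L:] != ds[:L]:
            return None
        left = _trusted_extension(cs, cq, L, overlap_right=True)
        over = _trusted_extension(ds, dq, L, overlap_right=False)
        if not over:
            return None
        seq = left + cs[-L:] + over
        bl, br = c.blocked_left, d_br
    elif cside == "L" and dside == "R":
        if ds[-L:] != cs[:L]:
            return None
        right = _trusted_extension(cs, cq, L, overlap_right=False)
        over = _trusted_extension(ds, dq, L, overlap_right=True)
        if not over:
            return None
        seq = over + cs[:L] + right
        bl, br = d_bl, c.blocked_right
    else:
        return None
    if min(seq, revcomp(seq)) != seq:
        seq = revcomp(seq)
        bl, br = br, bl
    return Contig(c.id, seq, 0.0,
                  c.constituent_read_count + d.constituent_read_count,
                  c.constituent_bases + d.constituent_bases, bl, br)


def assemble(reads: Iterable[tuple[str, Iterable[int]]],
             config: Optional[AssemblerConfig] = None) -> Assembly:
    """Full pipeline: pack/collapse -> initial contigs -> branch points ->
    decreasing-overlap joining -> per-contig depth."""
    config = config or AssemblerConfig()
    packed = pack_and_collapse(reads, config.low_quality_max_class)
    if not packed:
        return Assembly(parameters=config)
    if packed[0].length != config.read_length:
        config = AssemblerConfig(packed[0].length, config.overlap_floor,
                                 config.min_branch_support,
                                 config.min_branch_quality,
                                 config.min_contig_depth,
                                 config.low_quality_max_class)
    assembly = initial_contigs(packed, config.read_length, config)
    joined = join_contigs(assembly)
    kept = [c for c in joined.contigs if c.depth >= config.min_contig_depth]
    if kept and len(kept) < len(joined.contigs):
        joined.contigs = kept
    return joined


def find_overlaps(packed_reads: list[PackedRead], overlap: int) -> set[tuple[str, str]]:
    """All oriented read-word pairs (a, b) where the length-``overlap`` suffix
    of a equals the prefix of b, found via the end-word hash index.

    Both orientations of every read are considered; self-pairs are excluded.
    """
    words = sorted({w for r in packed_reads for w, _q in _oriented_words(r)})
    by_prefix: dict[str, list[str]] = {}
    for w in words:
        by_prefix.setdefault(w[:overlap], []).append(w)
    out = set()
    for a in words:
        for b in by_prefix.get(a[-overlap:], []):
            if a != b:
                out.add((a, b))
    return out


def phred_to_class(phred: Iterable[int], bounds: tuple[int, int, int] = (10, 20, 30)) -> list[int]:
    """Map Phred scores to the 4 two-bit quality classes."""
    out = []
    for q in phred:
        if q < bounds[0]:
            out.append(0)
        elif q < bounds[1]:
            out.append(1)
        elif q < bounds[2]:
            out.append(2)
        else:
            out.append(3)
    return out
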