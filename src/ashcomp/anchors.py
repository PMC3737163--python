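"""Shared k-mer anchoring machinery.

Both the reference-guided scaffolder and the whole-genome comparator place
sequences by collecting k-mers that occur exactly once in each sequence,
matching them, and chaining collinear matches with a longest-increasing-
subsequence pass.  k defaults to 31, near-unique in a low-repeat genome of
the ~9 Mb scale this toolkit targets.
"""

from __future__ import annotations

from bisect import bisect_left

from .io_formats import revcomp

DEFAULT_K = 31


def unique_kmers(seq: str, k: int = DEFAULT_K) -> dict[str, int]:
    """k-mer -> start offset (0-based) for k-mers occurring exactly once."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        counts[kmer] = -1 if kmer in counts else i
    return {kmer: pos for kmer, pos in counts.items() if pos >= 0}


def unique_kmer_index(named_seqs: dict[str, str], k: int = DEFAULT_K) -> dict[str, tuple[str, int]]:
    """k-mer -> (name, offset) for k-mers unique across a set of sequences."""
    index: dict[str, tuple[str, int] | None] = {}
    for name in sorted(named_seqs):
        seq = named_seqs[name]
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index[kmer] = None if kmer in index else (name, i)
    return {kmer: loc for kmer, loc in index.items() if loc is not None}


def kmer_index(named_seqs: dict[str, str], k: int = DEFAULT_K,
               max_occurrences: int = 4) -> dict[str, list[tuple[str, int]]]:
    """k-mer -> all (name, offset) occurrences, for k-mers occurring at most
    ``max_occurrences`` times across the sequence set.

    Low-multiplicity k-mers are kept so that a contig matching a short
    repeat family can be offered every candidate locus (secondary
    placements); high-copy k-mers are dropped as uninformative.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for name in sorted(named_seqs):
        seq = named_seqs[name]
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            lst = index.get(kmer)
            if lst is None:
                index[kmer] = [(name, i)]
            elif len(lst) <= max_occurrences:
                lst.append((name, i))
    return {kmer: locs for kmer, locs in index.items()
            if len(locs) <= max_occurrences}


def lis_chain(matches: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of (query_pos, target_pos) pairs increasing in both.

    Input is sorted by query position; patience-sorting LIS on the target
    coordinate; ties broken toward earlier matches for determinism.
    """
    if not matches:
        return []
    matches = sorted(matches)
    tails: list[int] = []          # target values of chain tails
    tails_idx: list[int] = []      # index into matches of each tail
    parent = [-1] * len(matches)
    for i, (_q, t) in enumerate(matches):
        j = bisect_left(tails, t)
        if j == len(tails):
            tails.append(t)
            tails_idx.append(i)
        else:
            tails[j] = t
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(matches[i])
        i = parent[i]
    return chain[::-1]


def anchor_matches(query: str, target_index: dict[str, tuple[str, int]],
                   k: int = DEFAULT_K) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Collect unique-in-both k-mer matches of a query against an indexed
    target set, grouped by (target_name, strand).

    For '-' strand matches the query positions are reported on the
    reverse-complemented query so that chains are increasing in both
    coordinates.
    """
    q_unique = unique_kmers(query, k)
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    n = len(query)
    for kmer, qpos in q_unique.items():
        hit = target_index.get(kmer)
        if hit is not None:
            name, tpos = hit
            grouped.setdefault((name, "+"), []).append((qpos, tpos))
        rc_hit = target_index.get(revcomp(kmer))
        if rc_hit is not None:
            name, tpos = rc_hit
            # position of this k-mer on the reverse-complemented query
            grouped.setdefault((name, "-"), []).append((n - k - qpos, tpos))
    return grouped


def anchor_matches_multi(query: str, target_index: dict[str, list[tuple[str, int]]],
                         k: int = DEFAULT_K
                         ) -> dict[tuple[str, str, int], list[tuple[int, int]]]:
    """Anchor matches against a multi-occurrence index, grouped by
    (target_name, strand, diagonal bucket) so each repeat copy yields its own
    chainable group.  Query k-mers must still be unique within the query."""
    q_unique = unique_kmers(query, k)
    width = max(len(query), 1_000)
    grouped: dict[tuple[str, str, int], list[tuple[int, int]]] = {}
    n = len(query)
    for kmer, qpos in q_unique.items():
        for name, tpos in target_index.get(kmer, ()):
            bucket = (tpos - qpos) // width
            grouped.setdefault((name, "+", bucket), []).append((qpos, tpos))
        rc_qpos = n - k - qpos
        for name, tpos in target_index.get(revcomp(kmer), ()):
            bucket = (tpos - rc_qpos) // width
            grouped.setdefault((name, "-", bucket), []).append((rc_qpos, tpos))
    return grouped
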