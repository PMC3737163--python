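"""Gene-order synteny: translocation breakpoints, ancestry, tandem arrays.

Breakpoints are adjacencies present in one genome but split — across
chromosomes or across non-adjacent positions — in the other.  Only genes with
1:1 ortholog mappings take part in adjacency tests; unmapped genes (e.g.
members of expanded families) are flagged and skipped.  Two breakpoints whose
four arms exchange partners form one reciprocal translocation event.
Ancestry labels come from an outgroup: the genome whose adjacency the
outgroup shares is the ancestral one.

Tandem arrays are maximal runs of >= 2 same-family genes on one chromosome
with at most ``max_intervening`` other genes between consecutive members,
orientation-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io_formats import AnnotatedGenome, GeneModel


@dataclass
class GeneOrder:
    genome: str
    chromosomes: dict[str, list[tuple[str, str]]]  # chrom -> [(gene_id, strand)]
    position: dict[str, tuple[str, int]] = field(default_factory=dict)
    flagged_unmapped: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.position:
            for chrom, genes in self.chromosomes.items():
                for i, (gid, _s) in enumerate(genes):
                    self.position[gid] = (chrom, i)


@dataclass
class SyntenyBreakpoint:
    chromosome: str          # chromosome (in genome A) carrying the adjacency
    left_gene: str
    right_gene: str
    partner_chromosomes_in_b: tuple[str, ...]
    type: str = "unclear"    # reciprocal | adjacent_reciprocal | three_way | telomeric | unclear
    ancestry: str = "unclear"  # A_ancestral | B_ancestral | unclear
    event_id: Optional[int] = None


@dataclass
class TandemArray:
    genome: str
    chromosome: str
    family_label: str
    member_gene_ids: list[str]
    min_pairwise_identity: Optional[float] = None

    @property
    def copy_count(self) -> int:
        return len(self.member_gene_ids)


def build_gene_orders(annotations_a: list[GeneModel], annotations_b: list[GeneModel],
                      ortholog_rows: list[tuple], name_a: str = "A", name_b: str = "B"
                      ) -> tuple[GeneOrder, GeneOrder, dict[str, str]]:
    """Build per-chromosome gene orders and the 1:1 ortholog mapping.

    Rows pairing a gene more than once are dropped from the 1:1 mapping (the
    genes stay in the orders, flagged).  A table gene absent from the
    annotations is an error.
    """
    ids_a = {g.gene_id for g in annotations_a}
    ids_b = {g.gene_id for g in annotations_b}
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    for a, b, _fam in ortholog_rows:
        if a is not None and a not in ids_a:
            raise ValueError(f"ortholog table gene {a!r} absent from annotations A")
        if b is not None and b not in ids_b:
            raise ValueError(f"ortholog table gene {b!r} absent from annotations B")
        if a:
            count_a[a] = count_a.get(a, 0) + 1
        if b:
            count_b[b] = count_b.get(b, 0) + 1
    mapping = {a: b for a, b, _f in ortholog_rows
               if a and b and count_a[a] == 1 and count_b[b] == 1}

    def make_order(annotations, name, mapped_ids):
        chroms: dict[str, list[tuple[str, str]]] = {}
        for g in sorted(annotations, key=lambda g: (g.chromosome, g.start)):
            chroms.setdefault(g.chromosome, []).append((g.gene_id, g.strand))
        order = GeneOrder(name, chroms)
        order.flagged_unmapped = {gid for gid in order.position if gid not in mapped_ids}
        return order

    order_a = make_order(annotations_a, name_a, set(mapping))
    order_b = make_order(annotations_b, name_b, set(mapping.values()))
    return order_a, order_b, mapping


def _reduced(order: GeneOrder, keep: set[str]) -> dict[str, list[str]]:
    return {chrom: [gid for gid, _s in genes if gid in keep]
            for chrom, genes in order.chromosomes.items()}


def find_breakpoints(order_a: GeneOrder, order_b: GeneOrder, mapping: dict[str, str],
                     max_skip: int = 2) -> list[SyntenyBreakpoint]:
    """Breakpoints of genome A's gene order relative to genome B.

    For each pair of 1:1-mapped genes adjacent in A (unmapped genes skipped),
    a breakpoint is recorded when their orthologs land on different
    chromosomes of B or more than ``max_skip`` mapped genes apart.  Breakpoint
    pairs whose arms exchange partners are classified reciprocal;
    interlinked triples three_way; chromosome-terminal cases telomeric.
    """
    keep_a = set(mapping)
    keep_b = set(mapping.values())
    red_a = _reduced(order_a, keep_a)
    red_b = _reduced(order_b, keep_b)
    pos_b: dict[str, tuple[str, int]] = {}
    for chrom, genes in red_b.items():
        for i, gid in enumerate(genes):
            pos_b[gid] = (chrom, i)

    breakpoints: list[SyntenyBreakpoint] = []
    for chrom in sorted(red_a):
        genes = red_a[chrom]
        for i in range(len(genes) - 1):
            g, h = genes[i], genes[i + 1]
            cb_g, ib_g = pos_b[mapping[g]]
            cb_h, ib_h = pos_b[mapping[h]]
            if cb_g == cb_h and abs(ib_g - ib_h) - 1 <= max_skip:
                continue
            partner = tuple(sorted({cb_g, cb_h}))
            bp = SyntenyBreakpoint(chrom, g, h, partner)
            if i == 0 or i + 1 == len(genes) - 1:
                bp.type = "telomeric"
            breakpoints.append(bp)

    _pair_events(breakpoints, red_a, red_b, mapping)
    return breakpoints


def _pair_events(breakpoints: list[SyntenyBreakpoint], red_a, red_b,
                 mapping: dict[str, str]) -> None:
    """Group breakpoints into events by matching exchanged arms in B."""
    inv = {v: k for k, v in mapping.items()}
    # novel adjacencies in B expressed in A gene ids
    adj_b: dict[str, set[str]] = {}
    for chrom, genes in red_b.items():
        for x, y in zip(genes, genes[1:]):
            gx, gy = inv[x], inv[y]
            adj_b.setdefault(gx, set()).add(gy)
            adj_b.setdefault(gy, set()).add(gx)

    n = len(breakpoints)
    partner_of: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            b1, b2 = breakpoints[i], breakpoints[j]
            arms1 = {b1.left_gene, b1.right_gene}
            arms2 = {b2.left_gene, b2.right_gene}
            crossed = sum(1 for g in arms1 for h in arms2 if h in adj_b.get(g, set()))
            if crossed >= 2:
                partner_of[i].add(j)
                partner_of[j].add(i)

    event = 0
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        group = {i}
        stack = [i]
        while stack:
            x = stack.pop()
            for y in partner_of[x]:
                if y not in group:
                    group.add(y)
                    stack.append(y)
        seen |= group
        event += 1
        kind = None
        if len(group) == 2:
            kind = "reciprocal"
        elif len(group) == 3:
            kind = "three_way"
        for idx in sorted(group):
            bp = breakpoints[idx]
            bp.event_id = event
            if kind and bp.type != "telomeric":
                bp.type = kind
            elif kind is None and bp.type != "telomeric":
                bp.type = "unclear"


def count_events(breakpoints: list[SyntenyBreakpoint]) -> int:
    return len({bp.event_id for bp in breakpoints if bp.event_id is not None})


def classify_ancestry(breakpoints: list[SyntenyBreakpoint], order_a: GeneOrder,
                      order_b: GeneOrder, mapping: dict[str, str],
                      outgroup_order: GeneOrder, mapping_to_outgroup: dict[str, str],
                      max_skip: int = 2) -> list[SyntenyBreakpoint]:
    """Label each breakpoint's ancestry using an outgroup gene order.

    The genome whose adjacency the outgroup shares is ancestral: if the
    outgroup preserves A's broken adjacency the B arrangement is derived
    (``A_ancestral``), and vice versa; both or neither give ``unclear``.
    """
    keep_og = set(mapping_to_outgroup.values())
    red_og = {chrom: [g for g, _s in genes if g in keep_og]
              for chrom, genes in outgroup_order.chromosomes.items()}
    pos_og: dict[str, tuple[str, int]] = {}
    for chrom, genes in red_og.items():
        for i, gid in enumerate(genes):
            pos_og[gid] = (chrom, i)

    inv_b = {v: k for k, v in mapping.items()}
    red_b = _reduced(order_b, set(mapping.values()))
    red_a = _reduced(order_a, set(mapping))
    adj_b: dict[str, set[str]] = {}
    for chrom, genes in red_b.items():
        for x, y in zip(genes, genes[1:]):
            adj_b.setdefault(inv_b[x], set()).add(inv_b[y])
            adj_b.setdefault(inv_b[y], set()).add(inv_b[x])
    adj_a: dict[str, set[str]] = {}
    for chrom, genes in red_a.items():
        for x, y in zip(genes, genes[1:]):
            adj_a.setdefault(x, set()).add(y)
            adj_a.setdefault(y, set()).add(x)

    def og_adjacent(g: str, h: str) -> Optional[bool]:
        og_g = mapping_to_outgroup.get(g)
        og_h = mapping_to_outgroup.get(h)
        if og_g is None or og_h is None or og_g not in pos_og or og_h not in pos_og:
            return None
        cg, ig = pos_og[og_g]
        ch, ih = pos_og[og_h]
        return cg == ch and abs(ig - ih) - 1 <= max_skip

    for bp in breakpoints:
        a_pres = og_adjacent(bp.left_gene, bp.right_gene)
        # B's *novel* adjacency at this breakpoint: a partner of left_gene in
        # B that is not also its neighbour in A
        b_partners = [h for h in adj_b.get(bp.left_gene, set())
                      if h != bp.right_gene and h not in adj_a.get(bp.left_gene, set())]
        b_pres = None
        for h in b_partners:
            r = og_adjacent(bp.left_gene, h)
            if r is not None:
                b_pres = r if b_pres is None else (b_pres or r)
        if a_pres is None and b_pres is None:
            bp.ancestry = "unclear"
        elif a_pres and not b_pres:
            bp.ancestry = "A_ancestral"
        elif b_pres and not a_pres:
            bp.ancestry = "B_ancestral"
        else:
            bp.ancestry = "unclear"
    return breakpoints


def find_tandem_arrays(annotations: list[GeneModel], families: dict[str, str],
                       max_intervening: int = 1, genome: Optional[AnnotatedGenome] = None,
                       genome_name: str = "") -> list[TandemArray]:
    """Maximal runs of >= 2 same-family genes on one chromosome with at most
    ``max_intervening`` other genes between consecutive members."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(annotations, key=lambda g: (g.chromosome, g.start)):
        by_chrom.setdefault(g.chromosome, []).append(g)

    arrays: list[TandemArray] = []
    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        claimed: set[int] = set()
        for i, g in enumerate(genes):
            fam = families.get(g.gene_id)
            if fam is None or i in claimed:
                continue
            members = [i]
            j = i
            while True:
                nxt = None
                for step in range(1, max_intervening + 2):
                    if j + step < len(genes) and families.get(genes[j + step].gene_id) == fam:
                        nxt = j + step
                        break
                if nxt is None:
                    break
                members.append(nxt)
                j = nxt
            if len(members) >= 2:
                claimed.update(members)
                member_genes = [genes[m] for m in members]
                identity = None
                if genome is not None:
                    identity = _min_pairwise_identity(member_genes, genome)
                arrays.append(TandemArray(genome_name, chrom, fam,
                                          [g.gene_id for g in member_genes], identity))
    return arrays


def _min_pairwise_identity(genes: list[GeneModel], genome: AnnotatedGenome) -> float:
    seqs = [genome.gene_sequence(g) for g in genes]
    best = 1.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a, b = seqs[i], seqs[j]
            n = min(len(a), len(b))
            if n == 0:
                continue
            ident = sum(1 for x, y in zip(a[:n], b[:n]) if x == y) / n
            best = min(best, ident)
    return best


def compare_arrays(arrays_a: list[TandemArray], arrays_b: list[TandemArray],
                   families_a: Optional[dict[str, str]] = None,
                   families_b: Optional[dict[str, str]] = None
                   ) -> list[tuple[str, int, int, bool]]:
    """Per-family copy-number comparison: (family, count_a, count_b, differs).

    Families with no array in a genome fall back to a singleton check against
    that genome's family census (1 if a lone copy exists, 0 if absent).
    """
    count_a = {arr.family_label: arr.copy_count for arr in arrays_a}
    count_b = {arr.family_label: arr.copy_count for arr in arrays_b}

    def singleton(fam: str, families: Optional[dict[str, str]]) -> int:
        if families is None:
            return 0
        return min(sum(1 for f in families.values() if f == fam), 1)

    out = []
    for fam in sorted(set(count_a) | set(count_b)):
        ca = count_a.get(fam, singleton(fam, families_a))
        cb = count_b.get(fam, singleton(fam, families_b))
        out.append((fam, ca, cb, ca != cb))
    return out
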