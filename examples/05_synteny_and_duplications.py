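"""Gene-order synteny between a species pair: translocations and tandem arrays.

Breakpoints are adjacencies in the rearranged genome whose orthologs lie on
different ancestral chromosomes; paired breakpoints whose arms exchange
partners form one reciprocal translocation.  Ancestry labels come from the
(untouched) ancestor as outgroup.
"""

from ashcomp.simulate import SimulationConfig, derive_species, generate_ancestor
from ashcomp.synteny import (GeneOrder, build_gene_orders, classify_ancestry,
                             compare_arrays, count_events, find_breakpoints,
                             find_tandem_arrays)

cfg = SimulationConfig(seed=5, n_chromosomes=3, chrom_length=30_000,
                       n_translocations=2,
                       tandem_events=[("famCWP1", 4, 4), ("famBENZ", 4, 0),
                                      ("famRAI1", 2, 1)])
ancestor = generate_ancestor(cfg)
species, truth = derive_species(ancestor, cfg)

rows = [(g.gene_id, g.gene_id, None) for g in species.genes
        if g.gene_id.startswith("g")]
order_sp, order_anc, mapping = build_gene_orders(species.genes, ancestor.genes, rows)
bps = find_breakpoints(order_sp, order_anc, mapping)
outgroup = GeneOrder("outgroup", {
    c: [(g.gene_id, g.strand) for g in sorted(
        (x for x in ancestor.genes if x.chromosome == c), key=lambda x: x.start)]
    for c in {g.chromosome for g in ancestor.genes}})
classify_ancestry(bps, order_sp, order_anc, mapping, outgroup,
                  {g.gene_id: g.gene_id for g in ancestor.genes})

print(f"{len(bps)} breakpoints grouping into {count_events(bps)} reciprocal "
      f"translocation event(s); planted: {cfg.n_translocations}")
for bp in bps:
    print(f"  {bp.chromosome}: {bp.left_gene} | {bp.right_gene} "
          f"(partner chromosomes {bp.partner_chromosomes_in_b}, {bp.type}, "
          f"ancestry {bp.ancestry})")

fams_a = {g.gene_id: g.ortholog_label for g in ancestor.genes
          if g.ortholog_label and g.ortholog_label.startswith("fam")}
fams_b = {g.gene_id: g.ortholog_label for g in species.genes
          if g.ortholog_label and g.ortholog_label.startswith("fam")}
arrays_a = find_tandem_arrays(ancestor.genes, fams_a)
arrays_b = find_tandem_arrays(species.genes, fams_b)
print("tandem copy numbers (family, strain lineage, species lineage, differs):")
for row in compare_arrays(arrays_a, arrays_b, fams_a, fams_b):
    print(" ", row)
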