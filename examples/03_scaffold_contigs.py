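"""Scaffold strain-B contigs against the strain-A reference with mate pairs.

Contigs are placed by unique 31-mer anchor chains; 58-base mate pairs with
~1.6 kb inserts link contig ends and size the gaps.
"""

from ashcomp.assembler import AssemblerConfig, assemble, phred_to_class
from ashcomp.io_formats import SeqRecord
from ashcomp.scaffolder import (ScaffoldConfig, anchor_contigs, build_scaffolds,
                                link_mate_pairs, scaffold_sequence)
from ashcomp.simulate import (SimulationConfig, derive_strain, generate_ancestor,
                              simulate_reads)

cfg = SimulationConfig(seed=21, n_chromosomes=1, chrom_length=30_000, depth=25,
                       mate_depth=10, tandem_events=[("famCWP1", 4, 4)],
                       seq_error_rate_by_quality_class=(0.0, 0.0, 0.0, 0.0))
ancestor = generate_ancestor(cfg)
strain_a, _ = derive_strain(ancestor, cfg, "A")
strain_b, _ = derive_strain(ancestor, cfg, "B")
singles, mates1, mates2 = simulate_reads(strain_b, cfg)

asm = assemble([(r.sequence, phred_to_class(q)) for r, q in singles],
               AssemblerConfig(read_length=36))
contigs = [SeqRecord(c.id, c.sequence) for c in asm.contigs if len(c) >= 31]

scfg = ScaffoldConfig(insert_mean=cfg.insert_mean, insert_sd=cfg.insert_sd)
placements = anchor_contigs(contigs, strain_a.records, scfg)
links = link_mate_pairs(mates1, mates2, contigs, scfg)
scaffolds = build_scaffolds(placements, links, strain_a.records, contigs, scfg)

print(f"{len(contigs)} contigs, {len(links)} mate-pair links "
      f"-> {len(scaffolds)} scaffold(s)")
for sc in scaffolds:
    seq = scaffold_sequence(sc, contigs)
    gaps = [g for _c, _o, g in sc.items[:-1]]
    print(f"{sc.id}: {len(sc.items)} contigs, {len(seq.sequence)} bases, "
          f"gap estimates {gaps} (N-runs between ordered contigs)")
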