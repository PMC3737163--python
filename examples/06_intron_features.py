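"""Intron statistics, splice-site consensus matrices, and 3' ORF overlaps."""

from ashcomp.features import (collect_introns, find_convergent_overlaps,
                              intron_stats, splice_consensus)
from ashcomp.simulate import SimulationConfig, generate_ancestor

cfg = SimulationConfig(seed=11, n_chromosomes=2, chrom_length=100_000,
                       gene_density=6.0, intron_rate=0.3, tandem_events=[])
genome = generate_ancestor(cfg)

introns = collect_introns(genome.genes, genome)
stats = intron_stats(introns)
print(f"{len(introns)} introns; per-class counts {stats['count_by_class']}; "
      f"mean CDS intron length {stats['mean_length']:.0f} bases")

cons = splice_consensus(introns, genome)
print("splice consensus (from position-frequency matrices, each column "
      "normalised to 1):")
print(f"  donor (-3..+6):    {cons.consensus_string('donor')} "
      f"(intron starts at column 4: GTATGT)")
print(f"  branch point:      {cons.consensus_string('branch')}")
print(f"  acceptor (-6..+3): {cons.consensus_string('acceptor')} "
      f"(intron ends ...AG before column 7)")

overlaps = find_convergent_overlaps(genome.genes)
conv = [p for p in overlaps if p.overlap_class == "3prime_convergent"]
print(f"{len(conv)} convergently transcribed gene pairs overlap at their 3' ends"
      + (f"; longest {max(p.overlap_length for p in conv)} bases" if conv else ""))
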