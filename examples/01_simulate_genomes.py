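"""Simulate a strain pair and a sibling species with full planted truth.

Builds a 2 x 30 kb ancestral genome, derives the reference strain, a second
strain at ~99.9% pairwise identity carrying one ~92%-identity introgressed
block, and a sibling species at ~90% identity with one reciprocal
translocation and tandem copy-number changes.
"""

from ashcomp.simulate import (SimulationConfig, derive_species, derive_strain,
                              generate_ancestor)

cfg = SimulationConfig(seed=1, n_chromosomes=2, chrom_length=30_000,
                       n_translocations=1,
                       tandem_events=[("famCWP1", 4, 4), ("famRAI1", 2, 1)])
ancestor = generate_ancestor(cfg)
strain_a, _ = derive_strain(ancestor, cfg, "A")
strain_b, truth = derive_strain(ancestor, cfg, "B")
species, truth_sp = derive_species(ancestor, cfg)

print(f"ancestor: {len(ancestor.records)} chromosomes, {len(ancestor.genes)} genes")
n_snp = sum(1 for v in truth.variants if v[4] == "SNP")
n_indel = len(truth.variants) - n_snp
print(f"strain pair: {n_snp} planted SNPs, {n_indel} indel events "
      f"(the truth the comparator must recover)")
chrom, s, e = truth.introgression
print(f"introgressed block: {chrom}:{s}-{e} "
      f"({e - s + 1} bases replaced by a diverged donor haplotype)")
print(f"species: {len(truth_sp.breakpoints)} translocation breakpoints planted, "
      f"tandem arrays {truth_sp.tandem_arrays}")
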