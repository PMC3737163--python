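key	value
telomere_unit	TGAGAGACCCATACACCACACCGC
introgression_start	179139
introgression_end	184589
introgression_total_snps	439
introgression_inter_orf_snps	139
introgression_synonymous_snps	186
introgression_nonsynonymous_snps	97
protein_coding_genes	4776
syntenic_homolog_genes	4300
nohby_genes	270
nohby_with_syntenic_homolog	146
single_intron_genes	263
two_intron_genes	7
utr5_introns	15
trna_intron_genes	49
mean_intron_length	107
strain_pair_snps	15337
strain_pair_single_base_indels	424
strain_pair_multi_base_indels	952
transition_percent	63
reciprocal_translocations	8
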