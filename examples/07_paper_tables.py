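"""Audit the transcribed re-annotation and tandem-duplication tables."""

from ashcomp import fixtures as fx

table2 = fx.load_table("table2")
print(f"re-annotation removals: {fx.count_features(table2, 'CDS')} protein-coding "
      f"genes, {fx.count_features(table2, 'tRNA')} tRNAs, "
      f"{fx.count_features(table2, 'snRNA')} noncoding RNA")

table5 = fx.load_table("table5")
g = fx.count_tandem_sets(table5, "A_gossypii", 2)
a = fx.count_tandem_sets(table5, "A_aceri", 2)
print(f"tandem duplication sets: {g} in the A. gossypii strains, "
      f"{a} of them also tandem in A. aceri")

consts = fx.load_constants()
span = fx.interval_length(int(consts["introgression_start"]),
                          int(consts["introgression_end"]))
print(f"introgression interval on chromosome IV: {span} bases "
      f"({consts['introgression_start']}..{consts['introgression_end']})")
print(f"telomeric terminal repeat {consts['telomere_unit']} "
      f"({fx.sequence_length(consts['telomere_unit'])} bp)")
print(f"{fx.rounded_percentage(4300, 4776)}% of protein-coding genes have "
      f"syntenic homologs in budding yeast; "
      f"{fx.rounded_percentage(146, 270)}% of NOHBY genes have a syntenic "
      f"homolog in at least one other fungus")
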