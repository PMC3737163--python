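# Tandem duplications of protein-coding genes, with copy numbers in the two
# genomes (A. gossypii strains vs A. aceri); 21 sets.
set_gene	members	identity	sc_homolog1	sc_homolog2	copies_gossypii	copies_aceri
AAL179W	AAL179W,AAL178W	47%	YJL079C(PRY1)	YKR013W(PRY2)	2	2
ABL189W	ABL189W,ABL188W	38%	YDL237W		2	2
ABR025C	ABR025C,ABR026C,ABR027C,ABR028C	26-46%	YKL096W(CWP1)		4	4
ACR272C	ACR272C,ACR273W	58%	YKL096W(CWP1)		2	2
AFL095W	AFL095W,AFL092C	56%	YHR211W(FLO5)		2	2
ABR182W	ABR182W,ABR183W	73%	YPR165W(RHO1)		2	2
ABR246W	ABR246W,ABR247W,ABR248W,ABR249W	65-84%	YIR035C	YIR036C	4	0
ACL202W	ACL202W,ACL201W,ACL200W	81-94%	YMR238W(DFG5)		3	1
ACR098C	ACR098C,ACR099C	45%	YPL129W(TAF14)	YOR213C(SAS5)	2	2
ACR143W	ACR143W,ACR144W	36%	YPL154C(PEP4)		2	2
ADL156C	ADL156C,ADL155C	66%	YOL119C(MCH4)		2	2
ADR081C	ADR081C,ADR082C	82%	YLR215C(CDC123)		2	1
ADR336C	ADR336C,ADR337C	60%	YNR055C(HOL1)		2	2
ADR403C	ADR403C,ADR404C,ADR405C	25-27%	YAL051W(OAF1)	YOR363C(PIP2)	3	3
AER452C	AER452C,AER453C,AER454C	74-80%	YJR107W		3	3
AFR262C	AFR262C,AFR263C	87%	YGL246C(RAI1)		2	1
AGL352W	AGL352W,AGL351W	59%	YMR307W(GAS1)		2	2
AGL326W	AGL326W,AGL325W	29%	YJL172W(CPS1)		2	2
AGR038C	AGR038C,AGR039C	72%	YDR046C(BAP3)	YBR068C(BAP2)	2	2
AGR188W	AGR188W,AGR189W	<30%	YDR227W(SIR4)		2	2
AGR405C	AGR405C,AGR406C	83%	YCL057W(PRD1)		2	2
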