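# Genes removed from the reference-strain re-annotation
# (15 protein-coding genes, 3 tRNA genes, 1 noncoding RNA gene).
location	feature	position	strand	orf_name	sc1_homolog	sc2_homolog	sc1_common	sc2_common
Chr2	snRNA	286517..286773	+	AgSNR81	SNR81
Chr3	CDS	564351..564956	+	ACR121W	NOHBY323
Chr3	CDS	711557..712282	-	ACR208C	NOHBY331
Chr4	CDS	114447..114788	-	ADL337C-A	YBR108WX
Chr4	CDS	430731..431204	+	ADL148W	NOHBY411
Chr4	tRNA	683817..683888	-	tRNA-Sec	tRNA-Sec
Chr4	CDS	712052..712354	-	ADR004C	NOHBY422
Chr4	CDS	937410..938060	+	ADR129W	NOHBY428
Chr4	CDS	1380467..1380700	+	ADR376W	NOHBY446
Chr5	tRNA	102468..102503,102525..102562	-	tRNA-Gln	tRNA-Gln
Chr5	tRNA	103053..103090,103112..103147	+	tRNA-Gln	tRNA-Gln
Chr5	CDS	564134..565534	-	AEL037C	NOHBY503
Chr6	CDS	411639..412373	+	AFL013W	NOHBY602
Chr6	CDS	1120279..1121118	+	AFR379W	NOHBY639
Chr6	CDS	1799446..1800129	-	AFR742C	NOHBY668
Chr7	CDS	616255..616749	+	AGL048W	NOHBY705
Chr7	CDS	913067..913483	+	AGR094W	NOHBY739
Chr7	CDS	944867..945574	+	AGR109W	NOHBY740
Chr7	CDS	1308521..1309006	-	AGR307C	NOHBY745
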