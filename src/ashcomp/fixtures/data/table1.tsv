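# Genes added to the reference-strain re-annotation.
# The source table prints the ADL397C-A and ADL397C-B rows twice; the
# duplicated rows are transcribed once here (49 distinct features).
location	feature	position	strand	orf_name	sc1_homolog	sc2_homolog	sc1_common	sc2_common
Chr1	CDS	189767..189973	+	AAL088W-A	NOHBY121
Chr2	CDS	2047..2991	+	ABL211W	NOHBY219
Chr2	ncRNA	286717..286792	-	AgSNR86	SNR86
Chr2	ncRNA	404973..405057	+	AgSNR87	SNR87
Chr2	5UTR_intron	458552..458694	-	5UTR_intron
Chr2	CDS	862752..863330	+	ABR250W	NOHBY220
Chr2	CDS	867475..867642	-	ABR251C	NOHBY221
Chr3	CDS	222051..222212	+	ACL074W-A	NOHBY335
Chr3	CDS	471357..471584	+	ACR063W-A	YIL102C-A
Chr4	CDS	10088..10672	-	ADL397C-B	NOHBY454
Chr4	CDS	11914..12576	-	ADL397C-A	NOHBY453
Chr4	CDS	83599..84255,84309..84314	-	ADL356C-A	NOHBY452
Chr4	5UTR_intron	153033..153181	+	5UTR_intron
Chr4	CDS	240411..241580	+	ADL265W-A	YOR099W		KTR1
Chr4	CDS	430981..431586	-	ADL148C	NOHBY450
Chr4	CDS	434768..435013	+	ADL147W-A	YGR236C		SPG1
Chr4	5UTR_intron	472058..472560	-	5UTR_intron
Chr4	CDS	593768..594280	-	ADL052C-A	NOHBY451
Chr4	CDS	712125..712700	+	ADR004W	NOHBY422
Chr4	5UTR_intron	877761..878116	+	5UTR_intron
Chr4	CDS	921189..921761	+	ADR121W-A	NOHBY455
Chr5	ncRNA	22986..23002	-	AgSNR50	SNR50
Chr5	CDS	98045..98974	+	AEL289W-A	YKR005C
Chr5	5UTR_intron	318815..318910	+	5UTR_intron
Chr5	CDS	471962..472540	-	AEL083C-A	NOHBY534
Chr5	CDS	563288..565171	+	AEL037W	NOHBY503
Chr5	5UTR_intron	733654..733809	+	5UTR_intron
Chr5	5UTR_intron	800547..800684	-	5UTR_intron
Chr5	CDS	939696..941048	-	AER160C-A	NOHBY536
Chr5	CDS	1017648..1018565	+	AER204W-A	NOHBY535
Chr5	5UTR_intron	1105232..1105307	+	5UTR_intron
Chr5	CDS	1132015..1133691	-	AER270C-A	NOHBY533
Chr5	5UTR_intron	1325900..1326076	-	5UTR_intron
Chr6	CDS	412760..413410	-	AFL013C	NOHBY671
Chr6	5UTR_intron	790825..790986	+	5UTR_intron
Chr6	5UTR_intron	791737..791787	+	5UTR_intron
Chr6	tRNA	1251500..1251538,1251548..1251583	+	tRNA-Tyr	tRNA-Tyr
Chr6	CDS	1251695..1252657	+	AFR451W-A	YDL209C		CWC2
Chr6	5UTR_intron	1300412..1300621	-	5UTR_intron
Chr6	CDS	1802735..1803337	+	AFR742W	NOHBY668
Chr7	5UTR_intron	181129..181250	-	5UTR_intron
Chr7	CDS	573775..574320	+	AGL073W-C	YMR073C		IRC21
Chr7	CDS	574575..575699	-	AGL073C-A	YKL032C	YMR072W	IXR1	ABF2
Chr7	CDS	575980..577428	-	AGL073C-B	NOHBY747
Chr7	CDS	619742..619921,619973..620005	-	AGL048C	YPR010C-A
Chr7	CDS	673624..674040	+	AGL024W-A	NOHBY748
Chr7	5UTR_intron	945704..945829	-	5UTR_intron
Chr7	CDS	1291412..1292176	-	AGR294C-A	NOHBY749
Chr7	5UTR_intron	1426879..1427068	+	5UTR_intron
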