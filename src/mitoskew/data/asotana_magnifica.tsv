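gene	from	to	size	IGR	start	stop	anticodon	strand
trnL1	1	58	58				TAG	-
trnL2	100	160	61	41			TAA	-
trnS1	152	216	65	-9			TCT	-
trnW	218	269	52	1			TCA	-
cytb	274	1399	1126	4	ATT	T		-
trnT	1400	1456	57				TGT	-
nad5	1456	3147	1692	-1	ATA	TAA		+
trnF	3140	3197	58	-8			GAA	+
trnH	3190	3247	58	-8			GTG	-
nad4	3247	4557	1311	-1	CTA	CAT		+
nad4L	4551	4850	300	-7	TTA	AAT		+
trnP	4851	4908	58				TGG	-
nad6	4910	5395	486	1	ATA	TAA		+
trnS2	5394	5454	61	-2			TGA	+
rrnL	5455	6533	1079					-
trnQ	6534	6588	55				TTG	-
trnM	6580	6644	65	-9			CAT	+
nad2	6645	7628	984		ATT	TAA		+
trnY	7663	7723	61	34			GTA	-
cox1	7724	9259	1536		ATG	TAA		+
cox2	9329	10006	678	69	ATC	TAA		+
trnK	10005	10065	61	-2			TTT	+
trnD	10073	10115	43	7			GTC	+
atp8	10125	10277	153	9	ATA	TAA		+
atp6	10271	10937	667	-7	ATG	T		+
cox3	10938	11723	786		ATG	TAA		+
trnR	11722	11777	56	-2			TCG	+
trnG	11781	11829	49	3			TCC	+
nad3	11829	12179	351	-1	ATA	TAA		+
trnA	12183	12220	38	3			TGC	+
trnV	12218	12274	57	-3			TAC	+
nad1	12274	13194	948	-1	ATT	TAA		-
trnN	13196	13256	61	1			GTT	+
rrnS	13257	13959	703				+
CR	13960	14435	475
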