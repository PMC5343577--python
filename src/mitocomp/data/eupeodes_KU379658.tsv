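#id=KU379658
#length=15326
#circular=false
gene	start	end	strand	category	anticodon	start_codon	stop_codon	length	intergenic
trnI	1	66	+	tRNA	GAT			66	-3
trnQ	64	133	-	tRNA	TTG			70	7
trnM	141	209	+	tRNA	CAT			69	0
nad2	210	1238	+	PCG		ATT	TAA	1029	-2
trnW	1237	1304	+	tRNA	TCA			68	4
trnC	1309	1374	-	tRNA	GCA			66	10
trnY	1385	1450	-	tRNA	GTA			66	22
cox1	1473	3029	+	PCG		ATT	TAA	1557	-5
trnL2	3025	3090	+	tRNA	TAA			66	2
cox2	3093	3776	+	PCG		ATG	TAA	684	0
trnK	3777	3847	+	tRNA	CTT			71	47
trnD	3895	3961	+	tRNA	GTC			67	0
atp8	3962	4123	+	PCG		ATT	TAA	162	-7
atp6	4117	4794	+	PCG		ATG	TAA	678	16
cox3	4811	5599	+	PCG		ATG	TAA	789	3
trnG	5603	5669	+	tRNA	TCC			67	0
nad3	5670	6023	+	PCG		ATT	TAA	354	3
trnA	6027	6095	+	tRNA	TGC			69	-1
trnR	6095	6158	+	tRNA	TCG			64	13
trnN	6172	6238	+	tRNA	GTT			67	-1
trnS1	6238	6304	+	tRNA	GCT			67	5
trnE	6310	6376	+	tRNA	TTC			67	26
trnF	6403	6469	-	tRNA	GAA			67	-1
nad5	6469	8189	-	PCG		ATT	TA	1721	15
trnH	8205	8270	-	tRNA	GTG			66	-1
nad4	8270	9610	-	PCG		ATG	TAA	1341	-7
nad4l	9604	9900	-	PCG		ATG	TAA	297	2
trnT	9903	9967	+	tRNA	TGT			65	0
trnP	9968	10033	-	tRNA	TGG			66	2
nad6	10036	10560	+	PCG		ATT	TAA	525	3
cob	10564	11700	+	PCG		ATG	TAA	1137	7
trnS2	11708	11775	+	tRNA	TGA			68	17
nad1	11792	12730	-	PCG		ATA	TAG	939	10
trnL1	12741	12805	-	tRNA	TAG			65	0
rrnL	12806	14139	-	rRNA				1334	0
trnV	14140	14211	-	tRNA	TAC			72	0
rrnS	14212	15006	-	rRNA				795	0
CONTROL	15007	15326	-	control
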