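#id=KU351241
#length=16175
#circular=true
gene	start	end	strand	category	anticodon	start_codon	stop_codon	length	intergenic
trnI	1	66	+	tRNA	GAT			66	2
trnQ	69	137	-	tRNA	TTG			69	14
trnM	152	220	+	tRNA	CAT			69	0
nad2	221	1252	+	PCG		ATT	TAA	1032	3
trnW	1256	1323	+	tRNA	TCA			68	8
trnC	1332	1398	-	tRNA	GCA			67	14
trnY	1413	1478	-	tRNA	GTA			66	5
cox1	1484	3043	+	PCG		ATT	TAA	1560	-5
trnL2	3039	3104	+	tRNA	TAA			66	2
cox2	3107	3790	+	PCG		ATG	TAA	684	5
trnK	3796	3866	+	tRNA	CTT			71	60
trnD	3927	3993	+	tRNA	GTC			67	0
atp8	3994	4155	+	PCG		ATT	TAA	162	-7
atp6	4149	4826	+	PCG		ATG	TAA	678	35
cox3	4862	5650	+	PCG		ATG	TAA	789	3
trnG	5654	5719	+	tRNA	TCC			66	0
nad3	5720	6073	+	PCG		ATT	TAA	354	4
trnA	6078	6146	+	tRNA	TGC			69	-1
trnR	6146	6209	+	tRNA	TCG			64	2
trnN	6212	6278	+	tRNA	GTT			67	-1
trnS1	6278	6344	+	tRNA	GCT			67	1
trnE	6346	6410	+	tRNA	TTC			65	23
trnF	6434	6500	-	tRNA	GAA			67	-1
nad5	6500	8221	-	PCG		ATT	TAA	1722	15
trnH	8237	8303	-	tRNA	GTG			67	-1
nad4	8303	9643	-	PCG		ATG	TAA	1341	-7
nad4l	9637	9933	-	PCG		ATG	TAA	297	2
trnT	9936	10000	+	tRNA	TGT			65	0
trnP	10001	10066	-	tRNA	TGG			66	2
nad6	10069	10593	+	PCG		ATT	TAA	525	3
cob	10597	11733	+	PCG		ATG	TAA	1137	1
trnS2	11735	11802	+	tRNA	TGA			68	16
nad1	11819	12757	-	PCG		ATA	TAA	939	10
trnL1	12768	12832	-	tRNA	TAG			65	0
rrnL	12833	14170	-	rRNA				1338	0
trnV	14171	14242	-	tRNA	TAC			72	0
rrnS	14243	15046	-	rRNA				804	0
CONTROL	15047	16175	-	control				1129	0
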