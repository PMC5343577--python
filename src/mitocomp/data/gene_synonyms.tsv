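# GenBank qualifier spellings mapped onto the canonical 37-token vocabulary.
# Matching is case-insensitive after stripping spaces; extend as needed.
# alias	canonical
nd1	nad1
nd2	nad2
nd3	nad3
nd4	nad4
nd4l	nad4l
nd5	nad5
nd6	nad6
nadh1	nad1
nadh2	nad2
nadh3	nad3
nadh4	nad4
nadh4l	nad4l
nadh5	nad5
nadh6	nad6
nadh dehydrogenase subunit 1	nad1
nadh dehydrogenase subunit 2	nad2
nadh dehydrogenase subunit 3	nad3
nadh dehydrogenase subunit 4	nad4
nadh dehydrogenase subunit 4l	nad4l
nadh dehydrogenase subunit 5	nad5
nadh dehydrogenase subunit 6	nad6
coi	cox1
coii	cox2
coiii	cox3
co1	cox1
co2	cox2
co3	cox3
cox-1	cox1
cox-2	cox2
cox-3	cox3
cytochrome c oxidase subunit 1	cox1
cytochrome c oxidase subunit 2	cox2
cytochrome c oxidase subunit 3	cox3
cytochrome c oxidase subunit i	cox1
cytochrome c oxidase subunit ii	cox2
cytochrome c oxidase subunit iii	cox3
cytochrome oxidase subunit 1	cox1
cytochrome oxidase subunit 2	cox2
cytochrome oxidase subunit 3	cox3
cytb	cob
cyt b	cob
cob	cob
cytochrome b	cob
atpase6	atp6
atpase8	atp8
atpase 6	atp6
atpase 8	atp8
atp synthase f0 subunit 6	atp6
atp synthase f0 subunit 8	atp8
16s	rrnL
l-rrna	rrnL
lrrna	rrnL
rrnl	rrnL
16s ribosomal rna	rrnL
large subunit ribosomal rna	rrnL
12s	rrnS
s-rrna	rrnS
srrna	rrnS
rrns	rrnS
12s ribosomal rna	rrnS
small subunit ribosomal rna	rrnS
trna-ile	trnI
trna-gln	trnQ
trna-met	trnM
trna-trp	trnW
trna-cys	trnC
trna-tyr	trnY
trna-leu(uur)	trnL2
trna-leu(taa)	trnL2
trna-leu(cun)	trnL1
trna-leu(tag)	trnL1
trna-lys	trnK
trna-asp	trnD
trna-gly	trnG
trna-ala	trnA
trna-arg	trnR
trna-asn	trnN
trna-ser(agn)	trnS1
trna-ser(gct)	trnS1
trna-ser(ucn)	trnS2
trna-ser(tga)	trnS2
trna-glu	trnE
trna-phe	trnF
trna-his	trnH
trna-thr	trnT
trna-pro	trnP
trna-val	trnV
a+t-rich region	CONTROL
at-rich region	CONTROL
control region	CONTROL
d-loop	CONTROL
misc_feature	CONTROL
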