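# alias	canonical
# Aliases are matched case-insensitively after stripping spaces and
# mapping '_' to '-'. Edit freely: GenBank naming is inconsistent.
cox1	cox1
coxi	cox1
co1	cox1
coi	cox1
cox-1	cox1
cytochromecoxidasesubuniti	cox1
cytochromecoxidasesubunit1	cox1
cytochromeoxidasesubunit1	cox1
cytochromeoxidasesubuniti	cox1
cox2	cox2
coxii	cox2
co2	cox2
coii	cox2
cytochromecoxidasesubunitii	cox2
cytochromecoxidasesubunit2	cox2
cytochromeoxidasesubunit2	cox2
cox3	cox3
coxiii	cox3
co3	cox3
coiii	cox3
cytochromecoxidasesubunitiii	cox3
cytochromecoxidasesubunit3	cox3
cytochromeoxidasesubunit3	cox3
cob	cob
cytb	cob
cyb	cob
cytochromeb	cob
cytochrome-b	cob
atp6	atp6
atpase6	atp6
atpsynthasef0subunit6	atp6
atpsynthasesubunit6	atp6
atp8	atp8
atpase8	atp8
atpsynthasef0subunit8	atp8
atpsynthasesubunit8	atp8
nad1	nad1
nd1	nad1
nadhdehydrogenasesubunit1	nad1
nad2	nad2
nd2	nad2
nadhdehydrogenasesubunit2	nad2
nad3	nad3
nd3	nad3
nadhdehydrogenasesubunit3	nad3
nad4	nad4
nd4	nad4
nadhdehydrogenasesubunit4	nad4
nad4l	nad4L
nd4l	nad4L
nadhdehydrogenasesubunit4l	nad4L
nad5	nad5
nd5	nad5
nadhdehydrogenasesubunit5	nad5
nad6	nad6
nd6	nad6
nadhdehydrogenasesubunit6	nad6
rrns	rrnS
rrn-s	rrnS
12s	rrnS
12srrna	rrnS
12sribosomalrna	rrnS
s-rrna	rrnS
srrna	rrnS
smallsubunitribosomalrna	rrnS
rrnl	rrnL
rrn-l	rrnL
16s	rrnL
16srrna	rrnL
16sribosomalrna	rrnL
l-rrna	rrnL
lrrna	rrnL
largesubunitribosomalrna	rrnL
d-loop	d_loop
dloop	d_loop
controlregion	d_loop
at-richregion	d_loop
a+t-richregion	d_loop
putativecontrolregion	d_loop
trna	trnA
trna-ala	trnA
trnc	trnC
trna-cys	trnC
trnd	trnD
trna-asp	trnD
trne	trnE
trna-glu	trnE
trnf	trnF
trna-phe	trnF
trng	trnG
trna-gly	trnG
trnh	trnH
trna-his	trnH
trni	trnI
trna-ile	trnI
trnk	trnK
trna-lys	trnK
trnl	trnL
trna-leu	trnL
trnl1	trnL1
trnl2	trnL2
trna-leu1	trnL1
trna-leu2	trnL2
trna-leu(cun)	trnL1
trna-leu(uur)	trnL2
trna-leu(taa)	trnL2
trna-leu(tag)	trnL1
trnm	trnM
trna-met	trnM
trnn	trnN
trna-asn	trnN
trnp	trnP
trna-pro	trnP
trnq	trnQ
trna-gln	trnQ
trnr	trnR
trna-arg	trnR
trns	trnS
trna-ser	trnS
trns1	trnS1
trns2	trnS2
trna-ser1	trnS1
trna-ser2	trnS2
trna-ser(agn)	trnS1
trna-ser(ucn)	trnS2
trna-ser(gct)	trnS1
trna-ser(tga)	trnS2
trnt	trnT
trna-thr	trnT
trnv	trnV
trna-val	trnV
trnw	trnW
trna-trp	trnW
trny	trnY
trna-tyr	trnY
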