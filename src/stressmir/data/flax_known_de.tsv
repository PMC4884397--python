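mirna	log2fc_AS	log2fc_AS2	log2fc_NSS
lus-miR159c	.	.	-1.0931792
lus-miR160a/e/f	.	1.20840613	-3.66411747
lus-miR160b/d	.	1.20719184	-3.66660396
lus-miR160j	.	1.20846291	.
lus-miR160h/i	.	1.20203167	-3.69976116
lus-miR169c	.	-1.13471672	.
lus-miR169e/i	.	-1.05752449	.
lus-miR171j	.	.	-1.02479034
lus-miR319a	.	.	-1.46989392
lus-miR393a/c	.	1.12123117	.
lus-miR393b/d	.	1.00414957	.
lus-miR394a	.	2.65759041	-3.63085489
lus-miR394b	.	2.77702791	-3.82176614
lus-miR398a	2.51091239	2.69813582	.
lus-miR408a	1.71297796	1.63630636	.
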