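mirna	srna_AS	srna_AS2	srna_NSS	target	annotation	position	alignment_score	category	dge_AS	dge_AS2	dge_NSS
lus-miR156g/a	Down	Down	Down	Lus10000257	Tetratricopeptide repeat (TPR)-like superfamily protein	761	4.5	4	Up	Up	Up
lus-miR159b	Down	Down	Down	Lus10010495	Cystatin/monellin superfamily protein	335	4.5	3	Up	Up	Up
lus-miR160a/b/d/e/f/h/i/j	Up	Up	Down	Lus10041268	Transducin/WD40 repeat-like superfamily protein	1014	4	2	Down	Down	Up
lus-miR162a/b	Down	Down	Down	Lus10015483	Heat shock protein 70 (Hsp 70) family protein	1243	4.5	2	Up	Up	Up
lus-miR164a/b/c/d/e	Down	Up	Down	Lus10006635	ARM repeat superfamily protein	153	4	4	Up	Down	Up
lus-miR166a/c/d/g/h/j	Down	Down	Down	Lus10020493	Pathogenesis-related gene 1	220	4	2	Up	Up	Up
lus-miR167a	Down	Down	Down	Lus10014324	G-box binding factor 1	679	3.5	2	Up	Up	Up
lus-miR168a/b	Down	Down	Down	Lus10000074	Methionine gamma-lyase	469	4.5	4	Up	Up	Up
lus-miR169a/d	Up	Down	Down	Lus10014674	Transducin/WD40 repeat-like superfamily protein	638	4	4	Down	Up	Up
lus-miR169e/i	Down	Down	Down	Lus10006846	Profilin 5	96	4.5	4	Up	Up	Up
lus-miR169g/l	Up	Down	Up	Lus10030904	Alpha/beta-Hydrolases superfamily protein	755	4.5	4	Down	Up	Down
lus-miR171b/c/e	Down	Down	Down	Lus10009876	UDP-glucosyl transferase 85A3	952	4	4	Up	Up	Up
lus-miR171d	Up	Down	Down	Lus10017991	Jasmonate-zim-domain protein 3	594	4.5	2	Down	Up	Up
lus-miR172a/b/c/d/f/h	Down	Down	Down	Lus10001322	Deoxyxylulose-5-phosphate synthase	1796	4	4	Up	Up	Up
lus-miR319b	Down	Down	Down	Lus10009442	O-methyltransferase family protein	502	4	4	Up	Up	Up
lus-miR390a/b/c/d	Down	Down	Down	Lus10015906	Purine permease 3	857	4.5	4	Up	Up	Up
lus-miR393a/b/c/d	Up	Up	Down	Lus10040438	F-box family protein	1620	3.5	4	Down	Down	Up
lus-miR394a/b	Up	Up	Down	Lus10018337	Pyruvate dehydrogenase kinase	536	4.5	2	Down	Down	Up
lus-miR395a/b/c/d	Down	Down	Down	Lus10006629	ATP sulfurylase 1	339	2.5	0	Up	Up	Up
lus-miR396a/c	Down	Down	Down	Lus10001321	Xylose isomerase family protein	648	3.5	2	Up	Up	Up
lus-miR397a	Up	Up	Down	Lus10004434	REF4-related 1	1875	4.5	4	Down	Down	Up
lus-miR397b	Down	Up	Up	Lus10001002	3-deoxy-d-arabino-heptulosonate 7-phosphate synthase	581	4.5	4	Up	Down	Down
lus-miR398a	Up	Up	Up	Lus10016155	Copper/zinc superoxide dismutase 2	449	4	0	Down	Down	Down
lus-miR398b/c/d/e	Down	Down	Down	Lus10003315	Myosin family protein with Dil domain	4406	4.5	2	Up	Up	Up
lus-miR399b/d	Down	Up	Down	Lus10019360	Trigalactosyldiacylglycerol	2323	4.5	4	Up	Down	Up
lus-miR399f/g	Up	Up	Up	Lus10003060	Cofactor-independent phosphoglycerate mutase	1097	4	4	Down	Down	Down
lus-miR408a	Up	Up	Up	Lus10003138	Cyclophilin 20-2	860	4.5	2	Down	Down	Down
lus-miR530a/b	Up	Up	Down	Lus10001902	WRKY family transcription factor	490	4.5	2	Down	Down	Up
lus-miR828a	Down	Up	Up	Lus10013640	Ribosomal protein L3 family protein	570	4.5	4	Up	Down	Down
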