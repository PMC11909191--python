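orf_id	transcript_id	gene_id	gene_name	chrom	strand	t_start	t_stop	g_start	g_stop	g_min	g_max	length_nt	start_codon	category	peptide
o1	tx1	g1	GENEA	chr1	+	1	24	100	123	100	123	24	ATG	novel_nc	LKNDAER
o2	tx2	g2	GENEB	chr1	+	1	24	200	223	200	223	24	CTG	uORF	MGGTAVK
o3	tx3	g3	GENEC	chr1	+	1	24	300	323	300	323	24	ATG	novel_nc	VSSPLLK
o4	tx4	g4	GENED	chr1	+	1	24	400	423	400	423	24	GTG	dORF	TTYHNLR
o5	tx5	g5	GENEE	chr1	+	1	24	500	523	500	523	24	ATG	altORF	AQQIWGK
o6	tx6	g6	GENEF	chr1	+	1	24	600	623	600	623	24	TTG	novel_nc	NNDEFSR
o9	tx9	g9	GENEG	chr1	+	1	24	700	723	700	723	24	ATG	annotated	GGHHLLK
o10	tx10	g10	GENEH	chr1	+	1	24	800	823	800	823	24	ATG	intORF	CCDDEEK
oL	txL	gL	GENEL	chr1	+	1	69	1000	1068	1000	1068	69	ATG	novel_nc	AAAAKWRGGGGMWWWWKRCCCC
oS	txS	gS	GENES	chr1	+	1	36	1030	1065	1030	1065	36	ATG	novel_nc	MWWWWKRCCCC
o11	tx11	g11	GENEI	chr1	+	1	24	2000	2023	2000	2023	24	ATG	novel_nc	QQRRSSK
o12	tx12	g12	GENEJ	chr1	+	1	24	2100	2123	2100	2123	24	ATG	novel_nc	TTVVWWK
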