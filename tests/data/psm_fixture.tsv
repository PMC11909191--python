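spectrum_id	sample_id	peptide	orf_ids	score	is_decoy
specA	s1	ACDEFGK	o1	20.0	false
specA	s1	ACDEGGK	o3	19.0	false
specB	s2	HHHHKKR	o4	18.0	false
specB	s2	HHHHKKW	o5	17.5	false
S001	s1	LKNDAER	o1	30.0	false
S002	s1	LKNDAER	o1	26.0	false
S003	s2	LKNDAER	o1	25.0	false
S004	s2	LKNDAER	o1	24.0	false
S005	s1	MGGTAVK	o2	29.0	false
S006	s1	MGGTAVK	o2	23.5	false
S007	s2	MGGTAVK	o2	22.0	false
S008	s1	VSSPLLK	o3	28.0	false
S009	s2	VSSPLLK	o3	21.5	false
S010	s2	VSSPLLK	o3	20.5	false
S011	s1	TTYHNLR	o4	27.0	false
S012	s1	TTYHNLR	o4	19.5	false
S013	s2	TTYHNLR	o4	18.5	false
S014	s2	AQQIWGK	o5	26.5	false
S015	s1	AQQIWGK	o5	17.0	false
S016	s1	AQQIWGK	o5	16.0	false
S017	s1	NNDEFSR	o6	25.5	false
S018	s2	NNDEFSR	o6	15.5	false
S019	s2	NNDEFSR	o6	14.5	false
S020	s1	AAAAKWR	oL	24.5	false
S021	s2	AAAAKWR	oL	13.5	false
S022	s1	AAAAKWR	oL	12.5	false
S023	s1	MWWWWKR	oS	23.8	false
S024	s2	MWWWWKR	oS	11.5	false
S025	s2	MWWWWKR	oS	10.5	false
S026	s1	GGHHLLK	o9	22.8	false
S027	s2	GGHHLLK	o9	9.5	false
S028	s1	CCDDEEK	o10	21.8	false
S029	s1	CCDDEEK	o10	8.5	false
S030	s1	QQRRSSK	o11	12.0	false
S031	s2	QQRRSSK	o11	10.0	false
S032	s2	TTVVWWK	o12	11.0	false
SD01	s1	REANDKL		13.0	true
SD02	s1	KVATGGM		9.0	true
SD03	s2	KLLPSSV		8.0	true
SD04	s2	RLNHYTT		7.0	true
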