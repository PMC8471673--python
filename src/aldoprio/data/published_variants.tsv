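# 21 somatic variants retained by the targeted-NGS screen of 75 hotspot-negative
# unilateral primary aldosteronism samples (one row per sample event).
# Positions are synthetic placeholders (gene anchor + 3 x residue number): the
# published table reports chromosome labels only.
sample_id	gene	chrom	pos	ref	alt	protein_change	consequence	vaf	dbsnp_maf	in_evs	in_tgp	gnomad_hits	exac_hits	cadd	pp2_score	pp2_category	sift_score	sift_category	in_disease_db
NGS01	ATP1A1	1	116917010	C	A	Leu670Ile	missense	5.07		false	false			25.9	0.978	probably_damaging	0.01	deleterious	false
NGS02	ATP2B3	X	152804567	G	A	Gly1189Ser	missense	12.56		false	false			25.7	0.901	probably_damaging			false
NGS03	ATP2B3	X	152804567	G	A	Gly1189Ser	missense	12.56		false	false			25.7	0.901	probably_damaging			false
NGS04	ATP2B3	X	152803604	T	C	Phe868Leu	missense	5.15		false	false			24.7	0.415	benign			false
NGS05	CACNA1D	3	53533119	G	A	Val1373Met	missense	5.59		false	false			33	1.0	probably_damaging	0	deleterious	false
NGS06	CACNA1D	3	53533119	G	A	Val1373Met	missense	20.35		false	false			33	1.0	probably_damaging	0	deleterious	false
NGS07	CACNA1D	3	53531016	C	T	Ser672Leu	missense	39.75		false	false			35	0.992	probably_damaging	0	deleterious	false
NGS08	CACNA1D	3	53529720	C	T	Arg240Cys	missense	5.58		false	false			35	1.0	probably_damaging	0	deleterious	false
NGS09	CACNA1D	3	53530770	G	A	Met590Ile	missense	5.56		false	false			30	0.917	probably_damaging	0	deleterious	false
NGS10	CACNA1D	3	53529744	T	C	Leu248Pro	missense	5.14		false	false			28	1.0	probably_damaging	0	deleterious	false
NGS11	CACNA1D	3	53535327	G	A	Ala2109Thr	missense	8.25		false	false			28.7	0.999	probably_damaging	0	deleterious	false
NGS12	CACNA1D	3	53529369	T	C	Val123Ala	missense	5.45		false	false			26.4	0.999	probably_damaging	0.02	deleterious	false
NGS13	CACNA1D	3	53533686	G	A	Gly1562Arg	missense	5.6		false	false			34	0.986	probably_damaging	0	deleterious	false
NGS14	CACNA1H	16	1203831	C	T	Pro277Ser	missense	48.37		false	false			24.4	0.971	probably_damaging	0.03	deleterious	false
NGS15	CACNA1H	16	1205625	A	G	Gln875Arg	missense	8.03		false	false			25.9	0.83	probably_damaging	0	deleterious	false
NGS16	CACNA1H	16	1204845	A	G	Thr615Pro	missense	10.45		false	false			25.3	0.766	probably_damaging	0	deleterious	false
NGS17	CACNA1H	16	1205712	C	T	Gln904Ter	nonsense	10.2		false	false			38			0	deleterious	false
NGS18	CACNA1H	16	1204446	G	A	Trp482Ter	nonsense	13.54		false	false			36			0.17	tolerated	false
NGS19	CLCN2	3	184064398	C	G	Gly466Ala	missense	37.01		false	false			25.5	0.489	probably_damaging	0	deleterious	false
NGS20	CLCN2	3	184063756	A	G	Phe252Ser	missense	17.33		false	false			28.3	0.997	probably_damaging	0	deleterious	false
NGS21	CTNNB1	3	41240369	C	T	Gln123Ter	nonsense	7.87		false	false			37			0.01	deleterious	false
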