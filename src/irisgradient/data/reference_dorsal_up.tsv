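transcript_id	annotation	v4	d4	v8	d8	log2fc4	log2fc8	log2fc
transcript114225	LOW QUALITY PROTEIN: ras-associated and pleckstrin homology domains-containing protein 1-like [Xenopus (Silurana) tropicalis]	0.0	2.987	0.0	1.296	NA	NA	NA
transcript89311	transmembrane protein 185A-like [Anolis carolinensis]	0.0	6.49	0.0	1.292	NA	NA	NA
transcript53947	similar to Chromatin assembly factor 1 subunit B [Canis familiaris]	0.0	5.182	0.0	1.986	NA	NA	NA
transcript75898	pG1 protein [Lactobacillus jensenii 269-3]	0.331	5.828	0.151	19.812	4.140	7.038	5.735
transcript41516	LOW QUALITY PROTEIN: probable E3 ubiquitin-protein ligase HERC2-like [Xenopus (Silurana) tropicalis]	0.0	4.07	0.193	2.527	NA	3.713	5.098
transcript28206	regeneration blastema forelimb-specific Tbx [Notophthalmus viridescens]	0.272	4.549	0.248	12.007	4.062	5.595	4.990
transcript14449	similar to TMEM116 protein [Gallus gallus]	0.335	1.492	0.485	20.092	2.156	5.373	4.719
transcript12545	hypothetical protein LOC432274 [Xenopus laevis]	0.0	3.858	0.253	1.988	NA	2.976	4.532
transcript63962	hypothetical protein LOC495396 [Xenopus laevis]	0.29	4.756	0.0	1.765	4.038	NA	4.493
transcript80306	ephrin-B2 [Taeniopygia guttata]	0.302	4.602	0.358	8.955	3.930	4.645	4.361
transcript87396	programmed cell death 2 [Xenopus laevis]	0.14	2.293	0.127	3.168	4.038	4.637	4.354
transcript89253	transmembrane protein 116-like [Meleagris gallopavo]	0.163	1.691	0.653	14.078	3.374	4.430	4.272
transcript59308	DEP domain-containing protein 1B-like isoform 1 [Nomascus leucogenys]	0.106	3.145	0.194	2.27	4.886	3.548	4.172
transcript15984	nuclear pore membrane glycoprotein 210 precursor [Mus musculus]	0.0	1.977	0.183	1.155	NA	2.658	4.097
transcript88594	similar to Thimet oligopeptidase [Canis familiaris]	0.0	3.005	0.298	1.991	NA	2.740	4.068
transcript82136	WD repeat and FYVE domain-containing protein 3 isoform 1 [Monodelphis domestica]	0.0	2.541	0.252	1.684	NA	2.740	4.068
transcript92162	netrin receptor UNC5B-like [Xenopus (Silurana) tropicalis]	0.0	2.333	0.476	5.587	NA	3.552	4.056
transcript89179	apoptosis-inducing factor 2-like [Anolis carolinensis]	0.0	4.743	0.387	1.246	NA	1.686	3.951
transcript22057	dihydroxyacetone kinase 2 [Taeniopygia guttata]	0.0	2.147	0.282	2.094	NA	2.892	3.911
transcript88286	lysophospholipid acyltransferase 5-like [Xenopus (Silurana) tropicalis]	0.132	2.776	0.181	1.922	4.394	3.412	3.909
transcript103122	LOW QUALITY PROTEIN: laminin subunit alpha-4-like [Xenopus (Silurana) tropicalis]	0.0	5.539	0.513	2.03	NA	1.985	3.884
transcript57122	calmodulin-regulated spectrin-associated protein 3 [Danio rerio]	0.0	4.118	0.497	2.953	NA	2.570	3.830
transcript65968	biphenyl hydrolase-like (serine hydrolase) [Xenopus laevis]	0.0	3.044	0.47	3.573	NA	2.928	3.817
transcript87765	ras and Rab interactor 2-like [Meleagris gallopavo]	0.278	4.391	0.127	1.32	3.979	3.378	3.816
transcript115898	serine/threonine-protein kinase PLK4 [Xenopus (Silurana) tropicalis]	0.0	3.9	0.467	2.426	NA	2.378	3.761
transcript105338	epithelial cell transforming sequence 2 oncogene [Xenopus (Silurana) tropicalis]	0.0	2.945	0.303	1.124	NA	1.892	3.748
transcript55938	hypothetical protein [Gallus gallus]	0.0	7.267	0.811	3.277	NA	2.015	3.701
transcript23291	LOW QUALITY PROTEIN: serine/threonine-protein kinase WNK1-like [Anolis carolinensis]	0.21	3.866	0.24	1.85	4.201	2.949	3.668
transcript93294	39S ribosomal protein L15, mitochondrial precursor [Xenopus laevis]	0.155	4.783	0.353	1.574	4.948	2.155	3.645
transcript11364	glycerol kinase [Candidatus Liberibacter americanus]	4.046	7.288	0.58	50.265	0.849	6.436	3.637
transcript111723	adenylate cyclase type 6 isoform 2 [Equus caballus]	0.285	7.856	0.519	1.35	4.786	1.378	3.517
transcript63503	coiled-coil domain-containing protein 85C-like [Anolis carolinensis]	0.0	3.369	0.567	3.051	NA	2.428	3.501
transcript56063	hypothetical protein RAYM_09754 [Riemerella anatipestifer RA-YM]	1.421	22.491	0.678	1.115	3.984	0.719	3.492
transcript63410	signal peptide, CUB and EGF-like domain-containing protein 3 [Monodelphis domestica]	0.0	2.531	0.479	2.609	NA	2.445	3.423
transcript59917	cell cycle regulator Mat89Bb homolog [Sus scrofa]	0.0	8.811	1.121	3.103	NA	1.469	3.409
transcript95772	hypothetical protein [Gallus gallus]	0.113	2.902	0.413	2.646	4.679	2.679	3.398
transcript23822	UPF0679 protein C14orf101-like [Sus scrofa]	0.0	6.341	0.88	2.745	NA	1.641	3.368
transcript109593	mesoderm development candidate 1 [Taeniopygia guttata]	0.261	3.091	0.298	2.522	3.564	3.081	3.327
transcript84524	unnamed protein product [Tetraodon nigroviridis]	0.0	1.879	0.356	1.497	NA	2.073	3.246
transcript25525	fas apoptotic inhibitory molecule 1-like [Anolis carolinensis]	0.0	7.291	0.973	1.763	NA	0.857	3.218
transcript47004	LOW QUALITY PROTEIN: matrix-remodeling-associated protein 5-like [Pongo abelii]	0.0	4.089	0.69	2.278	NA	1.722	3.205
transcript83773	hypothetical protein [Ornithorhynchus anatinus]	0.205	6.858	0.933	3.327	5.066	1.833	3.162
transcript80809	HIV-1 tat interactive protein [Danio rerio]	0.221	3.551	0.402	2.017	4.009	2.325	3.160
transcript101040	LOW QUALITY PROTEIN: protein NEDD1-like [Anolis carolinensis]	0.0	2.837	0.525	1.755	NA	1.740	3.128
transcript83315	ras GTPase-activating-like protein IQGAP2 [Xenopus (Silurana) tropicalis]	0.0	3.094	0.537	1.424	NA	1.407	3.073
transcript48784	30S ribosomal protein S14 [Chryseobacterium gleum ATCC 35910]	0.761	10.28	0.644	1.509	3.756	1.228	3.069
transcript19175	hyaluronan synthase 2-like [Anolis carolinensis]	0.205	7.412	1.975	10.789	5.175	2.450	3.062
transcript90710	vaccinia related kinase 1 [Xenopus laevis]	0.311	2.96	0.213	1.315	3.252	2.629	3.030
transcript119283	neurobeachin-like protein 1-like [Anolis carolinensis]	0.0	5.855	0.889	1.32	NA	0.570	3.013
transcript104553	exocyst complex component 1-like isoform 1 [Anolis carolinensis]	0.29	4.137	0.47	1.884	3.8202	2.011	2.985
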