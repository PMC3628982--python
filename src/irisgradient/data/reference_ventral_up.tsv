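transcript_id	annotation	v4	d4	v8	d8	log2fc4	log2fc8	log2fc
transcript31815	netrin-1-like [Xenopus (Silurana) tropicalis]	5.052	0.141	7.897	0.066	-5.166	-6.892	-5.965
transcript93602	retrotransposable element Tf2 155 kDa protein type 1-like, partial [Xenopus (Silurana) tropicalis]	2.2	0.0	3.177	0.124	NA	-4.678	-5.437
transcript32521	ventral anterior homeobox 2a-like [Xenopus (Silurana) tropicalis]	6.383	0.271	9.86	0.122	-4.560	-6.336	-5.371
transcript26555	nuclear receptor subfamily 2 group F member 5-like [Xenopus (Silurana) tropicalis]	6.299	0.378	14.165	0.158	-4.057	-6.482	-5.253
transcript73289	hypothetical protein LOC100486110 [Xenopus (Silurana) tropicalis]	8.643	0.196	2.039	0.404	-5.464	-2.336	-4.155
transcript99097	hypothetical protein LOC100485130 [Xenopus (Silurana) tropicalis]	19.132	0.951	3.079	0.708	-4.331	-2.121	-3.744
transcript45528	ORF2-encoded protein [Danio rerio]	9.423	0.436	1.574	0.449	-4.434	-1.808	-3.635
transcript14061	similar to reverse transcriptase-like protein [Strongylocentrotus purpuratus]	10.385	0.315	2.696	0.811	-5.043	-1.732	-3.538
transcript66096	retrotransposable element Tf2 155 kDa protein type 1-like [Danio rerio]	6.047	0.567	3.939	0.292	-3.413	-3.752	-3.538
transcript97196	ATP-binding cassette, sub-family G (WHITE), member 2 [Xenopus laevis]	4.516	0.424	2.059	0.218	-3.413	-3.237	-3.356
transcript19896	CR1-3 [Lycodichthys dearborni]	8.64	0.481	3.807	0.744	-4.167	-2.356	-3.345
transcript106073	sorting nexin-25 [Monodelphis domestica]	2.248	0.246	3.76	0.381	-3.191	-3.304	-3.261
transcript67285	zinc finger protein 850-like [Monodelphis domestica]	1.431	0.209	1.305	0.081	-2.776	-4.015	-3.240
transcript8700	similar to ORF2-encoded protein [Strongylocentrotus purpuratus]	6.676	0.0	3.119	1.103	NA	-1.500	-3.151
transcript116527	retrotransposable element Tf2 155 kDa protein type 1-like [Anolis carolinensis]	4.011	0.465	3.874	0.479	-3.109	-3.015	-3.062
transcript8488	hypothetical protein LOC100494670 [Xenopus (Silurana) tropicalis]	8.977	0.985	2.83	0.515	-3.188	-2.459	-2.977
transcript44589	reverse transcriptase [Anguilla japonica]	14.281	2.024	6.449	0.616	-2.819	-3.387	-2.973
transcript41350	hypothetical protein LOC100496475 [Xenopus (Silurana) tropicalis]	15.178	1.601	2.794	0.731	-3.245	-1.935	-2.946
transcript56731	hypothetical protein LOC100494422 [Xenopus (Silurana) tropicalis]	12.385	1.216	3.181	0.819	-3.349	-1.957	-2.935
transcript15059	reverse transcriptase [Danio rerio]	16.797	1.881	3.116	0.724	-3.159	-2.106	-2.934
transcript30275	cleavage stimulation factor subunit 2-like [Homo sapiens]	7.765	0.9	2.351	0.442	-3.109	-2.411	-2.914
transcript3811	pol protein [Salamandra salamandra]	15.064	1.665	5.586	1.192	-3.178	-2.229	-2.854
transcript19227	similar to reverse transcriptase-like protein, partial [Strongylocentrotus purpuratus]	8.679	0.292	2.69	1.281	-4.891	-1.070	-2.853
transcript41219	hypothetical protein LOC100493707 [Xenopus (Silurana) tropicalis]	7.539	0.842	1.994	0.485	-3.162	-2.040	-2.845
transcript21599	SPARC-related modular calcium-binding protein 1-like [Anolis carolinensis]	5.688	1.029	13.814	1.709	-2.467	-3.015	-2.832
transcript67066	phosphatidylinositol-3,4,5-trisphosphate 5-phosphatase 2-like [Anolis carolinensis]	8.278	0.68	3.421	0.964	-3.606	-1.828	-2.832
transcript40028	reverse transcriptase-like protein [Salmo salar]	8.686	0.839	4.019	0.951	-3.372	-2.079	-2.827
transcript84492	similar to Family with sequence similarity 116, member A [Ornithorhynchus anatinus]	6.781	0.431	1.496	0.741	-3.975	-1.015	-2.820
transcript18114	Pro-Pol-dUTPase polyprotein [Mus musculus]	3.825	0.234	3.326	0.783	-4.032	-2.087	-2.814
transcript29937	reverse transcriptase [Chironomus tentans]	10.035	0.84	2.872	0.999	-3.578	-1.523	-2.811
transcript5182	similar to LReO_3 [Strongylocentrotus purpuratus]	20.89	2.839	6.57	1.098	-2.879	-2.582	-2.802
transcript71146	putative nuclease HARBI1 [Xenopus (Silurana) tropicalis]	47.02	5.281	10.514	2.979	-3.154	-1.820	-2.800
transcript1139	sushi, von Willebrand factor type A, EGF and pentraxin domain-containing protein 1-like [Xenopus (Silurana) tropicalis]	27.032	2.851	7.238	2.099	-3.245	-1.786	-2.791
transcript57867	endonuclease/reverse transcriptase [Sus scrofa]	5.817	0.249	1.211	0.771	-4.545	-0.652	-2.785
transcript78186	reverse transcriptase-like protein-like [Saccoglossus kowalevskii]	15.112	1.917	2.519	0.67	-2.979	-1.910	-2.768
transcript2222	reverse transcriptase-like protein [Paralichthys olivaceus]	14.076	1.403	3.805	1.237	-3.327	-1.622	-2.760
transcript5593	Myb protein P42POP, isoform CRA_a [Mus musculus]	13.4	1.539	3.506	0.967	-3.122	-1.858	-2.754
transcript899	hypothetical protein TcasGA2_TC015886 [Tribolium castaneum]	10.49	0.88	2.036	0.982	-3.576	-1.051	-2.750
transcript51721	hypothetical protein LOC100488716 [Xenopus (Silurana) tropicalis]	4.344	0.0	1.585	0.882	NA	-0.845	-2.748
transcript7725	hypothetical protein LOC734400 [Xenopus laevis]	9.043	0.907	2.479	0.815	-3.317	-1.605	-2.742
transcript108620	hypothetical protein LOC100497892 [Xenopus (Silurana) tropicalis]	17.822	2.26	3.565	0.953	-2.980	-1.904	-2.735
transcript70652	hypothetical protein LOC100492542 [Xenopus (Silurana) tropicalis]	7.011	0.825	2.004	0.532	-3.087	-1.915	-2.733
transcript15129	similar to transposase [Strongylocentrotus purpuratus]	7.68	0.917	4.192	0.886	-3.066	-2.242	-2.718
transcript1001	hypothetical protein LOC100490320 [Xenopus (Silurana) tropicalis]	44.292	5.312	9.908	2.944	-3.060	-1.751	-2.715
transcript7879	NADH dehydrogenase (ubiquinone) 1 alpha subcomplex, 4 b [Xenopus laevis]	1521.4	153.4	130.6	98.732	-3.310	-0.403	-2.712
transcript112029	similar to CR1 Danio rerio 2 reverse transcriptase isoform 3 [Strongylocentrotus purpuratus]	17.674	1.804	3.208	1.394	-3.293	-1.202	-2.707
transcript68620	hypothetical protein LOC100497926 [Xenopus (Silurana) tropicalis]	5.412	0.79	3.565	0.611	-2.776	-2.545	-2.680
transcript1148	hypothetical protein LOC100493982 [Xenopus (Silurana) tropicalis]	17.683	2.6	5.544	1.056	-2.766	-2.392	-2.667
transcript338	reverse transcriptase-like protein [Takifugu rubripes]	364.357	50.283	86.144	20.794	-2.857	-2.051	-2.664
transcript1216	hypothetical protein LOC100495475, partial [Xenopus (Silurana) tropicalis]	8.246	0.355	2.898	1.419	-4.537	-1.030	-2.651
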