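# Whole-assembly SSR overview for twelve published weevil draft genomes,
# transcribed from the printed survey table (default scan thresholds
# 12/7/5/4/4/4, periods 1-6). Used as the no-download fixture for the
# cross-assembly correlation suite.
assembly_id	common_name	size_mb	n_loci	freq_per_mb	density_bp_per_mb	ssr_content_pct
R_ferrugineus_F	Female red palm weevil	1121.36	57175	50.99	1320.92	0.13
R_ferrugineus_M	Male red palm weevil	782.10	50723	64.86	1445.93	0.14
R_ferrugineus_L	Red palm weevil larva	589.40	67261	114.11	3649.45	0.36
S_oryzae	Rice weevil	770.57	84391	109.52	3287.11	0.33
H_hampei	Coffee berry borer	162.57	13092	80.53	3260.24	0.33
D_ponderosae_F	Female mountain pine beetle	223.74	6505	29.07	481.68	0.05
D_ponderosae_M	Male mountain pine beetle	224.79	6803	30.26	511.44	0.05
P_strobi	White pine weevil	2025.02	154511	76.30	1516.87	0.15
E_kamerunicus	African oil palm weevil	269.64	4397	16.31	249.98	0.02
I_nitidus	Qinghai spruce bark beetle	345.00	48372	140.21	3127.27	0.31
L_oregonensis	Carrot weevil	1293.28	534123	412.99	14406.26	1.44
L_bonariensis	Argentine stem weevil	1112.44	156716	140.88	3976.45	0.40
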