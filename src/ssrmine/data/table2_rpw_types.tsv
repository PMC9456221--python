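# Per-type SSR counts and total tract lengths for the adult-female and
# larval red palm weevil assemblies, transcribed from the printed survey
# table. Derived metrics (mean length, frequency, density, shares) are
# recomputed from these integers together with the assembly sizes in
# table1_weevils.tsv.
assembly_id	period	n_loci	total_bp
R_ferrugineus_F	1	6393	98929
R_ferrugineus_F	2	34681	1084748
R_ferrugineus_F	3	8517	142764
R_ferrugineus_F	4	5368	94688
R_ferrugineus_F	5	1318	30555
R_ferrugineus_F	6	898	29538
R_ferrugineus_L	1	4906	69520
R_ferrugineus_L	2	47993	1823936
R_ferrugineus_L	3	7407	126207
R_ferrugineus_L	4	5515	97284
R_ferrugineus_L	5	1151	25330
R_ferrugineus_L	6	289	8718
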