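# Deregulated genes implicated in HSCR and/or ENS formation
# (>= 2-fold, both adjusted p < 0.001). Decimal-comma and
# space-thousands dialect preserved from the printed table.
gene	function	fold	mutant_mean_count	control_mean_count	chromosome	start	end
Aldh1a1	retinoic acid metabolism	16,09	8 108	540	19	20 601 961	20 643 462
Aldh1a2	retinoic acid metabolism	7,14	12 001	1 824	9	71 215 789	71 296 243
Ece1	endothelin processing	2,30	8 084	3 758	4	137 862 237	137 965 229
Edn3	secreted ligand for Ednrb	4,80	1 875	432	2	174 760 619	174 784 042
Ednrb	Edn3 receptor	-2,80	20 420	57 755	14	103 814 625	103 844 173
Gdnf	secreted ligand for Ret	6,27	2 477	428	15	7 811 011	7 837 575
Hand2	transcription factor	-2,07	4 355	9 135	8	57 320 983	57 324 517
Hlx	transcription factor	3,57	2 736	841	1	184 727 140	184 732 619
Ntf3	neurotrophic ligand	3,52	494	153	6	126 101 413	126 166 744
Phox2b	transcription factor	-3,31	4 950	16 278	5	67 094 397	67 099 249
Ret	Gdnf receptor	-3,78	9 204	34 338	6	118 151 748	118 197 744
Sox10	transcription factor	-2,97	2 229	6 527	15	79 154 913	79 164 490
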