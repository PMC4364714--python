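# Downregulated X-linked genes (>= 2-fold, both adjusted p < 0.001),
# ordered by chromosomal position. No Y-linked gene was significantly
# upregulated. Printed-dialect numbers preserved.
gene	function	fold	mutant_mean_count	control_mean_count	start	end
Clcn5	ion channel	-2,14	4 078	8 936	7 153 810	7 319 358
Syp	vesicular trafficking	-2,89	382	1 125	7 638 471	7 653 256
Slc38a5	amino acid transport	-13,72	14	202	8 271 133	8 280 179
Lancl3	signal transduction	-2,91	117	341	9 199 902	9 268 085
Tspan7	signal transduction	-2,13	1 361	2 980	10 485 158	10 596 605
Gm5124	pseudogene	-2,17	117	261	21 360 865	21 364 622
Zcchc12	transcription factor	-2,32	495	1 165	36 195 904	36 199 158
Arhgap36	Rho GTPase activating protein	-2,15	151	335	49 463 945	49 500 244
Cxx1c	uncharacterized (protein-coding)	-2,18	258	573	53 607 922	53 609 132
Fgf13	growth factor	-2,68	690	1 871	59 062 145	59 568 071
Slitrk2	signal transduction	-2,67	968	2 623	66 649 318	66 661 393
Rab39b	vesicular trafficking	-2,60	402	1 065	75 572 046	75 578 231
Nlgn3	neuronal cell-cell interaction	-2,46	203	509	101 299 168	101 325 963
Nap1l2	chromatin regulation	-2,34	279	670	103 184 176	103 186 640
5330434G04Rik	uncharacterized (lincRNA)	-2,02	347	707	105 348 282	105 391 776
Bex1	signal transduction	-2,16	764	1 693	136 213 972	136 215 513
Plp1	major myelin protein	-2,43	1 289	3 194	136 822 671	136 839 733
Rab9b	vesicular trafficking	-2,95	78	232	136 858 147	136 868 755
Dcx	microtubule-associated	-3,17	1 103	3 517	143 855 842	143 933 311
Alas2	heme biosynthesis	-4,46	33	150	150 547 375	150 570 638
Map7d2	microtubule-associated	-2,47	158	398	159 414 572	159 498 757
Tmem27	amino acid transport	-32,40	1	39	164 088 830	164 118 860
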