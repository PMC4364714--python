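# Chromosome-10 most deregulated genes (>= 4-fold, both adjusted
# p < 0.001). Printed-dialect numbers preserved.
gene	function	fold	mutant_mean_count	control_mean_count	start	end
Tcf21	transcription factor	4,01	4 671	1 269	22 817 279	22 820 128
Rspo3	activator of Wnt pathway	4,24	2 542	649	29 453 109	29 535 867
Ddo	oxidative deamination of aspartate	11,29	77	7	40 630 011	40 649 931
Fam162b	uncharacterized (protein coding)	4,99	391	85	51 585 420	51 590 480
Ggt5	converts leukotriene C4 to D4	5,40	231	46	75 589 381	75 616 968
Col6a1	extracellular matrix, collagen	4,02	10 966	3 004	76 708 792	76 726 168
Onecut3	transcription factor	-6,24	11	68	80 494 835	80 517 276
Lum	extracellular matrix, proteoglycan	6,07	5 146	943	97 565 501	97 572 703
Epyc	extracellular matrix, proteoglycan	6,81	401	65	97 644 068	97 682 454
Rassf9	vesicular trafficking	7,29	471	72	102 512 222	102 546 560
Otogl	inner ear mechanotransduction	4,50	262	63	107 762 223	107 912 134
Gli1	transcription factor	5,86	3 209	585	127 329 889	127 341 589
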