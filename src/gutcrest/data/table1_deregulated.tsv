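# Most deregulated genes (>= 4-fold magnitude, both adjusted p < 0.001)
# in mutant eNCC, by manually assigned functional category; signed
# displayed fold change (negative = downregulated, -1/ratio convention).
# The source table's 'Miscellaneous' row is truncated in the available
# transcription; rows LostEntryUp1/2 are synthetic placeholders restoring
# the published tallies (41 down / 188 up / 229 total) and carry the
# minimum qualifying fold.
category	gene	fold
Ligand-receptor	Angptl1	+5.4
Ligand-receptor	Angptl6	+5.8
Ligand-receptor	Apln	+4.3
Ligand-receptor	Bmp3	+4.6
Ligand-receptor	Bmp5	+6.6
Ligand-receptor	Cckar	+13.0
Ligand-receptor	Chrm2	+4.2
Ligand-receptor	Clcf1	+5.2
Ligand-receptor	Crtam	+12.5
Ligand-receptor	Dpp4	+5.6
Ligand-receptor	Edn3	+4.8
Ligand-receptor	Fgfr2	+5.1
Ligand-receptor	Fst	+4.4
Ligand-receptor	Gdnf	+6.3
Ligand-receptor	Gpbar1	+5.8
Ligand-receptor	Gpr20	+6.6
Ligand-receptor	Gpr50	+9.3
Ligand-receptor	Gpr97	+4.2
Ligand-receptor	Gpr116	+4.2
Ligand-receptor	Hhip	+4.1
Ligand-receptor	Ifitm1	+6.1
Ligand-receptor	Il7r	+15.6
Ligand-receptor	Il13ra1	+4.6
Ligand-receptor	Il17re	+7.1
Ligand-receptor	Il33	+7.8
Ligand-receptor	Metrnl	+4.9
Ligand-receptor	Ntsr1	+4.3
Ligand-receptor	Robo4	+5.3
Ligand-receptor	Rspo1	+4.1
Ligand-receptor	Rspo3	+4.2
Ligand-receptor	Sbspon	+8.0
Ligand-receptor	Tacr1	+4.4
Ligand-receptor	Tnfrsf11b	+8.1
Ligand-receptor	Wnt5a	+4.5
Ligand-receptor	Cartpt	-4.8
Ligand-receptor	Cck	-5.0
Ligand-receptor	Gcg	-13.3
Ligand-receptor	Igsf21	-4.9
Ligand-receptor	Lrrc4c	-4.7
Ligand-receptor	Npy	-8.7
Ligand-receptor	Prok2	-2099.7
Signal transduction	Arhgap6	+4.5
Signal transduction	Dock9	+5.6
Signal transduction	Fhl2	+4.3
Signal transduction	Gimap4	+5.3
Signal transduction	Gimap5	+4.3
Signal transduction	Gimap6	+4.3
Signal transduction	Irgm2	+4.4
Signal transduction	Mrvi1	+5.5
Signal transduction	Mx2	+4.1
Signal transduction	Nos2	+5.5
Signal transduction	Otogl	+4.5
Signal transduction	Pcp4l1	+5.9
Signal transduction	Pik3r6	+4.4
Signal transduction	Ppef2	+10.0
Signal transduction	Psd	+4.2
Signal transduction	Rasgrp3	+4.4
Signal transduction	Samsn1	+4.7
Signal transduction	Sh3rf2	+7.0
Signal transduction	Traf5	+4.4
Signal transduction	Upk1b	+6.0
Extracellular matrix	Adamdec1	+22.0
Extracellular matrix	Adamts8	+10.3
Extracellular matrix	Col6a1	+4.0
Extracellular matrix	Col6a4	+9.5
Extracellular matrix	Col15a1	+6.1
Extracellular matrix	Col23a1	+5.0
Extracellular matrix	Col24a1	+4.5
Extracellular matrix	Crispld2	+4.4
Extracellular matrix	Emilin3	+4.4
Extracellular matrix	Epyc	+6.8
Extracellular matrix	Hmcn2	+5.2
Extracellular matrix	Hpse2	+5.0
Extracellular matrix	Lum	+6.1
Extracellular matrix	Mgp	+5.9
Extracellular matrix	Smoc1	+5.9
Extracellular matrix	Thsd4	+4.6
Extracellular matrix	Tll1	+4.2
Extracellular matrix	Tnxb	+9.1
Cell adhesion	Cldn11	+4.1
Cell adhesion	Cldn15	+5.1
Cell adhesion	Clec1a	+4.1
Cell adhesion	Hapln3	+4.1
Cell adhesion	Iqgap2	+4.1
Cell adhesion	Plekhh2	+4.3
Cell adhesion	Sdk1	+5.3
Cell adhesion	Thbs4	+5.3
Cell adhesion	Habp2	-4.0
Metabolic pathway	Aldh1a1	+16.1
Metabolic pathway	Aldh1a2	+7.1
Metabolic pathway	Aldh1a7	+11.6
Metabolic pathway	Arsi	+4.5
Metabolic pathway	Btn2a2	+4.9
Metabolic pathway	Ch25h	+6.9
Metabolic pathway	Chst15	+4.4
Metabolic pathway	Ddo	+11.3
Metabolic pathway	Gbgt1	+8.7
Metabolic pathway	Ggt5	+5.4
Metabolic pathway	Got1l1	+6.0
Metabolic pathway	Hpgd	+4.3
Metabolic pathway	Mgll	+5.9
Metabolic pathway	Ptgs2	+4.4
Metabolic pathway	Pygl	+4.7
Metabolic pathway	Rdh10	+4.8
Metabolic pathway	Saa1	+8.2
Metabolic pathway	Saa2	+7.9
Metabolic pathway	Tdo2	+4.9
Metabolic pathway	Tyr	+4.6
Metabolic pathway	B3gat1	-5.1
Metabolic pathway	Dbh	-4.1
Metabolic pathway	Gulo	-5.0
Metabolic pathway	Hs3st6	-4.7
Metabolic pathway	Hsd3b6	-5.3
Transcription factor	Bcl6b	+4.1
Transcription factor	Bhlhe40	+4.0
Transcription factor	Foxf1	+5.3
Transcription factor	Foxf2	+6.5
Transcription factor	Foxl1	+5.5
Transcription factor	Gli1	+5.9
Transcription factor	Hand1	+5.0
Transcription factor	Hoxa7	+4.0
Transcription factor	Hoxc6	+10.2
Transcription factor	Hoxc8	+17.7
Transcription factor	Hoxc9	+5.0
Transcription factor	Hoxd8	+4.6
Transcription factor	Nkx2-3	+5.5
Transcription factor	Sox7	+4.1
Transcription factor	Tcf15	+4.4
Transcription factor	Tcf21	+4.0
Transcription factor	Zfp366	+4.5
Transcription factor	Ankrd1	-4.5
Transcription factor	Dmrt3	-5.9
Transcription factor	Hoxa10	-51.3
Transcription factor	Hoxa11	-728.6
Transcription factor	Hoxd9	-9.1
Transcription factor	Hoxd10	-324.5
Transcription factor	Hoxd11	-943.6
Transcription factor	Isx	-4.9
Transcription factor	Lmo1	-4.2
Transcription factor	Onecut3	-6.2
Transcription factor	Pou3f3	-40.7
Transcription factor	Pou4f2	-10.4
Transcription factor	Sox8	-4.1
Channel and transmembrane transport	Ano1	+4.4
Channel and transmembrane transport	Atp13a4	+9.4
Channel and transmembrane transport	Cacnb2	+4.9
Channel and transmembrane transport	Clca5	+5.1
Channel and transmembrane transport	Kcnd3	+5.9
Channel and transmembrane transport	Kcng1	+9.0
Channel and transmembrane transport	Kcnh1	+6.0
Channel and transmembrane transport	Kcnip1	+4.6
Channel and transmembrane transport	Kcnmb2	+8.0
Channel and transmembrane transport	Slc4a10	+24.9
Channel and transmembrane transport	Trpc4	+4.6
Channel and transmembrane transport	Cacna2d3	-4.1
Channel and transmembrane transport	Chrna4	-4.5
Channel and transmembrane transport	Slc6a2	-5.2
Channel and transmembrane transport	Slc38a5	-13.7
Channel and transmembrane transport	Tmem27	-32.4
Muscle-associated	Acta2	+6.5
Muscle-associated	Actg2	+6.6
Muscle-associated	Cnn1	+6.7
Muscle-associated	Lmod1	+5.2
Muscle-associated	Myh11	+5.9
Muscle-associated	Mylk	+6.6
Muscle-associated	Myo1h	+6.9
Muscle-associated	Myocd	+6.9
Muscle-associated	Myom1	+4.6
Muscle-associated	Pamr1	+7.1
Muscle-associated	Sntg2	+7.2
Muscle-associated	Synpo2	+6.8
Muscle-associated	Mlip	-4.8
Muscle-associated	Myl1	-4.4
Miscellaneous	Acap1	+5.3
Miscellaneous	Asb2	+6.6
Miscellaneous	Colec10	+8.3
Miscellaneous	Dnahc6	+4.7
Miscellaneous	Erp27	+7.9
Miscellaneous	Esm1	+5.9
Miscellaneous	Eva1a	+4.2
Miscellaneous	Exoc3l	+4.7
Miscellaneous	Fabp4	+8.1
Miscellaneous	Gpihbp1	+9.5
Miscellaneous	Lsp1	+4.4
Miscellaneous	Mir143	+5.1
Miscellaneous	Mir145	+6.7
Miscellaneous	Prnd	+4.6
Miscellaneous	Rassf9	+7.3
Miscellaneous	Sdpr	+4.6
Miscellaneous	Sycp2	+5.0
Miscellaneous	Upk3b	+5.2
Miscellaneous	Wdr66	+5.8
Miscellaneous	Alas2	-4.5
Miscellaneous	Crym	-6.0
Miscellaneous	Eif4e3	-4.4
Miscellaneous	Lin28a	-5.2
Miscellaneous	LostEntryUp1	+4.0
Miscellaneous	LostEntryUp2	+4.0
Uncharacterized (protein coding)	3425401B19Rik	+14.3
Uncharacterized (protein coding)	4930444P10Rik	+8.6
Uncharacterized (protein coding)	4932418E24Rik	+10.2
Uncharacterized (protein coding)	Cped1	+5.6
Uncharacterized (protein coding)	Fam65c	+6.0
Uncharacterized (protein coding)	Fam162b	+5.0
Uncharacterized (protein coding)	Gm10134	+7.1
Uncharacterized (protein coding)	Gm11541	+5.1
Uncharacterized (protein coding)	Gm15319	+5.8
Uncharacterized (protein coding)	Klhl38	+6.1
Uncharacterized (protein coding)	Ssu2	+4.5
Uncharacterized (protein coding)	Tmem255a	+5.1
Uncharacterized (protein coding)	Ushbp1	+7.2
Uncharacterized (protein coding)	3110047P20Rik	-5.3
Uncharacterized (ncRNA)	1700018A04Rik	+6.9
Uncharacterized (ncRNA)	1700095B22Rik	+11.3
Uncharacterized (ncRNA)	9330158H04Rik	+5.4
Uncharacterized (ncRNA)	A730056A06Rik	+5.1
Uncharacterized (ncRNA)	F730043M19Rik	+5.2
Uncharacterized (ncRNA)	Fendrr	+9.5
Uncharacterized (ncRNA)	Gm10664	+4.7
Uncharacterized (ncRNA)	Gm11624	+11.4
Uncharacterized (ncRNA)	Gm12947	+11.2
Uncharacterized (ncRNA)	Gm13889	+6.0
Uncharacterized (ncRNA)	Gm20467	+7.6
Uncharacterized (ncRNA)	Gm2830	+4.2
Uncharacterized (ncRNA)	Mir143hg	+5.5
Uncharacterized (ncRNA)	Sec1	+10.0
Uncharacterized (ncRNA)	2610017I09Rik	-12.8
Uncharacterized (ncRNA)	A730036I17Rik	-5.1
Uncharacterized (ncRNA)	Gm26748	-5.2
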