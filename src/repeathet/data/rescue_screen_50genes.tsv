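gene_id	symbol	ratio_hf	ratio_treat	mitochondrion
ENSRNOG00000025757	Myh6	0.2	1.59	0
ENSRNOG00000026548	Dhrs7c	0.24	2.09	0
ENSRNOG00000012343	Pdp2	0.27	1.89	1
ENSRNOG00000026679	Scn4b	0.3	1.51	0
ENSRNOG00000006444	Fkbp4	0.32	1.6	0
ENSRNOG00000004078	Eno3	0.33	1.77	0
ENSRNOG00000015904	Wfdc1	0.34	1.59	0
ENSRNOG00000007290	Atp1a2	0.34	1.45	0
ENSRNOG00000004377	Lpin1	0.34	1.46	0
ENSRNOG00000002827	NP_001100444.2	0.35	1.69	0
ENSRNOG00000021174	Lrp16	0.36	1.79	1
ENSRNOG00000018735	Cd74	0.36	1.85	0
ENSRNOG00000011260	RGD:1306952	0.37	1.54	0
ENSRNOG00000004640	MGC94604	0.38	1.57	1
ENSRNOG00000000634	RGD:1306739	0.39	1.81	0
ENSRNOG00000003977	Dusp1	0.4	1.54	0
ENSRNOG00000010697	Hadhsc	0.41	1.4	1
ENSRNOG00000012091	Ppa2	0.41	1.96	1
ENSRNOG00000014641	Rpl3l	0.41	1.66	0
ENSRNOG00000033924	LOC691211	0.42	2.24	0
ENSRNOG00000014128	MGC94704	0.43	1.71	1
ENSRNOG00000033615	NU3M_RAT	0.43	1.93	0
ENSRNOG00000002916	Ca4	0.43	1.78	0
ENSRNOG00000039197	Col15a1	0.44	1.96	0
ENSRNOG00000015807	RGD:1303232	0.45	1.47	0
ENSRNOG00000002272	NP_001101828.1	0.45	1.65	0
ENSRNOG00000012827	NP_001101150.1	0.45	1.7	0
ENSRNOG00000029613	RGD:1562558	0.45	1.86	0
ENSRNOG00000002028	Tmem50b	0.45	1.89	0
ENSRNOG00000021200	Hfe2	0.45	1.43	0
ENSRNOG00000037446	Pxmp2	0.45	1.51	1
ENSRNOG00000021866	NP_001100071.1	0.46	1.93	0
ENSRNOG00000018516	Impa2	0.46	1.45	0
ENSRNOG00000013532	Pgam2	0.47	1.45	0
ENSRNOG00000031321	LOC363987	0.47	1.78	0
ENSRNOG00000021812	LOC684826	0.48	1.48	0
ENSRNOG00000016369	Peci	0.48	1.58	1
ENSRNOG00000006108	LOC690825	0.48	1.89	0
ENSRNOG00000016603	Rtn2	0.48	1.58	0
ENSRNOG00000012249	Txlnb	0.48	1.69	0
ENSRNOG00000007069	Adhfe1	0.48	1.46	1
ENSRNOG00000001912	NP_001102330.1	0.48	1.61	0
ENSRNOG00000017446	NP_001099792.1	0.49	1.54	1
ENSRNOG00000016368	Ppp1r14c	0.49	1.4	0
ENSRNOG00000018415	NP_001099581.1	0.49	1.46	1
ENSRNOG00000006968	Mrpl19	0.49	1.41	1
ENSRNOG00000012455	Tardbp	0.49	1.86	0
ENSRNOG00000005987	Suox	0.49	1.5	1
ENSRNOG00000005487	Chpt1	0.49	1.58	0
ENSRNOG00000015519	Ces3	0.49	1.84	0
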