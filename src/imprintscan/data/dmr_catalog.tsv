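name	display_name	chrom	start	end	methylated_allele	genes	n_cpg_reported
PPIEL:Ex1-DMR	PPIEL:Ex1-DMR	chr1	40024971	40025415	M	LOC728448	4
DIRAS3:Ex2-DMR	DIRAS3:Ex2-DMR	chr1	68512539	68513063	M	DIRAS3	8
DIRAS3:TSS-DMR	DIRAS3:TSS-DMR	chr1	68515788	68517273	M	DIRAS3	21
GPR1-AS:TSS-DMR	GPR1	chr2	207068254	207068409	M	GPR1	2
ZDBF2/GPR1:IG-DMR	ZDBF2/GPR1:IG-DMR	chr2	207116070	207129158	P		8
NAP1L5:TSS-DMR	NAP1L5/HERC3	chr4	89618533	89619236	M	NAP1L5;HERC3	14
VTRNA2-1:DMR	MIR886	chr5	135414858	135416613	M	MIR886	17
FAM50B:TSS-DMR	FAM50B	chr6	3849095	3850106	M	FAM50B	24
PLAGL1:alt-TSS-DMR	HYMAI/PLAGL1	chr6	144328421	144329887	M	HYMAI;PLAGL1	14
IGF2R:Int2-DMR	IGF2R	chr6	160427501	160427501	M	IGF2R	1
WDR27:Int13-DMR	WDR27	chr6	170054730	170055332	M	WDR27	2
GRB10:alt-TSS-DMR	GRB10	chr7	50849168	50850870	M	GRB10	8
PEG10:TSS-DMR	SGCE/PEG10	chr7	94285642	94287242	M	SGCE;PEG10	50
MEST:alt-TSS-DMR	MESTIT1/MEST	chr7	130130122	130133110	M	MESTIT1;MEST	54
SVOPL:alt-TSS-DMR	SVOPL	chr7	138348774	138348981	M	SVOPL	2
HTR5A:TSS-DMR	HTR5A	chr7	154862770	154863381	M	HTR5A	6
ERLIN2:Int6-DMR	ERLIN2	chr8	37605359	37605978	M	LOC728024;ERLIN2	7
PEG13:TSS-DMR	TRAPPC9	chr8	141108607	141110900	M	TRAPPC9	7
FANCC:Int1-DMR	FANCC	chr9	98075492	98075492	M	FANCC	1
INPP5F:Int2-DMR	INPP5F	chr10	121578137	121578639	M	INPP5F	4
H19/IGF2:IG-DMR	H19/MIR675	chr11	2019079	2024126	P	H19;MIR675	43
IGF2:Ex9-DMR	IGF2:Ex9-DMR	chr11	2153991	2154952	M	INS-IGF2;IGF2	9
IGF2:alt-TSS-DMR	IGF2:alt-TSS-DMR	chr11	2168625	2168625	M	IGF2AS;INS-IGF2	1
KCNQ1OT1:TSS-DMR	KCNQ1/KCNQ1OT1	chr11	2720229	2722195	M	KCNQ1;KCNQ1OT1	26
RB1:Int2-DMR	RB1	chr13	48892551	48895478	M	RB1	13
MEG3:TSS-DMR	MEG3	chr14	101290556	101293856	P	MEG3	32
MEG8:Int2-DMR	MEG8	chr14	101370989	101370989	M	MEG8	1
MKRN3:TSS-DMR	MKRN3	chr15	23807180	23812334	M	MKRN3	11
MAGEL2:TSS-DMR	MAGEL2	chr15	23892574	23893742	M	MAGEL2	6
NDN:TSS-DMR	NDN	chr15	23931451	23932758	M	NDN	8
SNRPN:alt-TSS-DMR	SNRPN:alt-TSS-DMR	chr15	25068738	25069376	M	SNRPN	7
SNRPN:Int1-DMR1	SNRPN:Int1-DMR1	chr15	25093244	25093521	M	SNRPN	4
SNRPN:Int1-DMR2	SNRPN:Int1-DMR2	chr15	25123287	25123688	M	SNRPN	4
SNURF:TSS-DMR	SNURF:TSS-DMR	chr15	25200253	25201732	M	SNRPN;SNURF	6
IGF1R:Int2-DMR	IGF1R	chr15	99408636	99409506	M	IGF1R	7
ZNF597:3' DMR	ZNF597:3' DMR	chr16	3481970	3482078	M		2
ZNF597:TSS-DMR	ZNF597/NAT15	chr16	3493133	3494155	P	ZNF597;NAT15	12
ZNF331:alt-TSS-DMR1	ZNF331:alt-TSS-DMR1	chr19	54040774	54042165	M	ZNF331	12
ZNF331:alt-TSS-DMR2	ZNF331:alt-TSS-DMR2	chr19	54057208	54058085	M	ZNF331	4
PEG3:TSS-DMR	ZIM2/PEG3/MIMT1	chr19	57349204	57352785	M	ZIM2;PEG3;MIMT1	34
MCTS2P:TSS-DMR	HM13	chr20	30134929	30135362	M	HM13;PSIMCT-1	8
NNAT:TSS-DMR	NNAT/BLCAP	chr20	36148604	36150061	M	BLCAP;NNAT	36
L3MBTL1:alt-TSS-DMR	L3MBTL	chr20	42142417	42143502	M	L3MBTL	26
GNAS-NESP:TSS-DMR	GNAS-NESP:TSS-DMR	chr20	57414039	57418015	P	GNASAS;GNAS	21
GNAS-AS1:TSS-DMR	GNAS-AS1:TSS-DMR	chr20	57425979	57427973	M	GNASAS;GNAS	60
GNAS-XL:Ex1-DMR	GNAS-XL:Ex1-DMR	chr20	57429858	57431303	M	GNAS	5
GNAS A/B:TSS-DMR	GNAS A/B:TSS-DMR	chr20	57463265	57465175	M	GNAS	40
WRB:alt-TSS-DMR	WRB	chr21	40757691	40758208	M	WRB	4
SNU13:alt-TSS-DMR	NHP2L1	chr22	42077939	42078723	M	NHP2L1	8
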