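gene_id	group	ZsG	LN1	LN2	LN3
MYH14	common_down	0,4972	0,2182	0,0534	0,0069
RSAD2	common_down	28,3575	20,9164	8,3588	1,1869
SLC28A3	common_down	0,7201	0,3187	0,1672	0,0511
LIPH	common_down	1,4704	0,896	0,5748	0,0333
GJA5	common_down	3,9214	0,7377	0,2756	0,1825
FGD3	common_down	0,8897	0,4476	0,1145	0,0305
VGLL1	common_down	5,1019	2,0341	0,6328	0,0501
RAB17	common_down	1,4872	1,0823	0,6931	0,1211
PLXDC2	common_down	0,5215	0,1356	0,0163	0,001
NMU	common_down	46,4355	34,3583	25,9269	3,6182
SCEL	common_down	2,7007	1,4439	0,4708	0,0844
SCNN1A	common_down	60,9356	35,3696	20,6939	4,5639
UNC5B	common_down	4,2487	3,189	2,3056	0,2049
ANGPTL4	common_down	25,9462	11,4337	7,7907	5,4245
CXADR	common_down	2,0463	1,6011	0,9881	0,5827
DAPK3	continuum	27,8868	23,4451	19,0566	22,2199
STX6	continuum	15,4365	13,654	11,4419	9,341
CHMP6	continuum	20,0775	18,2558	15,6105	18,5514
SRPRB	continuum	33,1723	30,4336	25,6505	29,8296
DIABLO	continuum	30,5994	32,3878	28,2071	33,1907
PIGG	continuum	13,7416	15,1826	12,9338	14,9107
TMED2	continuum	195,729	217,1806	178,7479	213,2503
TRPC4AP	continuum	30,9148	36,4274	30,1783	35,0563
PPARD	continuum	11,7148	13,8269	11,7824	10,1059
SLC8B1	continuum	14,8684	15,557	12,9781	10,6452
ENPP1	common_up	1,1246	1,4489	2,0885	5,2621
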