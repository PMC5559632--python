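site_id	trna	locus_tag	coordinates	phages
attB-1	tRNA-Ala	BCM27_0045	11498-11475	GMA4
attB-2	tRNA-Arg	BCM27_01925	422935-422970	UmaThurman, Twister6, Wizard
attB-3	tRNA-Ser	BCM27_02280	499312-499338	Attis, SoilAssassin, Nymphadora, BatStarr, Kita
attB-4	tRNA-Thr	BCM27_03985	854236-854279	CaptainKirk2, Guacamole, Obliviate, Hedwig, Eyre
attB-5	tRNA-Lys	BCM27_06460	1424071-1424110	Splinter, Vendetta
attB-6	tRNA-Ala	BCM27_07630	1682291-1682387	BaxterFox, Yeezy
attB-7	Intergenic	07635-07640	1683467-1683547	BaxterFox
attB-8	tRNA-Lys	BCM27_10365	2294155-2294191	McGonagall, Jeanie, GMA5, GRU3
attB-9	tRNA-Arg	BCM27_10435	2309527-2309565	Splinter, Vendetta, Bantam
attB-10	Intergenic	17750-17755	3953264-3953239	Howe, Lucky10
attB-11	tRNA-Ala	BCM27_17805	3962309-3962284	Howe, Lucky10
attB-12	tRNA-Gly	BCM27_22500	5080774-5080728	GMA1, GAL1
attB-13	Intergenic	22545-22550	5093356-5093312	GMA1, GAL1
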