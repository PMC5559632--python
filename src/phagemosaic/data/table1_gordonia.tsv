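name	host_species	strain	cluster	length_bp	gc_percent	end_type	accession
JSwag	G. terrae	3612	A15	52726	61.9	3′ 10-base ext.	KX557280
KatherineG	G. terrae	3612	A15	52689	61.9	3′ 10-base ext.	KU998251
Remus	G. terrae	3612	A15	52738	62.0	3′ 10-base ext.	KX557283
Rosalind	G. terrae	3612	A15	52684	61.9	3′ 10-base ext.	KU998250
Soups	G. terrae	3612	A15	52924	61.9	3′ 10-base ext.	KU998249
Strosahl	G. terrae	3612	A15	52738	62.0	3′ 10-base ext.	KX557284
Bachita	G. terrae	3612	CQ1	93843	61.9	3′ 10-base ext.	KU998247
ClubL	G. terrae	3612	CQ1	92618	61.9	3′ 10-base ext.	KU998246
Cucurbita	G. terrae	3612	CQ1	93686	62.0	3′ 10-base ext.	KU557276
Smoothie	G. terrae	3612	CQ1	93139	61.9	3′ 10-base ext.	KU998244
OneUp	G. terrae	3612	CQ2	93577	61.5	3′ 10-base ext.	KU998245
GRU1	G. rubripertincta	Grub38	CR1	65766	65.5	Cir. Perm	JF923797
GTE5	G. terrae	Gter34	CR1	65839	65.1	Cir. Perm	JF923796
GTE8	G. terrae	Gter34	CR2	67617	66.0	?	KR053201
GMA7	G. malaquae	BEN700	CS1	73419	56.6	?	KR063278
GTE7	G. terrae	Ben601	CS1	74431	56.8	?	JN035618
Hotorobo	G. terrae	3612	CS2	76972	58.9	191-bp DTR	KU963245
Monty	G. terrae	3612	CS2	75680	58.9	191-bp DTR	KU998241
Woes	G. terrae	3612	CS3	73752	59.1	184-bp DTR	KU998240
Benczkowski14	G. terrae	3612	CS4	75380	59.5	1,172-bp DTR	KU963262
Demosthenes	G. terrae	3612	CS4	74073	59.3	1,182-bp DTR	KU998242
Katyusha	G. terrae	3612	CS4	75380	59.5	1,172-bp DTR	KU963258
Kvothe	G. terrae	3612	CS4	75462	59.5	1,172-bp DTR	KU998243
Cozz	G. terrae	3612	CT	46600	60.0	3′ 10-base ext.	KU998239
Emalyn	G. terrae	3612	CT	43982	61.2	3′ 10-base ext.	KU963260
GTE2	G. terrae	Gter34	CT	45540	60.3	?	HQ403646
Splinter	G. terrae	3612	CU1	45858	66.1	3′ 12-base ext.	KU998238
Vendetta	G. terrae	3612	CU1	45858	66.1	3′ 12-base ext.	KU998237
Gsput1	G. sputi	G11	CU2	43505	62.8	5′ 16-base ext.	KP790011
Blueberry	G. terrae	3612	CV	54990	67.0	3′ 10-base ext.	KU998236
CaptainKirk2	G. terrae	3612	CV	47898	67.4	3′ 10-base ext.	KX557274
CarolAnn	G. terrae	3612	CV	54167	66.9	3′ 10-base ext.	KX557275
Guacamole	G. terrae	3612	CV	49894	67.2	3′ 10-base ext.	KU963259
Obliviate	G. terrae	3612	CV	49286	67.5	3′ 10-base ext.	KU963254
UmaThurman	G. terrae	3612	CV	50127	67.0	3′ 10-base ext.	KU963251
Utz	G. terrae	3612	CV	49768	67.7	3′ 10-base ext.	KU998248
Jeanie	G. neofelifaecis	NRRL 59395	Cw1	17118	68.6	3′ 10-base ext.	KU998256
McGonagall	G. neofelifaecis	NRRL 59395	Cw1	17119	68.6	3′ 10-base ext.	KU998255
GMA5	G. malaquae	BEN700	Cw2	17562	66.4	?	KR053198
GRU3	G. rubripertincta	Grub38	Cw2	17727	66.5	?	KR053197
Kampe	G. terrae	3612	CX	80649	47.0	249-bp DTR	KU998254
Orchid	G. terrae	3612	CX	80650	47.0	249-bp DTR	KU998253
PatrickStar	G. terrae	3612	CX	80729	47.0	249-bp DTR	KU998252
BatStarr	G. terrae	3612	CZ1	53432	66.6	3′ 10-base ext.	KX557273
Kita	G. terrae	3612	CZ1	50346	66.7	3′ 10-base ext.	KU963257
Nymphadora	G. terrae	3612	CZ1	53431	66.6	3′ 10-base ext.	KU963255
Zirinka	G. terrae	3612	CZ1	52077	66.7	3′ 11-base ext.	KX557287
Attis	G. terrae	3612	CZ2	47881	66.8	3′ 11-base ext.	KU963247
SoilAssassin	G. terrae	3612	CZ2	47880	66.8	3′ 11-base ext.	KU963246
BaxterFox	G. terrae	3612	CZ3	53717	66.5	3′ 10-base ext.	KU963263
Yeezy	G. terrae	3612	CZ3	51884	66.7	3′ 10-base ext.	KU963249
Howe	G. terrae	3612	CZ4	53182	65.6	3′ 11-base ext.	KU252585
Bowser	G. terrae	3612	DB	46570	67.1	3′ 10-base ext.	KU998235
Schwabeltier	G. terrae	3612	DB	46895	67.0	3′ 10-base ext.	KU963252
Hedwig	G. terrae	3612	DB	44536	67.2	3′ 10-base ext.	KX557279
Twister6	G. terrae	3612	DC	57804	67.7	Cir. Perm	KX557286
Wizard	G. terrae	3612	DC	58308	67.9	Cir. Perm	KU998234
GTE6	G. terrae	Gter34	DE	56982	67.8	?	KR053200
Phinally	G. terrae	3612	DE	59265	68.4	Cir. Perm	KU963253
Vivi2	G. terrae	3612	DE	59337	67.1	Cir. Perm	KU963250
Gmala1	Gordonia sp.	G7	DF1	75167	50.8	Cir. Perm	KP790009
GordDuk1	Gordonia sp.	G7	DF1	76276	50.7	Cir. Perm	KP790010
GordTnk2	Gordonia sp.	G7	DF1	75987	50.7	Cir. Perm	KP790008
GMA3	G. malaquae	BEN700	DF2	77779	51.3	Cir. Perm	KR063279
Jumbo	G. terrae	3612	DF3	78302	54.5	370-bp DTR	KX557281
Terapin	G. terrae	3612	Singleton	66611	59.6	Cir. Perm	KX557285
Bantam	G. terrae	3612	Singleton	92580	64.7	3′ 10-base ext.	KX557272
BetterKatz	G. terrae	3612	Singleton	50636	67.1	3′ 10-base ext.	KU963261
BritBrat	G. terrae	3612	Singleton	55524	65.0	3′ 10-base ext.	KU998233
Eyre	G. terrae	3612	Singleton	44929	67.5	3′ 11-base ext.	KX557277
Ghobes	G. terrae	3612	Singleton	45285	65.2	3′ 11-base ext.	KX557278
GMA1	G. malaquae	A448	Singleton	41207	65.7	?	KR053195
GMA2	G. malaquae	A448	Singleton	103424	53.4	?	KR063281
GMA4	G. malaquae	BEN700	Singleton	45537	66.4	?	KR053199
GMA6	G. malaquae	BEN700	Singleton	83324	58.2	?	KR063280
GAL1	G. alkanivorans	DSMZ44369	Singleton	49979	63.5	?	KR053194
Lucky10	G. terrae	3612	Singleton	42979	65.4	3′ 10-base ext.	KU963256
Nyceirae	G. terrae	3612	Singleton	41857	67.5	3′ 9-base ext.	KX557282
Yvonnetastic	G. terrae	3612	Singleton	98136	59.7	3′ 10-base ext.	KU963248
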