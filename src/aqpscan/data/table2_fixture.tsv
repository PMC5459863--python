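gene_id	name	lb_variant	lb_pos	le_variant	le_pos	h2	h5	le1	le2	distance	manual_flag	partial_flag
BnaA01g09720D	BnaANIP1-2a	NPA	114	NPG	233	W	V	A	R	116	0	0
BnaA03g43810D	BnaANIP1-2b	NPA	115	NPG	234	W	V	A	R	116	0	0
BnaA05g09450D	BnaANIP2-1a	NPA	104	NPA	223	V	V	A	R	116	0	0
BnaA05g09470D	BnaANIP2-1b	NPA	104	NPA	223	V	V	A	R	116	0	0
BnaA05g16540D	BnaANIP3-1a	NPA	67	NPA	186	W	I	A	R	116	0	0
BnaA05g16550D	BnaANIP3-1b	NPA	116	NPA	211	W	I	A	R	92	0	0
BnaA08g07040D	BnaANIP3-1c	NPA	75	NPA	194	W	I	A	R	116	0	0
BnaA04g08310D	BnaANIP4-1a	NPA	102	NPA	214	W	V	A	R	109	0	0
BnaA04g27980D	BnaANIP4-1b	NPA	54	NPA	166	W	V	A	R	109	0	0
BnaA02g22030D	BnaANIP5-1a	NPS	134	NPV	245	A	I	G	R	108	0	0
BnaA03g24370D	BnaANIP5-1b	NPS	134	NPV	245	A	I	A	R	108	0	0
BnaA07g16310D	BnaANIP5-1c	NPS	134	NPV	245	A	N	A	R	108	0	0
BnaA02g19440D	BnaANIP6-1a	NPA	139	NPV	250	A	I	A	R	108	0	0
BnaA02g36290D	BnaANIP6-1b	NPA	139	NPV	250	A	I	A	R	108	0	0
BnaA07g35330D	BnaANIP6-1c	NPA	139	NPV	250	A	I	A	R	108	0	0
BnaA05g31180D	BnaANIP7-1a	NPS	104	NPA	216	A	V	G	R	109	0	0
BnaA04g00710D	BnaAPIP1-1a	NPA	53	NPA	174	F	H	T	R	118	0	0
BnaA09g39170D	BnaAPIP1-1b	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaAnng23190D	BnaAPIP1-1c	NPA	34	NPA	155	F	H	T	R	118	0	0
BnaA03g21210D	BnaAPIP1-2a	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaA04g26560D	BnaAPIP1-2b	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaA05g05230D	BnaAPIP1-2c	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaA10g00360D	BnaAPIP1-3a	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaA03g27130D	BnaAPIP1-4a	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaA09g51960D	BnaAPIP1-4b	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaA03g45950D	BnaAPIP1-5a	NPA	115	NPA	236	F	H	T	R	118	0	0
BnaA09g33720D	BnaAPIP2-1a	NPA	107	NPA	228	F	H	T	R	118	0	0
BnaA03g17020D	BnaAPIP2-2a	NPA	105	NPA	226	F	H	T	R	118	0	0
BnaA03g17030D	BnaAPIP2-2b	NPA	105	NPA	226	F	H	T	R	118	0	0
BnaA05g07300D	BnaAPIP2-2c	NPA	105	NPA	251	F	H	T	R	143	0	0
BnaA02g06180D	BnaAPIP2-4a	NPA	80	NPA	201	F	H	T	R	118	0	0
BnaA03g08820D	BnaAPIP2-4b	NPA	82	NPA	203	F	H	T	R	118	0	0
BnaA10g13480D	BnaAPIP2-4c	NPA	82	NPA	203	F	H	T	R	118	0	0
BnaA07g16510D	BnaAPIP2-5a	NPA	106	NPA	227	F	H	T	R	118	0	0
BnaA09g34600D	BnaAPIP2-5b	NPA	106	NPA	227	F	H	T	R	118	0	0
BnaA03g18300D	BnaAPIP2-6a	NPA	105	NPA	226	F	H	T	R	118	0	0
BnaA08g10860D	BnaAPIP2-7a	NPA	101	NPA	222	F	H	T	R	118	0	0
BnaAnng11630D	BnaAPIP2-7b	NPA	101	NPA	222	F	H	T	R	118	0	0
BnaA07g17050D	BnaASIP2-1a	NPL	69	NPA	180	S	H	G	A	108	0	0
BnaA09g36250D	BnaASIP2-1b	NPV	69	NPA	177	S	H	G	A	105	0	0
BnaAnng22640D	BnaATIP1-1a	NPA	55	NPA	169	H	I	A	V	111	0	0
BnaAnng24130D	BnaATIP1-1b	NPA	55	NPA	169	H	I	A	V	111	0	0
BnaA02g28130D	BnaATIP1-2a	NPA	86	NPA	200	H	I	A	V	111	0	0
BnaA06g32840D	BnaATIP1-2b	NPA	86	NPA	200	H	I	A	V	111	0	0
BnaA09g51590D	BnaATIP1-3a	NPA	85	NPA	199	H	I	A	V	111	0	0
BnaA01g28120D	BnaATIP2-1a	NPA	83	NPA	197	H	I	G	R	111	0	0
BnaA03g34110D	BnaATIP2-1b	NPA	83	NPA	197	H	I	G	R	111	0	0
BnaA05g23460D	BnaATIP2-1c	NPA	83	NPA	197	H	I	G	R	111	0	0
BnaA01g35340D	BnaATIP2-2a	NPA	83	NPA	197	H	I	G	R	111	0	0
BnaA02g25440D	BnaATIP2-3a	NPA	43	NPA	157	H	I	G	R	111	0	0
BnaA06g40020D	BnaATIP2-3b	NPA	83	NPA	197	H	I	G	R	111	0	0
BnaA02g16380D	BnaATIP3-1a	NPA	93	NPA	207	H	I	A	R	111	0	0
BnaA07g22790D	BnaATIP3-1b	NPA	93	NPA	207	H	I	A	R	111	0	0
BnaA07g30640D	BnaATIP3-1c	NPA	93	NPA	207	H	I	A	R	111	0	0
BnaA06g12030D	BnaATIP3-2a	NPA	93	NPA	207	H	M	A	R	111	0	0
BnaA09g44820D	BnaATIP3-2b	NPA	93	NPA	207	H	M	A	R	111	0	0
BnaA06g17390D	BnaATIP5-1a	NPA	87	NPA	200	N	V	G	C	110	0	0
BnaC01g11410D	BnaCNIP1-2a	NPA	114	NPG	233	W	V	A	R	116	0	0
BnaC07g35550D	BnaCNIP1-2b	NPA	115	NPG	234	W	V	A	R	116	0	0
BnaC04g10820D	BnaCNIP2-1a	NPA	104	NPA	223	V	V	A	R	116	0	0
BnaC04g10830D	BnaCNIP2-1b	NPA	104	NPA	223	V	V	A	R	116	0	0
BnaC05g29140D	BnaCNIP3-1a	NPA	99	NPA	218	W	I	A	R	116	0	0
BnaC05g29150D	BnaCNIP3-1b	NPA	116	NPA	211	W	I	A	R	92	0	0
BnaC08g07910D	BnaCNIP3-1c	NPA	102	NPA	232	W	I	A	R	127	0	0
BnaC04g30520D	BnaCNIP4-1a	NPA	102	NPA	214	W	V	A	R	109	0	0
BnaC04g34450D	BnaCNIP4-1b	NPA	102	NPA	214	W	V	A	R	109	0	0
BnaC06g42210D	BnaCNIP4-2a	NPA	107	NPA	219	W	V	A	R	109	0	0
BnaC02g29210D	BnaCNIP5-1a	NPS	134	NPV	245	A	I	G	R	108	0	0
BnaC03g28980D	BnaCNIP5-1b	NPS	134	NPV	245	A	I	A	R	108	0	0
BnaC06g40240D	BnaCNIP6-1a	NPA	139	NPV	250	A	I	A	R	108	0	0
BnaC05g45720D	BnaCNIP7-1a	NPS	104	NPA	216	A	V	G	R	109	0	0
BnaC08g31360D	BnaCPIP1-1a	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaC03g25510D	BnaCPIP1-2a	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaC04g04640D	BnaCPIP1-2b	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaC04g50590D	BnaCPIP1-2c	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaC05g00440D	BnaCPIP1-3a	NPA	152	NPA	273	F	H	T	R	118	0	0
BnaCnng08780D	BnaCPIP1-3b	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaC03g32130D	BnaCPIP1-4a	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaCnng02360D	BnaCPIP1-4b	NPA	114	NPA	235	F	H	T	R	118	0	0
BnaC07g38190D	BnaCPIP1-5a	NPA	115	NPA	236	F	H	T	R	118	0	0
BnaC06g14590D	BnaCPIP2-1a	NPA	107	NPA	228	F	H	T	R	118	0	0
BnaCnng31040D	BnaCPIP2-1b	NPA	107	NPA	228	F	H	T	R	118	0	0
BnaC04g08090D	BnaCPIP2-2a	NPA	105	NPA	226	F	H	T	R	118	0	0
BnaC04g08100D	BnaCPIP2-2b	NPA	105	NPA	226	F	H	T	R	118	0	0
BnaC03g11160D	BnaCPIP2-4a	NPA	82	NPA	203	F	H	T	R	118	0	0
BnaC09g53920D	BnaCPIP2-4b	NPA	82	NPA	203	F	H	T	R	118	0	0
BnaC06g15450D	BnaCPIP2-5a	NPA	106	NPA	227	F	H	T	R	118	0	0
BnaC08g25570D	BnaCPIP2-5b	NPA	106	NPA	227	F	H	T	R	118	0	0
BnaC03g21800D	BnaCPIP2-6a	NPA	105	NPA	226	F	H	T	R	118	0	0
BnaC01g03410D	BnaCPIP2-7a	NPA	101	NPA	222	F	H	T	R	118	0	0
BnaC03g65520D	BnaCPIP2-7b	NPA	101	NPA	222	F	H	T	R	118	0	0
BnaC07g45370D	BnaCPIP2-7c	NPA	74	NPA	195	F	H	T	R	118	0	0
BnaC03g54990D	BnaCSIP2-1a	NPL	69	NPA	180	S	H	G	A	108	0	0
BnaC04g24760D	BnaCSIP2-1b	NPL	69	NPA	180	S	H	G	A	108	0	0
BnaCnng20470D	BnaCSIP2-1c	NPL	69	NPA	180	S	H	G	A	108	0	0
BnaCnng24720D	BnaCTIP1-1a	NPA	85	NPA	199	H	I	A	V	111	0	0
BnaC02g36210D	BnaCTIP1-2a	NPA	86	NPA	200	H	I	A	V	111	0	0
BnaC07g23630D	BnaCTIP1-2b	NPA	86	NPA	200	H	I	A	V	111	0	0
BnaCnng01570D	BnaCTIP1-3a	NPA	85	NPA	199	H	I	A	V	111	0	0
BnaC01g44580D	BnaCTIP2-1a	NPA	83	NPA	197	H	I	G	R	111	0	0
BnaC03g39560D	BnaCTIP2-1b	NPA	109	NPA	223	H	I	G	R	111	0	0
BnaC05g37160D	BnaCTIP2-1c	NPA	83	NPA	197	H	I	G	R	111	0	0
BnaC06g05270D	BnaCTIP2-1d	NPA	82	NPA	196	H	I	G	R	111	0	0
BnaC01g41690D	BnaCTIP2-2a	NPA	83	NPA	197	H	I	G	R	111	0	0
BnaC02g46870D	BnaCTIP2-3a	NPA	83	NPA	197	H	I	G	R	111	0	0
BnaC07g20220D	BnaCTIP2-3b	NPA	83	NPA	197	H	I	G	R	111	0	0
BnaC06g23750D	BnaCTIP3-1a	NPA	93	NPA	207	H	I	A	R	111	0	0
BnaC06g34100D	BnaCTIP3-1b	NPA	93	NPA	207	H	I	A	R	111	0	0
BnaCnng50290D	BnaCTIP3-1c	NPA	93	NPA	207	H	I	A	R	111	0	0
BnaC05g13770D	BnaCTIP3-2a	NPA	93	NPA	207	H	M	A	R	111	0	0
BnaC08g37510D	BnaCTIP3-2b	NPA	93	NPA	207	H	M	A	R	111	0	0
BnaC04g38040D	BnaCTIP4-1a	NPA	79	NPA	193	A	I	A	R	111	0	0
BnaCnng15220D	BnaCTIP5-1a	NPA	87	NPA	200	N	V	G	C	110	0	0
BnaA01g33700D	BnaASIP1-1a	NPT	69	NPA	184	T	V	P	I	112	1	0
BnaA05g37440D	BnaASIP1-1b	NPT	69	NPA	184	T	V	P	I	112	1	0
BnaA10g16540D	BnaASIP1-2a	NPC	72	NPA	188	V	F	P	I	113	1	0
BnaCnng65250D	BnaCNIP4-1c	NP	107			-	-	-	-		1	1
BnaC01g40230D	BnaCSIP1-1a	NPT	71	NPA	186	T	V	P	I	112	1	0
BnaC05g47470D	BnaCSIP1-1b	NPT	69	NPA	184	T	V	P	I	112	1	0
BnaC09g54320D	BnaCSIP1-2a	NPC	72	NPA	188	V	F	P	I	113	1	0
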