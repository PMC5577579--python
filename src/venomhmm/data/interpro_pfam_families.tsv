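interpro_combo	pfam_ids	families	total_count
IPR000737;IPR011052	PF00299	Protease inhibitor I7 (squash-type serine protease inhibitor) family	1
IPR002110;IPR020683	PF00023;PF12796	Latrotoxin superfamily	4
IPR002110;IPR020683;IPR013829	PF00023;PF12796;PF13606	Latrotoxin superfamily	3
IPR002223	PF00014	Venom Kunitz-type family	39
IPR002223;IPR020901	PF00014	Venom Kunitz-type family	8
IPR003614			1
IPR004169		Plectoxin superfamily=16|Spider toxin CSTX superfamily=1|No class=1	18
IPR004214	PF02950	Spider toxin Tx2 family=1|Huwentoxin-1 family=1	2
IPR005853;IPR013605	PF08396	Omega-agatoxin superfamily	13
IPR007733;IPR027300	PF05039	Spider agouti family	1
IPR008017	PF05353	Delta-atracotoxin family	7
IPR008197		Spider wap-1 family=17|Spider wap-2 family=4	21
IPR009243		Beta/delta-agatoxin family	12
IPR009243;IPR004169		Beta/delta-agatoxin family	2
IPR009415	PF06357	Shiva superfamily	13
IPR009415;IPR018071	PF06357	Shiva superfamily=14|No class=1	15
IPR011142		Spider toxin CSTX superfamily	6
IPR011696	PF07740	Huwentoxin-1 family	114
IPR011696;IPR013140	PF07740	Huwentoxin-1 family	119
IPR011696;IPR016191	PF07740	Huwentoxin-1 family	4
IPR012499	PF07945	Shiva superfamily	7
IPR012522	PF08025	Oxyopinin-2 family	4
IPR012625	PF08089	Huwentoxin-2 family	79
IPR012625;IPR012627	PF08092	Magi-1 superfamily	1
IPR012626	PF08091	Insecticidal toxin ABC family	5
IPR012627	PF08092	Magi-1 superfamily	82
IPR012628	PF08093	Magi-5 family	3
IPR012633	PF08115	Spider toxin SFI family	10
IPR012634	PF08116	Spider neurotoxin 21C2 family	4
IPR013139;IPR012628	PF08093	Omega-atracotoxin type 2 family	5
IPR013605	PF08396	Omega-agatoxin superfamily	14
IPR016328;IPR009243		Beta/delta-agatoxin family	13
IPR017946		Arthropod phospholipase D family	199
IPR017946;IPR000909		Arthropod phospholipase D family	2
IPR018802	PF10279	Latarcin superfamily	11
IPR019553	PF10530	Plectoxin superfamily=1|Spider toxin CSTX superfamily=6|U6-lycotoxin family=10|U7-lycotoxin family=11|U8-lycotoxin family=28|U11-lycotoxin family=6	62
IPR019553;IPR004169	PF10530	U10-lycotoxin family	5
IPR019553;IPR011142	PF10530	Spider toxin CSTX superfamily	104
IPR020683		Latrotoxin superfamily	1
IPR020683;IPR007094		Latrotoxin superfamily	1
IPR023569	PF06607	AVIT (prokineticin) family	9
IPR024079;IPR001506;IPR006026	PF01400	Peptidase M12A family	1
IPR027300		Plectoxin superfamily=5|No class=1	6
IPR027300;IPR004169		No class	1
IPR034035;IPR024079;IPR001506;IPR006026	PF01400	Peptidase M12A family	4
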