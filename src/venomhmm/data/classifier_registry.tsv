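toxin_type	name_range	legacy_annotation	interpro_ids	pfam_ids
SC	SC_01_00	Cytoinsectotoxin family
SC	SC_02_00	Oxyopinin family	IPR012522	PF08025
SC	SC_03_00 to SC_03_07	Latarcin superfamily	IPR018802	PF10279
SC	SC_04_01 to SC_04_10	Cupiennin family; CsTx-16
SC	SC_05_00	Bradykinin-related peptide family
SN	SN_01_00	U2-agatoxin family
SN	SN_02_00 to SN_02_09	Plectoxin superfamily; CsTx-19; CsTx-28,34,36	IPR004169
SN	SN_03_01 to SN_03_06	Spider toxin Tx2 family	IPR004214	PF02950
SN	SN_04_00 to SN_04_04	Omega-agatoxin superfamily	IPR005853;IPR013605	PF08396
SN	SN_05_00 to SN_05_06	Spider agouti family	IPR007733;IPR027300	PF05039
SN	SN_06_00	Delta-atracotoxin family	IPR008017	PF05353
SN	SN_07_00 to SN_07_04	Beta/delta agatoxin family	IPR009243
SN	SN_08_01 to SN_08_02	Shiva superfamily, Omega-toxin family	IPR009415;IPR018071	PF06357
SN	SN_09_00	Spider toxin Tx3-6 family
SN	SN_10_00 to SN_10_67	Huwentoxin-1 family	IPR011696	PF07740
SN	SN_11_00	Shiva superfamily, Kappa toxin family	IPR012499	PF07945
SN	SN_12_01 to SN_12_08	Huwentoxin-2 family	IPR012625	PF08089
SN	SN_13_00 to SN_13_03	Insecticidal toxin ABC family	IPR012626	PF08091
SN	SN_14_00 to SN_14_09	Magi-1 superfamily	IPR012627	PF08092
SN	SN_15_01 to SN_15_02	Magi-5 family	IPR012628	PF08093
SN	SN_16_00	Spider toxin SFI family	IPR012633	PF08115
SN	SN_17_00	Spider neurotoxin 21C2 family	IPR012634	PF08116
SN	SN_18_00	AVIT (prokineticin) family	IPR023569	PF06607
SN	SN_19_00 to SN_19_12	Spider toxin CsTx superfamily	IPR019553;IPR011142	PF10530
SN	SN_20_00	CsTx-20
SN	SN_21_00	Aptotoxin_family
SN	SN_22_00	Helical arthropod neuropeptide derived (HAND) family
SN	SN_23_00	Double-knot toxin subfamily
SN	SN_24_00	OAIP 4 subfamily
SN	SN_25_00	HWTX-LSTX family
SN	SN_26_00	Insecticidal toxin DTX family
SN	SN_27_00	JZTX-72 family
SN	SN_28_00	Litx family
SN	SN_29_00	Omega lycotoxin family
SN	SN_30_00	Phrixotoxin family
SN	SN_31_00	U12-lycotoxin family
SN	SN_32_00 to SN_32_02	MIT-like AcTx family; CsTx-21; CsTx-22	IPR020202	PF17556
SN	SN_33_00	CsTx-26
SN	SN_34_00	CsTx-29
SN	SN_35_00	CsTx-35
SN	SN_36_00	Huwentoxin type 10
SN	SN_37_00	CsTx-37
SN	SN_38_00	CsTx-38
SN	SN_39_00	Spider LiTx3 related peptide family
SN	SN_40_00	Spiderine
VP	VP_01_00	Protease inhibitor I7 (squash type serine protease inhibitor) family	IPR000737;IPR011052	PF00299
VP	VP_02_00	Peptidase M12A family	IPR024079;IPR001506	PF01400
VP	VP_03_01 to VP_03_02	Arthropod phospholipase D family	IPR017946
VP	VP_04_00	Venom metalloproteinase (M12B) family
VP	VP_05_00	Hyaluronidase	IPR018155
VP	VP_06_00	Arthropod Phospholipase A2	IPR001211
VP	VP_07_00	Angiotensin-converting Enzyme	IPR033591
VP	VP_08_00	Peptidylglycine alpha-amidating monooxygenase	IPR000720
VP	VP_09_00	Signal peptidase	IPR001733
VP	VP_10_00	Venom serine protease	IPR001314
VP	VP_11_01 to VP_11_02	Spider WAP family	IPR008197
VP	VP_12_01 to VP_12_04	Venom Kunitz-type family	IPR002223;IPR020901	PF00014
VP	VP_13_01 to VP_13_02	Cysteine-rich secretory protein	IPR014044;IPR002413
VP	VP_14_00	Thyroglobulin-like protein	IPR000716
VP	VP_15_00	Leucine rich peptide	IPR032675
VP	VP_16_00	Protein disulfide-isomerase	IPR005792
VP	VP_17_00	Tachylectin 5A	IPR002181
VP	VP_18_00	Cystatin	IPR027214
VP	VP_19_01 to VP_19_04	Latrotoxin superfamily	IPR002110;IPR020683	PF00023
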