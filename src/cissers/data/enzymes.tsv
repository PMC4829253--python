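# Starter restriction-enzyme catalogue (REBASE-derived names and IUPAC
# recognition sites). Caret marks the top-strand cleavage point where it is
# standard knowledge; site-only rows fall back to cutting at the site start
# during digestion (counting is unaffected).
# name	site[_with_optional_caret]	[cut_offset]
AatII	GACGT^C
AccI	GTMKAC
AccIII	T^CCGGA
AclI	AA^CGTT
AcsI	R^AATTY
AcuI	CTGAAG	16
AflII	C^TTAAG
AflIII	A^CRYGT
ApaI	GGGCC^C
ApaLI	G^TGCAC
AvaI	C^YCGRG
BaeGI	GKGCM^C
BalI	TGG^CCA
BamHI	G^GATCC
BanI	G^GYRCC
BanII	GRGCY^C
Bbv12I	GWGCW^C
BclI	T^GATCA
BfuAI	ACCTGC	4
BglII	A^GATCT
BlnI	C^CTAGG
BmuI	ACTGGG	5
BpmI	CTGGAG	16
BpuEI	CTTGAG	16
BsaWI	W^CCGGW
Bse3DI	GCAATG	2
BseRI	GAGGAG	10
BsgI	GTGCAG	16
BsiWI	C^GTACG
Bso31I	GGTCTC	1
Bsp1286I	GDGCH^C
Bsp1407I	T^GTACA
BspHI	T^CATGA
BspLI	GGN^NCC
BssECI	C^CNNGG
BssHII	G^CGCGC
BsuI	GTATCC	5
Bst1107I	GTA^TAC
Bst6I	CTCTTC	1
BstBAI	YAC^GTR
BstC8I	GCN^NGC
BstDSI	C^CRYGG
BstMCI	CGRY^CG
BstSFI	C^TRYAG
BstV2I	GAAGAC	2
BstX2I	R^GATCY
BtgZI	GCGATG	10
BtsI	GCAGTG	2
Cac8I	GCN^NGC
Cfr10I	R^CCGGY
ClaI	AT^CGAT
DraI	TTT^AAA
EaeI	Y^GGCCR
EciI	GGCGGA	11
Eco47III	AGC^GCT
Eco52I	C^GGCCG
Eco57MI	CTGRAG	16
EcoRI	G^AATTC
EcoRV	GAT^ATC
Esp3I	CGTCTC	1
FspI	TGC^GCA
HaeII	RGCGC^Y
Hin1I	GR^CGYC
HincII	GTY^RAC
HindIII	A^AGCTT
HpaI	GTT^AAC
Hpy166II	GTN^NAC
Hpy188III	TC^NNGA
KpnI	GGTAC^C
MluI	A^CGCGT
MmeI	TCCRAC	20
MspA1I	CMG^CKG
MunI	C^AATTG
NaeI	GCC^GGC
NarI	GG^CGCC
NcoI	C^CATGG
NdeI	CA^TATG
NheI	G^CTAGC
NmeAIII	GCCGAG	21
NruI	TCG^CGA
NsiI	ATGCA^T
NspI	RCATG^Y
NspV	TT^CGAA
PciI	A^CATGT
PinAI	A^CCGGT
PsiI	TTA^TAA
PspCI	CAC^GTG
PstI	CTGCA^G
PvuI	CGAT^CG
PvuII	CAG^CTG
SacI	GAGCT^C
SacII	CCGC^GG
SalI	G^TCGAC
ScaI	AGT^ACT
SmaI	CCC^GGG
SmlI	C^TYRAG
SnaBI	TAC^GTA
SpeI	A^CTAGT
SphI	GCATG^C
SspI	AAT^ATT
StuI	AGG^CCT
StyI	C^CWWGG
TaqI	T^CGA
TatI	W^GTACW
TsoI	TARCCA	11
VspI	AT^TAAT
XbaI	T^CTAGA
XhoI	C^TCGAG
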