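table	ko	clamp	state	TNF	IL6	TGFB1	JUN	FOS	JUND	NFKBIA	DAXX	ILK	NFKB1	MAP2K1	MAPK1	MAPK14
WT			ss1	0	0	0	0	0	0	0	0	0	0	0	0	0
WT			ss2	0	1	0	1	1	1	1	0	1	1	1	1	1
WT			ss3	0	1	1	1	1	1	1	1	1	1	1	1	1
WT			ss4	1	1	0	1	1	1	1	0	1	1	1	1	1
WT			ss5	1	1	1	1	1	1	1	1	1	1	1	1	1
MAPK1_MAPK14_KO	MAPK1=0,MAPK14=0	TNF=0	ss1	0	0	0	0	0	0	0	0	0	0	0	0	0
MAPK1_MAPK14_KO	MAPK1=0,MAPK14=0	TNF=0	ss2	0	1	0	1	1	1	1	0	1	1	1	0	0
MAPK1_MAPK14_KO	MAPK1=0,MAPK14=0	TNF=0	ss3	0	1	1	1	1	1	1	1	1	1	1	0	0
DAXX_ILK_MAP2K1_KO	DAXX=0,ILK=0,MAP2K1=0	TNF=0	ss1	0	0	0	0	0	0	0	0	0	0	0	0	0
DAXX_ILK_MAP2K1_KO	DAXX=0,ILK=0,MAP2K1=0	TNF=0	ss2	0	1	0	0	0	0	1	0	0	1	0	0	0
DAXX_ILK_MAP2K1_KO	DAXX=0,ILK=0,MAP2K1=0	TNF=0	ss3	0	1	1	1	1	1	1	0	0	1	0	0	1
DAXX_NFKB1_KO	DAXX=0,NFKB1=0	TNF=0	ss1	0	0	0	0	0	0	0	0	0	0	0	0	0
DAXX_NFKB1_KO	DAXX=0,NFKB1=0	TNF=0	ss2	0	1	0	1	1	1	1	0	1	0	1	1	1
DAXX_NFKB1_KO	DAXX=0,NFKB1=0	TNF=0	ss3	0	1	1	1	1	1	1	0	1	0	1	1	1
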