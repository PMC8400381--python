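DAXX	ACTIVATION	NFKB1
IL6	ACTIVATION	IL6
IL6	ACTIVATION	ILK
IL6	ACTIVATION	NFKB1
IL6	ACTIVATION	TGFB1
ILK	ACTIVATION	FOS
ILK	ACTIVATION	JUN
ILK	ACTIVATION	JUND
ILK	ACTIVATION	MAP2K1
ILK	ACTIVATION	NFKBIA
MAP2K1	ACTIVATION	MAPK1
MAP2K1	ACTIVATION	MAPK14
MAPK14	ACTIVATION	FOS
MAPK14	ACTIVATION	JUN
MAPK14	ACTIVATION	JUND
MAPK14	ACTIVATION	NFKB1
MAPK14	ACTIVATION	NFKBIA
NFKB1	ACTIVATION	IL6
NFKB1	ACTIVATION	NFKBIA
TGFB1	ACTIVATION	DAXX
TGFB1	ACTIVATION	FOS
TGFB1	ACTIVATION	JUN
TGFB1	ACTIVATION	JUND
TGFB1	ACTIVATION	MAPK14
TGFB1	ACTIVATION	TGFB1
TNF	ACTIVATION	IL6
TNF	ACTIVATION	MAPK14
TNF	ACTIVATION	NFKB1
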