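TNF, TNF
IL6, IL6 | TNF | NFKB1
TGFB1, TGFB1 & IL6
JUN, MAPK14 | ILK | TGFB1
FOS, MAPK14 | ILK | TGFB1
JUND, MAPK14 | ILK | TGFB1
NFKBIA, NFKB1 | ILK | MAPK14
DAXX, TGFB1
ILK, IL6
NFKB1, IL6 | TNF | MAPK14 | DAXX
MAP2K1, ILK
MAPK1, MAP2K1
MAPK14, MAP2K1 | TGFB1 | TNF
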