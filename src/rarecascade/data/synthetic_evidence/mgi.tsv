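gene	category
FBLN5	cardiovascular
PCSK5	cardiovascular
PCSK5	metabolism
FAM161A	metabolism
KLHL8	cardiovascular
KLHL8	metabolism
RALY	metabolism
TOP2A	cardiovascular
CHST14	cardiovascular
C2orf73	metabolism
LDLR	liver
LDLR	metabolism
QTRT1	metabolism
GBA	liver
ADGRA2	cardiovascular
SPRYD3	cardiovascular
RASGEF1B	metabolism
TOE1	liver
APBB2	cardiovascular
LTF	endocrine/exocrine
TP53BP1	metabolism
FGB	cardiovascular
HPSE2	endocrine/exocrine
MNS1	cardiovascular
PM20D1	adipose
SLK	cardiovascular
HLA-E	cardiovascular
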