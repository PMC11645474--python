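gene	tc_p	tg_p	ldl_p	hdl_p
QTRT1	3.65e-16	NA	2.18e-19	NA
PPARD	1.61e-7	NA	5.65e-6	NA
CABP1	NA	NA	2.87e-5	NA
LDLR	5.43e-202	NA	3.85e-262	6.32e-5
HLA-E	5.15e-7	1.35e-9	NA	4.01e-5
KLHL8	NA	4.2e-6	NA	NA
PCSK5	NA	NA	NA	7.7e-7
C2orf73	2.9e-5	NA	NA	NA
ZNF101	NA	6.1e-8	NA	NA
SORT1	1.0e-30	NA	1.0e-40	NA
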