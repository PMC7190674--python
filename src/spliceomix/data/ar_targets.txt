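KLK3
KLK2
TMPRSS2
ELL2
CENPN
GNMT
MAF
NNMT
MED28
EAF2
MPHOSPH9
PTGER4
HERC3
ZBTB10
ACSL3
FKBP5
C1orf116
NKX3-1
ABCC4
PMEPA1
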