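rbp_name	motif
RBP01	TGCATG
RBP02	GGGGAG
RBP03	UCUUC
RBP04	ACWAC
RBP05	GTRAGT
RBP06	YGCY
RBP07	AGGUAA
RBP08	CAKCAK
RBP09	TTTTCC
RBP10	MGMG
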