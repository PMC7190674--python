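MFAP1
SF3A2
GPATCH1
XAB2
CELF2
SF3A1
SAP18
SRP54
PPIL2
SF1
MATR3
ELAVL4
CDK10
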