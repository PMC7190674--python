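SRSF1
KHDRBS3
ESRP1
HNRNPH1
U2SURP
LSM5
TIA1
CHERP
HNRNPR
HNRNPH2
HNRNPH3
KHDRBS1
HNRNPAB
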