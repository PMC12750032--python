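# common monoatomic / small ionic components
NA
K
MG
CA
ZN
MN
FE
FE2
CU
CO
NI
CD
CL
BR
IOD
F
SO4
PO4
NO3
NH4
CS
LI
SR
BA
AL
HG
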