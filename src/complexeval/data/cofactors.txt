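# common cofactors and cofactor-like components
ATP
ADP
AMP
GTP
GDP
NAD
NAI
NAP
NDP
FAD
FMN
SAM
SAH
COA
ACO
HEM
HEC
PLP
TPP
BTN
F43
H4B
MQ7
UQ1
PQQ
B12
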