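# buffer molecules, cryoprotectants and precipitants
GOL
EDO
PEG
PG4
PGE
1PE
MPD
DMS
ACT
ACY
FMT
EOH
IPA
TRS
EPE
MES
BME
DTT
IMD
CIT
TLA
MLI
SCN
AZI
BCT
CAC
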