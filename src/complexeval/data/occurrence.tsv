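# example occurrence table: component_id	PDB entries containing it
# (illustrative counts; supply a full table for production use)
STI	45
LIG	3
VIA	12
CFF	60
BEZ	250
GLC	4500
NAG	16000
ATP	3900
HEM	5200
GOL	21000
SO4	32000
MG	41000
ZN	23000
PRP	80
TES	90
EST	70
RET	95
CLR	150
MYR	300
PLM	700
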