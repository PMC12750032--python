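# component_id	parent (standard component, or: unknown / non-linking / orphan)
MSE	MET
SEP	SER
TPO	THR
PTR	TYR
CSO	CYS
CME	CYS
OCS	CYS
KCX	LYS
MLY	LYS
ALY	LYS
M3L	LYS
HYP	PRO
FME	MET
MLE	LEU
AIB	ALA
DAL	ALA
PCA	GLN
SAC	SER
CSD	CYS
HIC	HIS
NEP	HIS
PSU	U
5MU	U
H2U	U
4SU	U
OMC	C
5MC	C
OMG	G
7MG	G
2MG	G
M2G	G
1MA	A
6MA	A
5CM	DC
6OG	DG
8OG	DG
UNK	unknown
N	unknown
DN	unknown
ACE	non-linking
NH2	non-linking
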