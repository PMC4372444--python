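# Random-coil chemical shift reference (ppm), Wishart-style values
# (Wishart et al., J. Biomol. NMR 5, 67-81, 1995; DSS-referenced).
# Gly has no CB entry by construction.
residue_name,atom,shift_ppm
ALA,CA,52.5
ALA,CB,19.1
ALA,CO,177.8
ALA,HA,4.32
ARG,CA,56.0
ARG,CB,30.9
ARG,CO,176.3
ARG,HA,4.34
ASN,CA,53.1
ASN,CB,38.9
ASN,CO,175.2
ASN,HA,4.74
ASP,CA,54.2
ASP,CB,41.1
ASP,CO,176.3
ASP,HA,4.64
CYS,CA,58.2
CYS,CB,28.0
CYS,CO,174.6
CYS,HA,4.55
GLN,CA,55.7
GLN,CB,29.4
GLN,CO,176.0
GLN,HA,4.34
GLU,CA,56.6
GLU,CB,29.9
GLU,CO,176.6
GLU,HA,4.35
GLY,CA,45.1
GLY,CO,174.9
GLY,HA,3.96
HIS,CA,55.0
HIS,CB,29.0
HIS,CO,174.1
HIS,HA,4.73
ILE,CA,61.1
ILE,CB,38.8
ILE,CO,176.4
ILE,HA,4.17
LEU,CA,55.1
LEU,CB,42.4
LEU,CO,177.6
LEU,HA,4.34
LYS,CA,56.2
LYS,CB,33.1
LYS,CO,176.6
LYS,HA,4.32
MET,CA,55.4
MET,CB,32.9
MET,CO,176.3
MET,HA,4.48
PHE,CA,57.7
PHE,CB,39.6
PHE,CO,175.8
PHE,HA,4.62
PRO,CA,63.3
PRO,CB,32.1
PRO,CO,177.3
PRO,HA,4.42
SER,CA,58.3
SER,CB,63.8
SER,CO,174.6
SER,HA,4.47
THR,CA,61.8
THR,CB,69.8
THR,CO,174.7
THR,HA,4.35
TRP,CA,57.5
TRP,CB,29.6
TRP,CO,176.1
TRP,HA,4.66
TYR,CA,57.9
TYR,CB,38.8
TYR,CO,175.9
TYR,HA,4.55
VAL,CA,62.2
VAL,CB,32.9
VAL,CO,176.3
VAL,HA,4.12
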