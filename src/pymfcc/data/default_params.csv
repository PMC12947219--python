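residue,atom,charge,epsilon,rmin_half
GLY,N,-0.47,0.20,1.85
GLY,H,0.31,0.046,0.2245
GLY,CA,-0.02,0.055,2.175
GLY,HA2,0.09,0.022,1.32
GLY,HA3,0.09,0.022,1.32
GLY,C,0.51,0.11,2.00
GLY,O,-0.51,0.12,1.70
ALA,N,-0.47,0.20,1.85
ALA,H,0.31,0.046,0.2245
ALA,CA,0.07,0.055,2.175
ALA,HA,0.09,0.022,1.32
ALA,C,0.51,0.11,2.00
ALA,O,-0.51,0.12,1.70
ALA,CB,-0.27,0.078,2.04
ALA,HB1,0.09,0.024,1.34
ALA,HB2,0.09,0.024,1.34
ALA,HB3,0.09,0.024,1.34
SER,N,-0.47,0.20,1.85
SER,H,0.31,0.046,0.2245
SER,CA,0.07,0.055,2.175
SER,HA,0.09,0.022,1.32
SER,C,0.51,0.11,2.00
SER,O,-0.51,0.12,1.70
SER,CB,0.05,0.055,2.175
SER,HB2,0.09,0.022,1.32
SER,HB3,0.09,0.022,1.32
SER,OG,-0.66,0.1521,1.77
SER,HG,0.43,0.046,0.2245
CYS,N,-0.47,0.20,1.85
CYS,H,0.31,0.046,0.2245
CYS,CA,0.07,0.055,2.175
CYS,HA,0.09,0.022,1.32
CYS,C,0.51,0.11,2.00
CYS,O,-0.51,0.12,1.70
CYS,CB,-0.11,0.055,2.175
CYS,HB2,0.09,0.022,1.32
CYS,HB3,0.09,0.022,1.32
CYS,SG,-0.23,0.45,2.00
CYS,HG,0.16,0.10,0.45
VAL,N,-0.47,0.20,1.85
VAL,H,0.31,0.046,0.2245
VAL,CA,0.07,0.055,2.175
VAL,HA,0.09,0.022,1.32
VAL,C,0.51,0.11,2.00
VAL,O,-0.51,0.12,1.70
VAL,CB,-0.09,0.032,2.00
VAL,HB,0.09,0.022,1.32
VAL,CG1,-0.27,0.078,2.04
VAL,HG11,0.09,0.024,1.34
VAL,HG12,0.09,0.024,1.34
VAL,HG13,0.09,0.024,1.34
VAL,CG2,-0.27,0.078,2.04
VAL,HG21,0.09,0.024,1.34
VAL,HG22,0.09,0.024,1.34
VAL,HG23,0.09,0.024,1.34
ASP,N,-0.47,0.20,1.85
ASP,H,0.31,0.046,0.2245
ASP,CA,0.07,0.055,2.175
ASP,HA,0.09,0.022,1.32
ASP,C,0.51,0.11,2.00
ASP,O,-0.51,0.12,1.70
ASP,CB,-0.28,0.055,2.175
ASP,HB2,0.09,0.022,1.32
ASP,HB3,0.09,0.022,1.32
ASP,CG,0.62,0.07,2.00
ASP,OD1,-0.76,0.12,1.70
ASP,OD2,-0.76,0.12,1.70
GLU,N,-0.47,0.20,1.85
GLU,H,0.31,0.046,0.2245
GLU,CA,0.07,0.055,2.175
GLU,HA,0.09,0.022,1.32
GLU,C,0.51,0.11,2.00
GLU,O,-0.51,0.12,1.70
GLU,CB,-0.18,0.055,2.175
GLU,HB2,0.09,0.022,1.32
GLU,HB3,0.09,0.022,1.32
GLU,CG,-0.28,0.055,2.175
GLU,HG2,0.09,0.022,1.32
GLU,HG3,0.09,0.022,1.32
GLU,CD,0.62,0.07,2.00
GLU,OE1,-0.76,0.12,1.70
GLU,OE2,-0.76,0.12,1.70
LYS,N,-0.47,0.20,1.85
LYS,H,0.31,0.046,0.2245
LYS,CA,0.07,0.055,2.175
LYS,HA,0.09,0.022,1.32
LYS,C,0.51,0.11,2.00
LYS,O,-0.51,0.12,1.70
LYS,CB,-0.18,0.055,2.175
LYS,HB2,0.09,0.022,1.32
LYS,HB3,0.09,0.022,1.32
LYS,CG,-0.18,0.055,2.175
LYS,HG2,0.09,0.022,1.32
LYS,HG3,0.09,0.022,1.32
LYS,CD,-0.18,0.055,2.175
LYS,HD2,0.09,0.022,1.32
LYS,HD3,0.09,0.022,1.32
LYS,CE,0.21,0.055,2.175
LYS,HE2,0.05,0.022,1.32
LYS,HE3,0.05,0.022,1.32
LYS,NZ,-0.30,0.20,1.85
LYS,HZ1,0.33,0.046,0.2245
LYS,HZ2,0.33,0.046,0.2245
LYS,HZ3,0.33,0.046,0.2245
PHE,N,-0.47,0.20,1.85
PHE,H,0.31,0.046,0.2245
PHE,CA,0.07,0.055,2.175
PHE,HA,0.09,0.022,1.32
PHE,C,0.51,0.11,2.00
PHE,O,-0.51,0.12,1.70
PHE,CB,-0.18,0.055,2.175
PHE,HB2,0.09,0.022,1.32
PHE,HB3,0.09,0.022,1.32
PHE,CG,0.00,0.07,1.9924
PHE,CD1,-0.115,0.07,1.9924
PHE,HD1,0.115,0.03,1.3582
PHE,CD2,-0.115,0.07,1.9924
PHE,HD2,0.115,0.03,1.3582
PHE,CE1,-0.115,0.07,1.9924
PHE,HE1,0.115,0.03,1.3582
PHE,CE2,-0.115,0.07,1.9924
PHE,HE2,0.115,0.03,1.3582
PHE,CZ,-0.115,0.07,1.9924
PHE,HZ,0.115,0.03,1.3582
LNK,H,0.09,0.022,1.32
ETA,N,-0.30,0.20,1.85
ETA,HN1,0.33,0.046,0.2245
ETA,HN2,0.33,0.046,0.2245
ETA,HN3,0.33,0.046,0.2245
ETA,C1,0.21,0.055,2.175
ETA,H11,0.05,0.022,1.32
ETA,H12,0.05,0.022,1.32
ETA,C2,0.05,0.055,2.175
ETA,H21,0.09,0.022,1.32
ETA,H22,0.09,0.022,1.32
ETA,O,-0.66,0.1521,1.77
ETA,HO,0.43,0.046,0.2245
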