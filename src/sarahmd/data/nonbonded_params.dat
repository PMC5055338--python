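# Simplified nonbonded parameter table.
# Integer formal charges are spread over terminal side-chain heavy atoms
# of Asp/Glu/Lys/Arg and protonated His (HSP); all other charges are zero.
# LJ parameters are generic per element (CHARMM convention: epsilon
# kcal/mol well depth, Rmin/2 in Angstrom).
# res_name atom_name charge epsilon rmin_half
ALA  N      0.0000  0.1700  1.8500
ALA  CA     0.0000  0.0700  2.0000
ALA  C      0.0000  0.0700  2.0000
ALA  O      0.0000  0.1200  1.7000
ALA  OXT    0.0000  0.1200  1.7000
ALA  CB     0.0000  0.0700  2.0000
ARG  N      0.0000  0.1700  1.8500
ARG  CA     0.0000  0.0700  2.0000
ARG  C      0.0000  0.0700  2.0000
ARG  O      0.0000  0.1200  1.7000
ARG  OXT    0.0000  0.1200  1.7000
ARG  CB     0.0000  0.0700  2.0000
ARG  CG     0.0000  0.0700  2.0000
ARG  CD     0.0000  0.0700  2.0000
ARG  NE     0.0000  0.1700  1.8500
ARG  CZ     0.0000  0.0700  2.0000
ARG  NH1    0.5000  0.1700  1.8500
ARG  NH2    0.5000  0.1700  1.8500
ASN  N      0.0000  0.1700  1.8500
ASN  CA     0.0000  0.0700  2.0000
ASN  C      0.0000  0.0700  2.0000
ASN  O      0.0000  0.1200  1.7000
ASN  OXT    0.0000  0.1200  1.7000
ASN  CB     0.0000  0.0700  2.0000
ASN  CG     0.0000  0.0700  2.0000
ASN  OD1    0.0000  0.1200  1.7000
ASN  ND2    0.0000  0.1700  1.8500
ASP  N      0.0000  0.1700  1.8500
ASP  CA     0.0000  0.0700  2.0000
ASP  C      0.0000  0.0700  2.0000
ASP  O      0.0000  0.1200  1.7000
ASP  OXT    0.0000  0.1200  1.7000
ASP  CB     0.0000  0.0700  2.0000
ASP  CG     0.0000  0.0700  2.0000
ASP  OD1   -0.5000  0.1200  1.7000
ASP  OD2   -0.5000  0.1200  1.7000
CYS  N      0.0000  0.1700  1.8500
CYS  CA     0.0000  0.0700  2.0000
CYS  C      0.0000  0.0700  2.0000
CYS  O      0.0000  0.1200  1.7000
CYS  OXT    0.0000  0.1200  1.7000
CYS  CB     0.0000  0.0700  2.0000
CYS  SG     0.0000  0.4500  2.0000
GLN  N      0.0000  0.1700  1.8500
GLN  CA     0.0000  0.0700  2.0000
GLN  C      0.0000  0.0700  2.0000
GLN  O      0.0000  0.1200  1.7000
GLN  OXT    0.0000  0.1200  1.7000
GLN  CB     0.0000  0.0700  2.0000
GLN  CG     0.0000  0.0700  2.0000
GLN  CD     0.0000  0.0700  2.0000
GLN  OE1    0.0000  0.1200  1.7000
GLN  NE2    0.0000  0.1700  1.8500
GLU  N      0.0000  0.1700  1.8500
GLU  CA     0.0000  0.0700  2.0000
GLU  C      0.0000  0.0700  2.0000
GLU  O      0.0000  0.1200  1.7000
GLU  OXT    0.0000  0.1200  1.7000
GLU  CB     0.0000  0.0700  2.0000
GLU  CG     0.0000  0.0700  2.0000
GLU  CD     0.0000  0.0700  2.0000
GLU  OE1   -0.5000  0.1200  1.7000
GLU  OE2   -0.5000  0.1200  1.7000
GLY  N      0.0000  0.1700  1.8500
GLY  CA     0.0000  0.0700  2.0000
GLY  C      0.0000  0.0700  2.0000
GLY  O      0.0000  0.1200  1.7000
GLY  OXT    0.0000  0.1200  1.7000
HIS  N      0.0000  0.1700  1.8500
HIS  CA     0.0000  0.0700  2.0000
HIS  C      0.0000  0.0700  2.0000
HIS  O      0.0000  0.1200  1.7000
HIS  OXT    0.0000  0.1200  1.7000
HIS  CB     0.0000  0.0700  2.0000
HIS  CG     0.0000  0.0700  2.0000
HIS  ND1    0.0000  0.1700  1.8500
HIS  CD2    0.0000  0.0700  2.0000
HIS  CE1    0.0000  0.0700  2.0000
HIS  NE2    0.0000  0.1700  1.8500
HSP  N      0.0000  0.1700  1.8500
HSP  CA     0.0000  0.0700  2.0000
HSP  C      0.0000  0.0700  2.0000
HSP  O      0.0000  0.1200  1.7000
HSP  OXT    0.0000  0.1200  1.7000
HSP  CB     0.0000  0.0700  2.0000
HSP  CG     0.0000  0.0700  2.0000
HSP  ND1    0.5000  0.1700  1.8500
HSP  CD2    0.0000  0.0700  2.0000
HSP  CE1    0.0000  0.0700  2.0000
HSP  NE2    0.5000  0.1700  1.8500
ILE  N      0.0000  0.1700  1.8500
ILE  CA     0.0000  0.0700  2.0000
ILE  C      0.0000  0.0700  2.0000
ILE  O      0.0000  0.1200  1.7000
ILE  OXT    0.0000  0.1200  1.7000
ILE  CB     0.0000  0.0700  2.0000
ILE  CG1    0.0000  0.0700  2.0000
ILE  CG2    0.0000  0.0700  2.0000
ILE  CD1    0.0000  0.0700  2.0000
LEU  N      0.0000  0.1700  1.8500
LEU  CA     0.0000  0.0700  2.0000
LEU  C      0.0000  0.0700  2.0000
LEU  O      0.0000  0.1200  1.7000
LEU  OXT    0.0000  0.1200  1.7000
LEU  CB     0.0000  0.0700  2.0000
LEU  CG     0.0000  0.0700  2.0000
LEU  CD1    0.0000  0.0700  2.0000
LEU  CD2    0.0000  0.0700  2.0000
LYS  N      0.0000  0.1700  1.8500
LYS  CA     0.0000  0.0700  2.0000
LYS  C      0.0000  0.0700  2.0000
LYS  O      0.0000  0.1200  1.7000
LYS  OXT    0.0000  0.1200  1.7000
LYS  CB     0.0000  0.0700  2.0000
LYS  CG     0.0000  0.0700  2.0000
LYS  CD     0.0000  0.0700  2.0000
LYS  CE     0.0000  0.0700  2.0000
LYS  NZ     1.0000  0.1700  1.8500
MET  N      0.0000  0.1700  1.8500
MET  CA     0.0000  0.0700  2.0000
MET  C      0.0000  0.0700  2.0000
MET  O      0.0000  0.1200  1.7000
MET  OXT    0.0000  0.1200  1.7000
MET  CB     0.0000  0.0700  2.0000
MET  CG     0.0000  0.0700  2.0000
MET  SD     0.0000  0.4500  2.0000
MET  CE     0.0000  0.0700  2.0000
PHE  N      0.0000  0.1700  1.8500
PHE  CA     0.0000  0.0700  2.0000
PHE  C      0.0000  0.0700  2.0000
PHE  O      0.0000  0.1200  1.7000
PHE  OXT    0.0000  0.1200  1.7000
PHE  CB     0.0000  0.0700  2.0000
PHE  CG     0.0000  0.0700  2.0000
PHE  CD1    0.0000  0.0700  2.0000
PHE  CD2    0.0000  0.0700  2.0000
PHE  CE1    0.0000  0.0700  2.0000
PHE  CE2    0.0000  0.0700  2.0000
PHE  CZ     0.0000  0.0700  2.0000
PRO  N      0.0000  0.1700  1.8500
PRO  CA     0.0000  0.0700  2.0000
PRO  C      0.0000  0.0700  2.0000
PRO  O      0.0000  0.1200  1.7000
PRO  OXT    0.0000  0.1200  1.7000
PRO  CB     0.0000  0.0700  2.0000
PRO  CG     0.0000  0.0700  2.0000
PRO  CD     0.0000  0.0700  2.0000
SER  N      0.0000  0.1700  1.8500
SER  CA     0.0000  0.0700  2.0000
SER  C      0.0000  0.0700  2.0000
SER  O      0.0000  0.1200  1.7000
SER  OXT    0.0000  0.1200  1.7000
SER  CB     0.0000  0.0700  2.0000
SER  OG     0.0000  0.1200  1.7000
THR  N      0.0000  0.1700  1.8500
THR  CA     0.0000  0.0700  2.0000
THR  C      0.0000  0.0700  2.0000
THR  O      0.0000  0.1200  1.7000
THR  OXT    0.0000  0.1200  1.7000
THR  CB     0.0000  0.0700  2.0000
THR  OG1    0.0000  0.1200  1.7000
THR  CG2    0.0000  0.0700  2.0000
TRP  N      0.0000  0.1700  1.8500
TRP  CA     0.0000  0.0700  2.0000
TRP  C      0.0000  0.0700  2.0000
TRP  O      0.0000  0.1200  1.7000
TRP  OXT    0.0000  0.1200  1.7000
TRP  CB     0.0000  0.0700  2.0000
TRP  CG     0.0000  0.0700  2.0000
TRP  CD1    0.0000  0.0700  2.0000
TRP  CD2    0.0000  0.0700  2.0000
TRP  NE1    0.0000  0.1700  1.8500
TRP  CE2    0.0000  0.0700  2.0000
TRP  CE3    0.0000  0.0700  2.0000
TRP  CZ2    0.0000  0.0700  2.0000
TRP  CZ3    0.0000  0.0700  2.0000
TRP  CH2    0.0000  0.0700  2.0000
TYR  N      0.0000  0.1700  1.8500
TYR  CA     0.0000  0.0700  2.0000
TYR  C      0.0000  0.0700  2.0000
TYR  O      0.0000  0.1200  1.7000
TYR  OXT    0.0000  0.1200  1.7000
TYR  CB     0.0000  0.0700  2.0000
TYR  CG     0.0000  0.0700  2.0000
TYR  CD1    0.0000  0.0700  2.0000
TYR  CD2    0.0000  0.0700  2.0000
TYR  CE1    0.0000  0.0700  2.0000
TYR  CE2    0.0000  0.0700  2.0000
TYR  CZ     0.0000  0.0700  2.0000
TYR  OH     0.0000  0.1200  1.7000
VAL  N      0.0000  0.1700  1.8500
VAL  CA     0.0000  0.0700  2.0000
VAL  C      0.0000  0.0700  2.0000
VAL  O      0.0000  0.1200  1.7000
VAL  OXT    0.0000  0.1200  1.7000
VAL  CB     0.0000  0.0700  2.0000
VAL  CG1    0.0000  0.0700  2.0000
VAL  CG2    0.0000  0.0700  2.0000
ANY  H      0.0000  0.0300  1.3400
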