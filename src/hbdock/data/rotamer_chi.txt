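# Backbone-independent side-chain rotamer table.
# Columns: AA chi1 chi2 chi3 chi4 weight   ("-" = chi not defined)
# Angles in degrees; rows for each amino acid are ordered by weight
# (most probable first).  The chi modes are the canonical gauche-/trans/
# gauche+ combinations; a Dunbrack-format file may be supplied instead.
ALA  -     -     -     -     1.00
GLY  -     -     -     -     1.00
PRO  -     -     -     -     1.00
SER  62    -     -     -     0.48
SER  -65   -     -     -     0.30
SER  180   -     -     -     0.22
THR  62    -     -     -     0.49
THR  -61   -     -     -     0.44
THR  180   -     -     -     0.07
CYS  -65   -     -     -     0.55
CYS  180   -     -     -     0.26
CYS  62    -     -     -     0.19
VAL  175   -     -     -     0.73
VAL  -60   -     -     -     0.21
VAL  63    -     -     -     0.06
ILE  -65   170   -     -     0.60
ILE  -57   -60   -     -     0.15
ILE  180   165   -     -     0.15
ILE  62    170   -     -     0.10
LEU  -65   175   -     -     0.55
LEU  180   65    -     -     0.30
LEU  -85   60    -     -     0.10
LEU  62    80    -     -     0.05
MET  -65   -65   -70   -     0.35
MET  -65   180   75    -     0.25
MET  180   180   180   -     0.25
MET  62    180   75    -     0.15
PHE  -65   90    -     -     0.50
PHE  180   80    -     -     0.35
PHE  62    90    -     -     0.15
TYR  -65   90    -     -     0.50
TYR  180   80    -     -     0.35
TYR  62    90    -     -     0.15
TRP  -65   95    -     -     0.35
TRP  -65   -5    -     -     0.25
TRP  180   -105  -     -     0.25
TRP  62    -90   -     -     0.15
ASP  -70   -15   -     -     0.50
ASP  180   10    -     -     0.30
ASP  62    -10   -     -     0.20
ASN  -65   -40   -     -     0.35
ASN  -65   120   -     -     0.20
ASN  180   60    -     -     0.20
ASN  62    -20   -     -     0.15
ASN  180   -120  -     -     0.10
GLU  -67   180   -10   -     0.35
GLU  -65   -65   -40   -     0.25
GLU  180   180   0     -     0.20
GLU  62    180   -10   -     0.20
GLN  -67   180   -25   -     0.35
GLN  -65   -65   -40   -     0.25
GLN  180   180   20    -     0.20
GLN  62    180   20    -     0.20
HIS  -65   -70   -     -     0.30
HIS  -65   80    -     -     0.20
HIS  180   60    -     -     0.20
HIS  180   -100  -     -     0.15
HIS  62    -75   -     -     0.15
LYS  -67   180   180   180   0.40
LYS  180   180   180   180   0.30
LYS  -67   180   180   65    0.15
LYS  180   180   65    180   0.15
ARG  -67   180   180   180   0.30
ARG  -67   180   180   -85   0.20
ARG  180   180   180   180   0.20
ARG  -67   180   65    85    0.15
ARG  180   180   65    180   0.15
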