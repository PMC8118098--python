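grapheme,position_class,context_set
IGH,any,
EIGH,any,
AIGH,any,
TCH,any,
DGE,any,
CH,any,
SH,any,
TH,any,
PH,any,
WH,any,
GH,any,
CK,any,
NG,any,
QU,any,
KN,syllable_initial,
WR,syllable_initial,
GN,syllable_initial,
MB,word_final,
EA,any,
EE,any,
EI,any,
EY,any,
IE,any,
OO,any,
OU,any,
OW,any,
OI,any,
OY,any,
AI,any,
AY,any,
AW,any,
AU,any,
OA,any,
OE,any,
UE,any,
UI,any,
EW,any,
AR,any,
ER,any,
IR,any,
OR,any,
UR,any,
BB,any,
DD,any,
FF,any,
GG,any,
LL,any,
MM,any,
NN,any,
PP,any,
RR,any,
SS,any,
TT,any,
ZZ,any,
C,any,E|I|Y
G,any,E|I|Y
A,any,
B,any,
C,any,
D,any,
E,any,
F,any,
G,any,
H,any,
I,any,
J,any,
K,any,
L,any,
M,any,
N,any,
O,any,
P,any,
Q,any,
R,any,
S,any,
T,any,
U,any,
V,any,
W,any,
X,any,
Y,any,
Z,any,
A,word_initial,
I,word_initial,
E,word_initial,
O,word_initial,
U,word_initial,
Y,word_final,
I,word_final,
O,word_final,
E,word_final,
A,word_final,
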