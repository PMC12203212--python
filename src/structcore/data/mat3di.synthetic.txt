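# Synthetic uniform structural-alphabet substitution matrix.
# Match +6, mismatch -3, X scores 0 against everything.
   A  C  D  E  F  G  H  I  K  L  M  N  P  Q  R  S  T  V  W  Y  X
A   6  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   0
C  -3   6  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   0
D  -3  -3   6  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   0
E  -3  -3  -3   6  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   0
F  -3  -3  -3  -3   6  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   0
G  -3  -3  -3  -3  -3   6  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   0
H  -3  -3  -3  -3  -3  -3   6  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   0
I  -3  -3  -3  -3  -3  -3  -3   6  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   0
K  -3  -3  -3  -3  -3  -3  -3  -3   6  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   0
L  -3  -3  -3  -3  -3  -3  -3  -3  -3   6  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   0
M  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   6  -3  -3  -3  -3  -3  -3  -3  -3  -3   0
N  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   6  -3  -3  -3  -3  -3  -3  -3  -3   0
P  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   6  -3  -3  -3  -3  -3  -3  -3   0
Q  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   6  -3  -3  -3  -3  -3  -3   0
R  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   6  -3  -3  -3  -3  -3   0
S  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   6  -3  -3  -3  -3   0
T  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   6  -3  -3  -3   0
V  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   6  -3  -3   0
W  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   6  -3   0
Y  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3  -3   6   0
X   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0
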