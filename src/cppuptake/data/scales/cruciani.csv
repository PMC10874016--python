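residue,PP1,PP2,PP3
A,-0.96,-0.76,0.31
C,-0.55,-0.47,0.19
D,1.0,-0.89,-1.0
E,0.94,-0.54,-0.99
F,-0.85,0.48,-0.58
G,-0.88,-1.0,0.49
H,0.67,-0.11,0.37
I,-0.94,0.04,-0.18
K,0.6,0.1,1.0
L,-0.9,0.03,-0.24
M,-0.82,0.03,0.16
N,0.82,-0.57,0.02
P,-0.81,-0.4,-0.07
Q,0.78,-0.3,-0.38
R,0.8,0.63,0.99
S,0.41,-0.82,0.57
T,0.4,-0.64,0.37
V,-0.94,-0.13,-0.49
W,-0.59,0.85,-0.56
Y,0.31,0.42,-0.09
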