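alternative,x,y
A,2.00,3.00
B,3.00,2.00
D,1.75,2.75
Dprime,1.90,2.90
F,1.75,3.00
R,2.00,2.75
C,1.00,4.00
S,2.90,2.10
J,2.90,2.00
H,1.90,2.00
G,1.80,2.00
K,0.50,4.50
L,1.50,3.50
Q,2.50,2.50
U,3.50,1.50
W,4.50,0.50
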