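# extended Ala-X-Ala (phi=-120, psi=+120), probe 1.4 Å, 960 points
aa,max_sasa
A,110.2682
C,135.8536
D,177.2274
E,205.0829
F,268.1849
G,87.6385
H,233.4812
I,186.9216
K,208.1131
L,186.9216
M,187.7788
N,179.0272
P,160.2531
Q,206.0872
R,260.0132
S,127.5989
T,158.9691
V,160.2531
W,346.5007
Y,288.2502
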