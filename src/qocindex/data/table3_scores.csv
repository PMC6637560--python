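facility,base,alt_a,alt_b,alt_c,alt_d
A,11.07,9.81,2.37,11.20,0.33
B,10.67,9.59,2.13,7.97,0.22
C,10.50,9.36,1.92,8.27,0.13
D,10.03,8.89,1.92,8.27,0.13
E,9.88,8.96,2.00,5.13,0.07
F,9.83,8.75,1.79,5.39,0.06
G,9.68,9.43,1.46,4.49,0.05
H,9.37,8.28,1.79,4.10,0.02
I,9.36,8.15,1.13,2.90,0.04
J,9.21,8.74,1.29,3.75,0.02
K,9.14,7.55,1.67,1.50,0.02
L,8.99,8.43,1.00,1.99,0.02
M,8.84,7.51,1.17,1.64,0.01
N,8.50,7.50,0.79,-2.35,0.01
O,8.48,7.51,1.17,-1.46,0.01
P,8.28,7.83,1.29,-1.72,0.00
Q,8.24,7.37,1.13,-2.77,0.01
R,8.12,7.52,1.00,-2.43,0.00
S,8.10,7.63,1.00,-2.76,0.00
T,7.85,7.16,1.50,-3.80,0.00
U,7.52,7.37,0.70,-4.79,0.00
V,7.44,6.79,1.00,-5.77,0.00
W,7.39,7.39,0.50,-7.96,0.00
X,7.16,6.68,1.00,-9.16,0.00
Y,7.11,6.70,1.00,-8.40,0.00
Z,6.45,5.67,0.50,-9.99,0.00
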