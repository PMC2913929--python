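a1: 8.345
a2: 3.7925
a3: 0.3154
a4: 0.6787
a5: 10.0718
a6: 6.6644
a7: 2.4695
b1: 4.1472
b2: 0.156
b3: 0.7149
b4: 2.9415
b5: 4.1075
b6: 0.4715
b7: 3.5676
b8: 0.5805
b9: 7.0233
b10: 0.8218
d1: 7.4608
d2: 0.4405
d3: 2.171
d4: 3.0883
d5: 23.312
f1: 0.1962
f2: 0.1317
gamma1: 0.0422
gamma2: 0.0244
r1: 5.1759
r2: 5.0326
n: 1.0168
m: 2.8134
k: 1.4135
g: 1.273
h: 3.6978
light_params:
  intensity: 1.0
  ramp: 0.0
  dawn_offset: 0.0
chain_len_frq: 2
chain_len_wc: 2
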