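n	VDE_exp	ADE_exp
0	1.30	1.05
1	1.80	1.55
2	2.05	1.80
3	2.20	1.95
4	2.30	2.05
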