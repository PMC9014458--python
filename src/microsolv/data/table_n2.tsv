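name	dG	VDE	ADE	x_M
two-m3	1.4	2.00	1.62	0.04
two-m5	1.9	1.81	1.46	0.02
two-m6	2.0	1.74	1.42	0.01
two-m19	0.0	1.81	1.32	0.46
two-m22	2.1	1.75	1.42	0.01
two-m23	0.1	1.81	1.53	0.39
two-m24	1.7	2.07	1.68	0.03
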