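name	dG	VDE	ADE	x_M
three-m1	0.2	2.17	1.76	0.13
three-m2	0.2	2.17	1.76	0.13
three-m3	0.5	2.17	1.77	0.08
three-m4	0.2	2.09	1.72	0.12
three-m5	0.2	2.11	1.72	0.12
three-m6	0.4	2.08	1.71	0.09
three-m13	0.3	2.08	1.71	0.11
three-m15	0.0	2.07	1.69	0.18
three-m21	1.4	2.37	1.93	0.02
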