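name	dG	VDE	ADE	x_M
manual-9	2.5	1.63	1.20	0.01
one-m1	2.2	1.59	1.31	0.02
one-m2	1.6	1.64	1.33	0.05
one-m5	2.6	1.65	1.36	0.01
one-m7	2.0	1.65	1.33	0.02
one-m9	2.0	1.36	1.18	0.03
one-m12	2.6	1.59	1.31	0.01
one-m14	1.9	1.36	0.97	0.03
one-m17	1.6	1.67	1.35	0.05
one-m18	2.6	1.65	1.36	0.01
one-m20	2.0	1.70	1.38	0.03
one-m23	0.0	1.70	1.37	0.71
one-m29	2.3	1.33	0.97	0.02
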