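name	dG	VDE	ADE	x_M
four-m1	1.6	2.23	1.76	0.03
four-m3	2.0	2.13	1.75	0.01
four-m4	1.1	2.14	1.76	0.06
four-m5	1.7	2.14	1.76	0.02
four-m8	1.6	2.18	1.79	0.03
four-m13	0.7	2.39	1.97	0.12
four-m14	1.1	2.17	1.79	0.06
four-m15	1.1	2.25	1.84	0.06
four-m16	0.8	2.12	1.75	0.10
four-m23	0.0	2.34	1.90	0.38
four-m27	1.7	2.24	1.82	0.02
four-m31	0.8	2.37	1.97	0.10
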