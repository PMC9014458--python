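n	weighted_VDE	weighted_ADE
1	1.66	1.34
2	1.82	1.43
3	2.11	1.73
4	2.28	1.73
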