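n	wbe_kcal_mol
1	-18.0
2	-22.9
3	-26.7
4	-30.5
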