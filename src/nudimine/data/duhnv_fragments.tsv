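fragment	length_bp	gc_percent	n_cds	reads_mapped
F1	6515	28.49	5	1210
F2	52843	27.93	40	10280
F3	51592	27.88	40	9858
F4	31968	27.56	23	6202
F5	4261	29.46	2	687
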