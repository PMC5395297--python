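gene	chrom	start	end	fdr	lfc
g1	chr1	2100	2600	0.03	0.2
g2	chr1	3100	3400	0.2	1.0
g3	chr1	5100	5400	0.04	-0.5
g4	chr1	8300	8800	0.01	1.0
g5	chr1	9299	9700	0.001	2.0
g6	chr1	15900	16500	0.04	0.5
g7	chr1	30000	31000	0.001	3.0
g8	chr1	32000	33000	0.5	0.1
g9	chr1	34000	35000	0.06	2.0
g10	chr1	36000	37000	0.01	-3.0
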