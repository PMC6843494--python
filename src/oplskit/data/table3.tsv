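compound	direction	p_value	vip
Alanine	decreased	0.026	1.94
Glycine	decreased	0.025	1.95
Isoleucine	decreased	0.016	1.93
Leucine	decreased	0.031	1.60
Lysine	decreased	0.025	1.37
Tryptophan	decreased	0.025	0.95
1-monohexadecanoylglycerol	increased	0.004	1.79
Aspartic acid	increased	0.007	2.19
Hexadecanoic acid	increased	0.013	1.71
Hexadecenoic acid	increased	0.039	1.63
Lauric acid	increased	0.008	1.51
Myristic acid	increased	0.026	1.44
Oleic acid	increased	0.033	1.72
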