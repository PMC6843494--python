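compound	direction	p_value	vip
Arabinose	decreased	0.013	1.83
Ribose	decreased	0.014	1.76
Sucrose	decreased	0.034	1.83
Xylitol	decreased	0.025	1.41
Fructose	increased	0.022	1.96
1,5-anhydroglucitol	increased	0.016	1.93
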