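variable	active_n	active_total	placebo_n	placebo_total	printed_p
Smokers	5	55	6	44	0.47
Diabetes	11	55	8	44	0.82
Hypertension	34	55	31	44	0.91
IHD	12	55	10	44	0.91
NYHA class I	37	55	22	44	0.08
NYHA class II	12	55	18	44	0.04
NYHA class III	6	55	4	44	0.77
NYHA class IV	0	55	0	44
Unclassified NYHA	0	55	0	44
ACEI or ARB	11	55	12	44	0.39
Beta-blockers	20	55	17	44	0.82
Digitalis	3	55	0	44	n/a
Diuretics	13	55	13	44	0.51
Statins	13	55	7	44	0.34
EF<40%	6	55	2	44	0.25
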