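metabolite	p_value	vip
Alanine	0.001	1.79
Alanine-3-cyano	0.016	1.62
Arachidonic acid	NS	1.30
Aspartic acid	0.017	1.65
Butyric acid, 2-amino	NS	1.16
Cysteine	0.048	1.05
Fucose	NS	1.21
Glutamic acid	0.022	1.60
Glycine	0.010	1.50
Isoleucine	0.031	1.49
Leucine	NS	1.45
Methionine	0.030	1.51
Myo-inositol	0.022	1.42
Ornithine-1,5-lactam	0.013	1.29
Phenylalanine	NS	1.25
Proline-4-hydroxy	0.026	1.39
Salicylic acid	NS	1.34
Serine	0.032	1.44
Threonine	0.049	1.36
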