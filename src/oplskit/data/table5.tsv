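compound	main	validation1	validation2
1,5-anhydro-d-glucitol	N	↑	↑
1-dodecanoyl-sn-glycero-3-phosphocholine	N	N	↑
1-Monohexadecanoylglycerol	N	↑	↑
1-Palmitoyl-sn-glycero-3-phosphocholine	N	↓	N
2-aminobutyric acid	N	↓	↓
3-hydroxybutyric acid	N	↑	↑
Alanine	↓	↓	↓
Alanine, 3-cyano	↓	N	N
Allothreonine	N	↓	N
Alpha-ketoglutarate	↓	N	N
Aminomalonic acid	N	N	↓
Arabinose	↓	↓	↓
Arabitol/ribitol	↓	N	N
Arachidonic acid	↓	N	N
Arginine	↓	↓	↓
Asparagine, DL-	↓	↓	↓
Aspartic acid, DL	↓	↓	↑
Benzyl alcohol	↓	N	N
Beta-Alanine	↓	N	N
Butanoic acid, 2,4-dihydroxy-	↑	N	N
Butyric acid, 2-amino	↓	N	N
Campesterol	↑	↑	↑
Cholesterol	↑	N	N
Citric acid	↓	↑	↑
Creatinine	↓	↓	↑
Cysteine	↓	↓	↓
Cystine	↓	↑	↓
Docosanoic acid	↑	↑	N
Docosahexaenoic acid, 4,7,10,13,16,19-(Z,Z,Z,Z,Z,Z)	↓	N	↓
Eicosanoic acid, n-	↓	N	N
Eicosapentaenoic acid	↓	N	N
Ethanolamine	↓	↑	↑
Fructose	↑	↑	↑
Fucose	↓	N	N
Glucose	↑	N	N
Glucose, 1,6-anhydro, beta	↓	↓	N
Glutamic acid	↓	↓	↓
Glutamine	↓	↓	↑
Glyceric acid	↓	↓	↓
Glycerol	↑	N	N
Glycerol-2-phosphate	↓	N	N
Glycerol-3-phosphate	↑	↓	↓
Glycine	↓	↓	↑
Glycolic acid	N	N	↑
Heptadecanoic acid, n-	↑	↓	N
Heptanoic acid	↑	N	N
Hexadecanoic acid	↑	↑	↑
Hexadecenoic acid	↑	↑	↑
Hippuric acid	↓	N	N
Histidine	↓	↓	↓
Indole-3-acetic acid	↓	N	N
Inosine	↑	N	N
Inositol, myo	↓	↑	↓
Inositol-1-phosphate	↑	↓	↑
Isoleucine	↓	↓	↓
Itaconic acid	↓	N	N
Lactic acid,	↓	↓	↑
Lauric acid (dodedecanoic acid)	↑	↑	↑
Leucine	↓	↓	↓
Linoleic acid	↑	↑	↑
Lysine	↓	↓	↓
Malic acid	↓	↓	↑
Malonic acid, 2-amino	↑	N	N
Maltose	↓	↓	↑
Mannitol	N	N	↓
Mannose	↑	N	N
Methionine	↓	N	N
Monomethylphosphate	↑	↑	↑
Myristic acid	↑	↑	↑
Nonanoic acid,n	↓	↑	↓
Oleic acid	↑	↑	↑
Ornithine	↓	↓	↓
Ornithine-1,5-lactam	↓	N	N
Oxalic acid	N	N	↓
Phenylalanine	↓	↓	↓
Phosphoric acid	↑	N	N
Pipecolic acid	↓	N	N
Proline	↓	↓	↓
Proline, 4-hydroxy	↓	N	N
Protocatechuic acid	↓	N	N
Pseudouridine	N	↓	↑
Putrescine	↓	N	N
Pyridine, 3-hydroxy	↓	N	N
Pyroglutamic acid	↓	↓	↑
Pyruvic acid	↑	↓	↓
Ribose	↓	↓	↓
Salicylic acid	↓	↓	↓
Serine	↓	↓	↓
Sitosterol	↑	↓	N
Sorbitol	↑	N	N
Stearic acid	↑	↑	↑
Succinic acid	↑	N	↑
Sucrose	↑	↑	↑
Taurine	↓	↓	↓
Threitol	↑	N	N
Threonic acid	↓	↑	↓
Threonine	↓	↓	↓
Tocopherol, alpha-	↑	↑	↓
Tocopherol, gamma-	↓	↓	↑
Tryptophan	↓	↓	↓
Tyrosine	↓	↓	↓
Urea	↓	N	↓
Uric acid	↓	↓	↑
Valine	↓	↓	↓
Xylitol	↑	↓	↓
Xylose	↓	↓	↑
Xylulose	↓	N	↑
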