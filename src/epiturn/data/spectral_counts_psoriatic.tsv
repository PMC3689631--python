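protein_name	unique_peptides	total_peptide_count	mol_wt_da
Keratin 6A	58	191	60045
Keratin 10	46	147	58827
Keratin 1	50	128	66039
Keratin 14	36	92	51622
Keratin 2	34	81	65433
Keratin 5	29	58	62378
Keratin 17	19	44	48106
Keratin 16	22	46	51268
Histone cluster 4	4	8	11367
S100 calcium-binding protein A8	3	7	10834
Serine (or cysteine) proteinase inhibitor, clade B, member 4	6	14	44854
Pyruvate kinase, muscle isoform 2	9	18	58062
Junction plakoglobin	12	22	81745
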