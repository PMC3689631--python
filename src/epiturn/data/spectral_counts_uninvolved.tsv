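protein_name	unique_peptides	total_peptide_count	mol_wt_da
Keratin 10	34	91	58827
Keratin 1	37	95	66039
Keratin 2	34	66	65433
Keratin 6A	10	24	60045
Keratin 77 (Keratin 1B)	16	24	61801
Keratin 5	11	20	62378
Keratin 14	5	7	51622
Glycine-N-acyltransferase isoform b	2	2	18506
Keratin 6 irs4	3	6	57865
Glyceraldehyde-3-phosphate dehydrogenase	2	3	36053
Keratin 9	4	5	62064
Keratin 5b	3	4	56866
Transglutaminase 3 precursor	2	2	76731
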