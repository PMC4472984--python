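gene_id	forward_primer	reverse_primer	role
CaNAC02	CCATGGGAGCTACCAAAGAA	TTTCGATCTCTCGGGCTAAA	target
CaNAC04	AACAAGACCACCTGACCCTG	AATGCGTCGATTTCTCAACC	target
CaNAC05	CTAAGGCAACGTTCGGAGAG	TTTGGCCTAGCACCATTAGG	target
CaNAC06	GTCCCTTCTGTGTCCACGAT	GCTCCACCACTCTGAACCTC	target
CaNAC16	CACCAAAGGGCCTCAAGACAG	GCCTCATGGATCCAATTTGCCTAT	target
CaNAC19	AGAGGTTTGGTTTGTTGGTG	CCAAACACATGGTGAGGAAA	target
CaNAC21	CTTACCCTTTACCCGCTTCC	TCTTCTCCCAAATCACCTGG	target
CaNAC24	TGCCACCAGGTTTTAGGTTC	AATGATGGAAACAGGCAAGG	target
CaNAC27	GCTTTGTTTGGGGATGAAGA	ACCTGCACCAGCTGCTCTAT	target
CaNAC40	ACGATCCTTGGGATCTTCCT	ATATTTCCTGTCTCGTGGCG	target
CaNAC41	CCTGAAGAGGCAATTGACAGA	TCACCACTGCAGTCAAAGGT	target
CaNAC43	CACTGGTGTTCTACGCTGGA	GCCGGCTGATCTATCAACAT	target
CaNAC44	CCCACATGGTACTCGTACTGG	TTGCAAGCCAGAAGAAGGAT	target
CaNAC46	TATTGGAAGGCAACAGGGTC	TTTCTTAGGCCAACAATGCC	target
CaNAC47	TTTCACACGGATTCAAGCTG	ACAAATTCGTTCCACTTGGG	target
CaNAC50	CCCACCGATGAAGAACTTGT	TACTGGAAGGGGTGCAGAAG	target
CaNAC52	GCTACATCAAAGCCATGCCC	GGCCTCACTCCATTTGGGTA	target
CaNAC57	GTGGTATGCAGGACCAAGCA	GGTGGTGGACGATGGTGATT	target
CaNAC67	ACAGGAGGAGAAGCTCGGAT	TCCTCATCCCGCTTTGAACC	target
IF4a	TGGACCAGAACACTAGGGACATT	AAACACGGGAAGACCCAGAA	reference
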