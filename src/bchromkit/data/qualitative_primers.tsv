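id	sequence	role	template
49B1-F	GAGCTTCACACTTGCAGAGGTAAGTCATTTTTGCAGAGAC	B	contig_49
49B2-F	GCTTCACACTTGCAGAGGTAAGTCATTTTT	B	contig_49
49C+-F	GTTTACAGTCTGATGATGGGACATCATGCTCTGC	C	contig_49
49-R	TGTCCAGAGTATAATCGCAGCCTTTGCGGT	R	contig_49
80B-F	GAGGCATTACATCGGTCTTTCCATCA	B	contig_80
80C+-F	GGTGAGCAGCAGGATTTTGAATTGAATGCG	C	contig_80
80-R	CCTGATTGAGTGCTTCTCACAC	R	contig_80
182B1-F	GGGTGTGTTTGGTTGTGGTTTGACAAGGAGTG	B	contig_182
182B2-F	GGAGTGAATTGTGATGGT	B	contig_182
182B3-F	GGTTTGACAAGGAGTGAATTGTGATGGTTAGATC	B	contig_182
182B4-F	GAGTGAATTGTGATGGTTAGATCACTAGGTAT	B	contig_182
182C+-F	AGAATGGTCCAAGGAAGG	C	contig_182
182-R	CCATCAGAACCAGCATTAA	R	contig_182
207B-F	GAGACACTTCTTGGAGAAAATGAAATGCCCAC	B	contig_207
207C+-F	ACCAGGCCAGGAGACGACTGAAGAACT	C	contig_207
207-R	GACCTGCAGAAATGTGAACATGGTTGCAGTTTACAA	R	contig_207
323B-F	GGGGGTGTTTTGCTTTTGGTTTTCCTACATTAGTTA	B	contig_323
323C+-F	GTATAAGCCATCTCTGTCATCTAAGGTACA	C	contig_323
323-R	GACACAGTACAGCTGACACAGACGAAGCAACAG	R	contig_323
764B-F	CCTGAGATGGTCCGATTGGGCTGGTAA	B	contig_764
764C+-F	GGTGAAGCATCAAAGAGCTCTCTGAGTCT	C	contig_764
764-R	GGAGACAAGGAGATGCGTGTTGGTGAAGTCCTAA	R	contig_764
1100B-F	GGGTGTGTGGAGATGTACATCAGCACACATGTT	B	contig_1100
1100C+-F	CACTGAGACGGCATTGGCATGAGAAA	C	contig_1100
1100-R	AGCATGGTGGCAGAGGTCTTTA	R	contig_1100
1987B-F	CCCTCCTGTTATTCATTCCCTA	B	contig_1987
1987C+-F	TACTTTGCTGTGTGTTTTGCCTGTC	C	contig_1987
1987-R	AAGTGTGGCTGTGTGCAGGCAGGAAT	R	contig_1987
2519B-F	GCAGGATTCAGGAGTGAAGCATCTGTGTGA	B	contig_2519
2519C+-F	CACTAAACTGCAGACATCAGGCTG	C	contig_2519
2519-R	CATTGTTCTGCTGCAGTCAATGGAC	R	contig_2519
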