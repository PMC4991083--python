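id	sequence	role	template
Scaffold_3-F	GCCACCATGTTCAGATTATTGGAGAGTA	F	Scaffold_3
Scaffold_3-R	AATGCCTGACTTATCCATGCCAGGTG	R	Scaffold_3
Scaffold_13-F	CGTTTTGTACGTCTGCTGGA	F	Scaffold_13
Scaffold_13-R	ACCGGTACCTGTGGTCTAGT	R	Scaffold_13
Scaffold_19-F	TGGAGCATGAGTCGAAAAGCA	F	Scaffold_19
Scaffold_19-R	TCGCAGAACAGTGTGAACCA	R	Scaffold_19
Scaffold_26-F	AGACGGGTCGGGATCTTACA	F	Scaffold_26
Scaffold_26-R	TGTTTGAGCATCCCCCAGAC	R	Scaffold_26
Scaffold_31-F	CCAAGGCTCAGGAAATAGGGG	F	Scaffold_31
Scaffold_31-R	ACCACTGCTTCTCAAAGAGGG	R	Scaffold_31
Scaffold_324-F	CAGGTCCCTCTGCGTAACTG	F	Scaffold_324
Scaffold_324-R	GACGCCCCAGTCATCATTCA	R	Scaffold_324
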