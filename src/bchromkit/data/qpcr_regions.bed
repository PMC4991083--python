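Scaffold_3	9112721	9126380	Scaffold_3_region	0
Scaffold_13	5682225	5684956	Scaffold_13_region	0
Scaffold_19	960417	963148	Scaffold_19_region	0
Scaffold_26	1707513	1710244	Scaffold_26_region	0
Scaffold_31	5673821	5680650	Scaffold_31_region	0
Scaffold_324	77097	77779	Scaffold_324_region	0
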