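isotype	primer	signature
IGM	Cm	CAGGAGACGAGGGGGAAAAGG
IGG	Cg	CCGATGGGCCCTTGGTGGA
IGA	Ca	GAAGACCTTGGGGCTGGTCG
IGE	Ce	TTGCAGCAGCGGGTCAAGGG
IGD	Cd	GCACCCACGAAGGCTCCGGA
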