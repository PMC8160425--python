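>IGHV1-2*01
AGTAGCCCTTCCAAAGGACAAGCTCCGTAGGAAACTCTCTCAAACTCGATAAACCTAAGTCTTGAGACATACTGGCCATTCGATAATACTGCTTAGACAAATGCCTTCTGCGAAGTTGGAACAATGACTTTGAGGATAAAATATTTCGGGCTCAAGGGGCGAGAGTATCCTCGGGCTCACACAGCGACCATGCTAAGAAATGGCTCACCAAATACGGGTAACTATCGATTGCATCTAAGGATCTAATATCCTCAGAGCCATTTCATGGACAATATTTGCGAAGAGGAGTGCCTTTCTCGC
>IGHV3-23*01
TCGTAATTATAAACGACATCCTCTGGTCGCTTGATCCGTGGGCCCGGTCGCAATCGCCCTCTGAGAGTGGTTTCAACAGGACATTGCTCAGGTCAGCATGGGGTAAGGCACGCCGTTGCTTCGATAACACTAACAATAACGATTCCCTGCGAAATTACTGGCGTTGACAGAGCGCGCTTTGGGCCCGTTACCCCTATGTTGTTATGCCCAGAATCGTATAGTAAAGCACACTACCCCGGGTGAGAAGAGTAATTTCCGGGAATAGCTCATACAGTGTAGTATTTTAATTGCCGTGTGTCG
>IGHV4-34*01
TCTCGTCGTGCGGCGTCCGAGCACGACGGTTGTTTCGGGGTAAACTTCGTAAAACTGTGCGCCAACCGCCGTGAAGTTCTGCTCGATATTCGTCCGCACGTTCAGTCCTACCCGTCCCCCTACTTATAAGGGATCCATTTACACTGTCTGTTCTGCAAGTAGCTCCATAATGACCCGGTCATCTTCGGCAGCCCGGAATTAAACAACGTACACGTACTGGTCGCTCTAATCCAATTAGGTGAATAACGCCCGCAGCTGCTCCACGCGTCTTCTGAGGAGGAGCCAGATTGCGTGCTCATC
>IGHV5-51*01
GTCGCCATGCCCAGGCCACGTTAGTCATGGAGCGTGAGCCTCGCACGAAATGTAACACGGTGCGTGTAACCGTGTCCAGCTGCGTTTGCTAATGGCTATTAATACGAGGAACAGCCGGCCCTTATCGGGCCTGTGGTTGGCCTGTGCTTCAAGCCAGCAACTAGACGTGTCACTGTCTGCGCGAAAACAATCAGGTACTCTTTGCCAAAAGTCTAGTCCGATGTGGGCGGACTATCTTTAGATTTTTAGGATATGCTTCTGTGCCTACGTTGCCAGTTAGGCTCTTCGTGCTTTGCTGGG
>IGHV6-1*01
GTCTATTAGCTCGGGGAGATGCAGATTCTTCAAACGGAGCTTGTAGCACACGACTGGAACTTTCGGATCTGACCCGGTGCCTAAAGCTCGACCGAATACCGACTGTCGGCGCCTAGGCTTGCACGGTTTAAAACATTACCCACGTGAATAAGCACAACAACTCATGGCGTTAGACTTTTCAACGACATGTATCGGCTAACGATAGAATACTGGTGCTTGGCTACATTTATAAGGCGCCAGAATCAGGGCTTTGTTCACAATGGCACGGAGCGTCGCGAAGACATTTAGTGCGCAAATTTT
>IGHJ4*01
TTTTGCACCTGTTGGAACCTCCGGCTCGCTACGATATGATATAACCAA
>IGHJ5*01
CGAAGAGAAGAATGGGCTTCGTCCTTTTGCGGGGGAAGTTTCTCGCAA
>IGHJ6*01
ACGCGAACAGCTTGGAGGGGTAGCCATCTAGACTTTGAGACTACTCGT
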