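>SYNTH_REGION:1-565 synthetic promoter-like CpG island region
AACTAACCTTGTATTTGGCGCTCCTTGGACTTATCTCACGACAGAAGTGACTCGACTGTAGAGTATCCGC
AGGGTGTTACAGCTCTTCGCCTGACTTTTAGGATTAATTCGCCAACCACCAGCTCCGTAACTATCACACC
TCGTAATAGACTAACATCCTACGGCCATCTGGTGCTCGTATGGGATAATTCTCGTGGAGTCTATTCTACG
CATTAAAGACTCTAACGTTATAAGGATGGTCTATAGACGGAACTCCCATACTCGGACATACCTACTTGGG
CTCGAAAACACTAAGTGAGAGAACGGTATGTCCTATGAGTGACCGTGGACTTATTCCCCCACGGGGATTC
CCTTAACTCGGGGAAGAGAAGGGGGAACTGTGGGGGTTGTAATAACGTTTCTTGAGCTAAGCCGATGGCT
GGATGCCGCACTCAGGACAACCGGATGCAGATCTCTACTCGTTAGTAAAGCTAAAACCCTGCGCCAAGAT
AAACTCTCTCGTGCAGGCTTGCTTCCGATAGGCATCATCTGTGGCGAGTGATTACTACAAAGACGATTAA
TTTAA
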