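>ecoli16s_synthetic constructed E. coli-like 16S rRNA reference (synthetic sequence; primer sites and pseudoknot positions at E. coli coordinates)
AAATTGAAGAGTTTGATCATGGCTCAGGTTGACAGCCTCATAAGTCCACATGGTGATCTGCCGTGGGGGC
GCATCCGTCTTTCGGCAAGATGCATATAGCAGCTGCGTCATAGGATGGCCTTCAGCGCCGGACTTGCGTG
TATCGCGATGCTTGGAAGCTGACTTGATGTTATGATGCAATTAGTCGAGTATCCGCTACGACCATGGCCG
GGAATTTCTAAGACGGTGTAACTCAGCTGCACAGCATCCTCCCTTGGTGCCGGGGGAAAGAGTTCCTGCC
TTGCGAACGACCCTTATTAACCTACTGGGCCGGGAGCCAAGCAACACCTCACTGTCGGAAAATCTAGGGG
GCGGGGACGGGGGTGGAGCCCCCCGGGAGTCCTGTGTCGTCGATCGATGTAAGAGACGCAGACGATCCGA
GTGACGATAGGCGCTCGCCAGCTATTGCGATCGCTGGTAGCGGTGCTCATTAGAGGAATTAACTTGGAAC
CATTAGTTGCGGCAGCCCGGAGCAATATCGTGGTAGAAGCCTAGCGCGATTGCACCCTAATTCGTTGCTA
GTCCTATACGGGTCGAGGGCACTGACTTGGGGTCTGAGTGCGTCACTCGGTCGAGCGTTTTAGGAACAGC
GCTTAGACAGGCTGCGCATGATTGAGATGGGGTAGTACGGTGTAACCTCTGGCTCGCTGCCACGCTATAC
CCCGGCTAACGGTTGCATAAACTAACCCTCACTTGGGCAGTCAGTAAGGTCGGTTGCGTGAACTGGCCAG
TTCGGGCGGACACATGGGGGGGATGTACGTAGGATGTACAGCAGAACGCGTACCCCCTTTGGGCATGTAA
GCTACCCTCGCGCAGCCCTATTGTTATTTCCAGGGTTCCTCTTTAAGCGGTCGCATGCACAATTTGGCGT
GGCAATGAAGAGATTCTGACACCCGACGTCGGCGCGTTTGCGACTCTGTCGGCGTGTCATGCTCAATGTG
ATGATCCGTACGAGCACTCACATGTACGCCTCGTTTAGAGGCAGCGTGGGGTCCACCTCTAAGTAATATT
ATACTCGCCCACGGCGAAAGCTTGTTCCCGAGGGTCGCGAAAACAGTGCCACGGATGCCGGTGCCTTCTT
AGAGGGGGCACTCGGTCCGGACCACCAGCGCCGCTTGAGCAGTTGTAACGGATAACCCGGAGGGGACAGT
ACAGCGGGCCTAGCGTTGTCGCGAGAACACATCCGAGGCGGGAGGGGGTGGGACGTCTCGGCCACGAGAT
GAGGCCACAAACCGGAGCCGGTCTCACGGTTGGGAGTGAAACACTCAATAGCTTATTGCTACAATGACAC
TGACGCGACCATTAGTCTCGATCGCTGAGGGCTAAAGTGACAGGAAGTTTACACGCCTCCCGCACTATGC
ACGGCTACTTGTGTTTATCCGCATAGAACCCTCTTGGGGGTCGTATGAAATGGCACCGCTAACTCCACGT
TCCCCGCACTCTGGCAGAATGAATAAATCCTTGCTCCTGCCGACGTGCAATGGCGGCTGGATCACCTCCT
TA
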