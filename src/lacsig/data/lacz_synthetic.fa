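>lacZ_synthetic synthetic 3096 bp stand-in for the lacZ CDS
TGGTGAAAAACTGAGAGCTGTAACGCTGAAGCGTGTCCTGCCTGTGACAGCCCCGCGCCG
CCCATTGAGCGACCGCGTAATGCATTCGAGCCACTACGCCAAGCTCGAACAGGCTCGCGC
ACCAGGACACATCCTACCAGGACATGTTGATATATTCTAACCGCGCGTCAAACCTACAGG
ATGTCGGAATTATGATAAGCACAACTCTCCGACCCGCAGCGCGGACGTACGGCCGGGCTG
TCATAGTCCCGGGGCCTCCCGTGCTTGATACCGGTAATAGATGCGGGACCGATAGAGCTG
GCCAGGATGCATCGGCTGGACCGGCTCACCGTGTGACCTGGCACTATCCGCCTGCAGCGC
ACACGAATGGAACCCCTTTGGGGGCTAGTGGTGGGGGACGGCGTCGTCTCGCGCGTGCCA
GCGCTCGCCGGTGATAATTGTCAATGTCTCATTACGGGCCCCAAGTCCGTTATAGTCGGC
GTTCCCGTCCAGCAACCTGATAATACTCCAGCGCGCGAATGAGCTGTCATGCTAGGGCGG
GTACGTGAACCGCTTGTAAGAACGGCAATCCCCACCGCACAGCTTCAAAGGCCTTAGATC
CCTGGGCAGCGCCGATGTGATTTAGATACCACACCTCTGCGCCCACAAGACCTGGACCTA
CGAAGTTTTAGCGAGTTTCCGTAATCCCTTACTGTCGATCCGCGGGGAATGTAGCCGAAC
AGGGAGGTGGTCAAGACCCACGTCGCGATTATGTGGTCGGCAAAGACTCACCCCGGATCC
TCCTGGGCGACATGGATAGGCAACGGTTGAATGGGTCTAGTGCTAGGGGGTAGTCGGGCT
CCCGTCCGCTGGAACGTGGGTTTGGCATCGGCTCTGCTAATCGGCCAGGTGGTGATGGCC
AGATTTAAATCGGGTCCCCCCAGGTGCCGGGCCCCAAACTAGACCATGGTAACTTCCTCT
CTGACGGGTTTAGATTGTATGGATTCCCGCCTTGCATTTTCGCGTCTACGACGTGCAGAC
TATCACCGGTTCTTTTCGCCATGCCGCCATCCACCGTAGACAAGATGGTGACCGACGCTT
ACGCCGGACGAGGCTGTTTGGCTACATGATTCATCAAACTGCGAGCCCCCGTATGGTGGG
CAGTGTCCCCAAGGGGGACCCACAACAAGTGGCGGAGCAAGCACAGGCCATCTACGTCGG
ATTGACCGCTAGTCTAAGGCGGGGCAGGTAAATGCGGCAATCACCCTAGCTGCACAGAAC
AACCCTCATGCGGTAGGGGTCACATTGGCATGGGGGCTGAAGGTATGAGGTTATCACGGT
TGGGTCTTTAACTAGGTCCCGTTCATTGCAGGCGGCGCGGGAGCAGGGGTCAGTGATTTC
AAACGTAGTCTTTTAGTAGTGATTTTCCACTACGATGTGGGCGACGTAGCCCACTACACT
CGTATTTGTTCCGTCCAATACCTAAAATTTGTTTCCCAGGTCACCTCAGTTGTCCTTTGT
GATTCCCATGGTGATGTGGCCTCCAATGAGACAAGGCGGTTTCATAGCAATCCGGGAGGC
GGCAGGCCCAGGCGTTGTCGAGATTGATCATTCGGACGCCGACCTCGGTCCGAGATTAGG
AACGCGGCTACGCTGTCCCGGGGCGCATCTGAAATACCAGTACATCAGGCTCCTCCCTGC
TCCCCCCCTCGTTCAGAGGCATCGCAGCACCCGAGCTAGAACATCCCGTAGGAGCGCCCG
GGGCTGATTTGTCTCTGAGCTTAACTCCACTGCATGATGCCAAAGGCTGGCCGTTCGGTC
GCGGTGTCACACGGGCGCGGCGACAGCCGTGACGGGTCCGTGAATTACGCGGGGAGGGGT
CCCACTAATAGGACTCCTAGAAACAGAGTACGCTCGTATCACGACTGCCCCATATCTTGT
AGACAGCGCCTATGTACCCCGTTCCGCTAGCAATGCTGTTTTCCGCGGTGCTACAACCCG
TGCACCTCGCGCGCAACCAGATGCCCGGTCTCCTCGAGGCCTGCCTCCACCAGACAGGGA
GCTGACTCGACCCGAAAACTTAGGCGCTGTGCAATGCCCGATTGTGGGGCCGAACACCTA
TCCCTCCTAAACACCTGTGGCCGAAGTGGGATGCTGAGGGCCGGTCCTGCCTAAAGACGC
AGCGAGTGCGCCCACCCACTAGGGCGCGAACAGCGCATAATGAATGGGAACTCGTCGGGT
CGCGGATAGTAGGCAGGCAATCCTTGGCGGGAATTTGGGGTGTACGTGCACCCCACCCTC
CTAACACAATTATGACGGAGGGTGCATATGTTAATGCCCCGTATTTTATCTAGTCTGTAC
GGCCCTACCAGGGTGATCTATTCCCCCATAACGTATCAACACAGGCTCGGGACGCCTCTG
TTCGCCCTAAAAGAGCGTCCACATAAAATCGGCGAAGGATTATGGGACGTCTCGTTTCCT
TCAGGCGGAAGGCCCGTCCGTGGGAGCCAGGTCTACCAGAAGATGAACCTCCGAATATAG
TGGCCGTTGTGCGTAGTCCGCACATAACCCCTGGGATGAATCCGACGCACCACGGCTCGT
CTAGAAACAAAATCAAGCGACGCGTTGGGTGTCCTTTAGTGGTGCGTGGTTGTGCACCGA
CTGACCCTGAGACCAAGTTGGTGTGAATGAATCTCCAAAGGGCCTAAAGACCTGGTCACG
CATAGAATCATTCCGTTGTCCACTCCGGCACATCCCGGATTTGCTGCGGACCCTGATTGG
GCCGCCGATCAACACTCACATGTAACGCGCCATACGTTCGGCTGCGCCTCTACTATGGAG
ATACGTGCATCTGAAGCGCATGATTACTCAGAGTCGGGAGGCCAGCAGGAGCGAAACCTC
GACGATCAGGAGAACGGGCGTAGCGAGAGATACGGTTAGGAGGAATCCTGGACATCTGGA
CCGGTGCTGGTTGGGGACCTACACCAATAAGCGCAGCTAGACACGCGTAGAAACTCACGA
AGACTAAATTCAGACGGCAATCCGGCACTATTTTGCCTATCCACTTGAGTGCACGGTTCG
ACTCCCAGATCGGGCAGCGCAGGGCGGTGGTAACAC
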