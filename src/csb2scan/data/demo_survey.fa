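>syn00000 synthetic demo record; planted G6AG8
GTTAACCTTACTATACTCCCGCTCCGGGGTTTGGCTCATATGAACAAGTCTTTGCGCCCATAAATGTAGC
CAGTGAGCTTAGTTGGAGCAAGGGGTGCGGAAGCGCAACTCCGTCGCGCGGGTAGCCAACTACTTAAGAC
CTAGGATTCTGTGTTTAAGTGCTGTGGCCAGAAGCGGGGGGAGGGGGGGGTTTGGTGGAAATTTTTTGTT
ATGAGTTGCAGATTAGAACTTGGGACTCAAGATTGCTGCCCTAAGCTATACTAGGCAGCTGCAGCGTCTG
GTTTTACTCAGTGTGATCTTTATGCTTGAGAAAATCAACCCTTGTCACATACATAGTGTTTGGGTCTTCC
GTAAACAGGTGCTT
>syn00001 synthetic demo record; planted G6AG8 (reference strand)
CGACAATTCGGCATAAACAGCTCGATTATCACCTCCGGTAAACTTCGGCAACATCCTGCGGAATGTTACG
AAGAGCACTCTATCTAATTTGACAAGTCGAGTTCTGCCGGGCACCTTAGCTCCAGAGTGAACCTTCCGTG
TTAGAGCTGGTCATAACAAAAAATTTCCACCAAACCCCCCCCTCCCCCCGCTTCTGGCCACAGCACTTAA
ACACACAACTCGTACGCGCCTGAAAATGAGACGGATCGTTGAGCTTAAAGATTGCATTCTCGACCAACGG
TTCTTTCGTTCATATCGGTGTTTGAACAACACAATACAACATGCTCTTCGCTGAATGGCGCTGACCTCAA
AGTGTTTCGCGGAA
>syn00002 synthetic demo record; planted G6AG7
CACTCGACTGAGTCATCTCCTAATTTAACGTTCTCACAGTAAAAGGTCTTTACTTATTAACCAAACCCCG
ACGATTCTCTGAACGAGACATGTAAAGTGCTAAGTCCGTCTGGGCGTCTTATCACACAGTTTAAGTTAGG
CCGTTATCCGGTGTTTAAGTGCTGTGGCCAGAAGCGGGGGGAGGGGGGGTTTGGTGGAAATTTTTTGTTA
TGATAGATCTTATTTTTTGCTGGTGCCCAATTACTTGTCTTGACGCAATCGCTACGTCGTGTTACACAGA
TGCCGCAAGGTAAGGTAGTTCCCAGGGTGTATGCGATGATCAGAGTATGCAAACTGAGCTTTGAGCTACT
GATCGGGCCAGCC
>syn00003 synthetic demo record; planted G6AG7
ATTGACATTCCTATTCTGTAGCTTCGCGTGTGCGCCAACCGCACGTGCCCTCAGTTCTTCCCCTCCTGAA
ATACGCAATCCTCTACTTGCTCGGCAGCGGTTGAAGGTCCAAAGGACGCCCGTCCCAGTGAAATCCTCAC
CAGCTTCGTAGTGTTTAAGTGCTGTGGCCAGAAGCGGGGGGAGGGGGGGTTTGGTGGAAATTTTTTGTTA
TGAAAACTTCCTTCGGGTTCTACACTCACAACCAGCATACATCTTAAAACATCTAACAAACTTGACGACT
CCTGAGTATGGCAAGTGCTTAATATAACCCATTGTTTCGTGTGCGATTGTCCGCACGCGGCGTTTACGAC
AGACCTCGTACCT
>syn00004 synthetic demo record; planted G6AG7 (reference strand)
TGGCCGGTGCTATATAGTTGTGCTCCGGTCAGTGAAGGAGTAAAACGATCGGCCCAGTTATAAGGGTCGC
TCATACTCTGTCACAATTCTCGCCGAGGGGCACATCAACCTTGACGTGCAATCAACCCGACCCCATCTTT
TTGCTGGAAATCATAACAAAAAATTTCCACCAAACCCCCCCTCCCCCCGCTTCTGGCCACAGCACTTAAA
CACGAGGAGGGTAACGTCGTTAAAGCATGAAGAAATGTCCCCTGCAACGTGGATCTTGCTATCGCGGGGA
TGAGGCATTCCAGTTGTCTCGGTCTCAACGAACGGCCGACAACGTTCATCCTGCATCAGTGCCGAAAGTT
ACTATTTTAATTG
>syn00005 synthetic demo record; planted G6AG7
ACCTTCATGTCCAGCCCATCCGTTGACGTCTACTAGAAATTAGATCATTACTCGTACGTCTGCGTGGTGA
TTCCGTGTATCCACCTCTGCCTGCGCATACCCACACGAAATTAGCGCTGAGAGCCCGTGCCCCGTACATG
ATCCCGGAGCGTGTTTAAGTGCTGTGGCCAGAAGCGGGGGGAGGGGGGGTTTGGTGGAAATTTTTTGTTA
TGATGTCGCTGTGTAAGAAGTCAGCTAATGCCGATCTTATGTGCGCCGCTACAGGAAGATCGAGAATTCT
AGGTAGACTGTAGTATCCATATAAAGGAACAGTCCGCAAGTGGAGGGAATCAGGTGTTGGGAAATCAAAC
GTTTTCCGAGAAT
>syn00006 synthetic demo record; planted G6AG8
TCTCCGCAGCTAAGGGGTTTTCTCTTCGAAAACTGGGAGGAGGCTTCTAAGACCGTTGTGTGAACTCACG
TACCCTCGCACCAGCAGCGATGGCTGTCTGTAGTATTCGCGTGCGTGCTGGCGGATGACTGGCCTCTAGC
CGAAGGATCTGTGTTTAAGTGCTGTGGCCAGAAGCGGGGGGAGGGGGGGGTTTGGTGGAAATTTTTTGTT
ATGAATGTTAATCAGTCTAGCGGAAGTCGACAATTTGATACCGATATGCCACGATGCCTCTCGTTACGCC
GTCCTGCTGGTATAATCAGCCTGAGACATAGCGGACGATTGTCGCAAGAGCCTTCCTGGAGGATGGTCTT
GGTCTCTTGATGGG
>syn00007 synthetic demo record; planted G6AG7
ACTCTTTCTGTCGTTTAAATCGCATCCAAGTAGCGCTGATGTTCGGCATCATCACTGGCCCTTCCTTACA
CTGCAATGACGGGGATGATGATACATTACTCGGTGTATCAAGTACCTCGGCGATTACACCTTCGCGTTAG
TCGAACCTTGGTGTTTAAGTGCTGTGGCCAGAAGCGGGGGGAGGGGGGGTTTGGTGGAAATTTTTTGTTA
TGAGAACCCGGCGATGCCCCGTTAGTCGTACATGCAACTTCCTAGGGTACTCACTTTCCAACTGCCACCT
ATCAGGTGTAAGCTCTTTATGCTACTCTGGCATAAAAGAAGACTTCTTTACGACCTTCTGACGGTGTCGG
TTTTCTACGGAGC
>syn00008 synthetic demo record; planted G6AG7
TTTCCTTTACTCTAATCACATTAGCGGGAATAGCCAAGAGTGTGGAGAATTATGGATTTAGCCGGGATCG
TCTACGTTCACTAACCCGGGCTCGGCGGCCGCTCACTCCATACCGCTTCTACTGATTCAGGCGGTTTAAT
TGCTAGCTGCGTGTTTAAGTGCTGTGGCCAGAAGCGGGGGGAGGGGGGGTTTGGTGGAAATTTTTTGTTA
TGATGCCCGCGGAGATTATCGACAGGACGTGAGACCATGACAGCCAAAGGGATGTAAATCCGGCCCCCCC
GGGAGCGTCAGCCGGACCGGAACTAACCATGTTGCAACGGACTCAACCCAAACTCCGCTCCTTGACGCCC
CCTCGTATCATAT
>syn00009 synthetic demo record; planted G6AG9 (reference strand)
CCATGCTAACCAACTTTATAGGAGCAGAGGCGATATGTTACTAAAAGAGGTTTACGCCCCGGGATCATGT
GTGCGAGTCTACCCAGTCTGTTTGGGTGACATCTGTCAGCAGGCCTTGGGCCTATCGAAATCTACATGCT
ACCCATGAGCTCATAACAAAAAATTTCCACCAAACCCCCCCCCTCCCCCCGCTTCTGGCCACAGCACTTA
AACACTATGTAGACCAAATTGAATGGGAGGTGGTCCGGCGCACCCACAATAATGTTCCTTGACCGCGAGG
AGAGGTAGTGCCGCCGCACCGCTCAAATCCTAAATACATTCGTTCTACCGTTGGTCGCGTTAAGGCTTAG
GGAATCAGCTTCACA
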