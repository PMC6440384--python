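>TRGV1
GATCGCCTACCGGTGCAGTACCCACCGAGCCTACCTGACGGGGGGGTCGTCTATGGAGCAGGCATTAACTTCGATTGCGAAATAGCAGGGGTGAGAATAAGTTCACTCATGAAAAGCAGGGTAGTTACACGCTGCGCTCTCAGCTCCTCA
>TRGV2
ATAGTTCGTAGATGCCTATACCTTCTCAGATCGCTGCCGACCCAGGATGGGACATACTTTCAGGCCTTAAACCGAGTCGTGCACGACTGGAGTCGTCTCAGCATGGCCTGCATAGTCATTGCCTTGAGTAAATGTCGGTTAACGGGTTCG
>TRGV3
CGAACGCGTGCAGATTTCCCCTATACCGATTTAGTGAGGGCGTGTAGCTGCAAGGGTGCACGACTAGAACATCACGAACCCGCTATCAACGGGGACATGAGACCGCCTCCAGATCCTGTTCTTCCCCAGCCTTGCTTTGACTGTATCCGA
>TRGV4
TGGGTCGGTTCCAGTCATGCCTCCATTTGCCCACGGAGTCTCTTCTTGGAACCTTGTAGTCTAACCCCGGATACTGCGGGGTATTATTTAGAGCATGTCACGTACCCAGCACACTTCCATGATTGTGATACATGCCCCGTATCTTCCGTT
>TRGV5
ACCGCAAACGATCCATACTGGGCTCCGCACCTATCTAGTTTGCTGAATAGGGAGGGACGGATAGATCAGGACGCTATAGTAGGAGAGGCGGCTGGCTTCGTTGCTCATCCAACAAACCGGTCAGCGCAGAGCTGTCCAGCGAATTGTGGT
>TRGV5P
GGGAGTGCTGTGGTGCCAACGCTTAGGACGGATCCCCGGTGTCCTTTTACGTACCCCTGGCAGTTCCTTTATTACATTTTATGCGTTTGTCACTCCTTGGAGGTGGCAAATATCTCCCAAGCAGTTCGTCCATGTAGAATTTGGAGCTTG
>TRGV6
CCCGGGCCAGAATTAATGTATCGATTCAACCAGCGCCTTACCCACTCCCCAGATTTTTCTCTAAATTGGTTGCCGCGTTACAGTCGGCTTCCGGACTCCCGAGGGGACAAGTCTGTAAGAGATGAGGCGGGGTGTGGAACAGCCAGTAGT
>TRGV7
TGGATCTGTGGGCCCAAACTGACCGCTCTACTGTGGCTTCCAGAACTTTTAACCTTACCCATCGGCGCGATGAAGCTTCCCCGGAATCAGACGGCCGGCTGCTTGACGTATATGAGTGAATCATTGGTACGTTGCAAGTCAGGACTATCT
>TRGV8
CTTTTACCGGGCGGTGCCGACATTGGCCTGTCCTACAAATGGTATGAACGGGTCCACAAAAAAACAACCCAGTGCAGTGTGGTAGCGATCGATGATTGTGGATGCCTTGTTCGGCCTTGGCTGTACCCAGGCTGCGCACCGACAAGAACT
>TRGV10
TTATTGTGTAGCTGGGTCCGGGACTGTGATTTACTCCAGAAGTTTATAAGGTACGTCCTTCCCAAGCGTATCAACTACGGATCTGATCTTAACCAAGGTTACGCACTGCGACGAAGAGCTGTGGAGGAGATGTGCCAGTACGGGCGTGAG
>TRGV11
AGTATGGGTTCCCAAGTCCGACCTCCTAGCCACTCACCTGATATGGACGGCGCTACCATTTTTAGTGTGGGTTGTGTGCAAGGACAGCCCCGACTCAGATTAAAACTAACCCCGCCTTACGAGGTTTCGTATTGCAGTCCCGTTGACCCG
>TRGVA
GTCTCAAACGACGAACCATGTTTAGAATTCTCGAGCGGAGTTGAAGTTGGCCCCAGTCAGAAGCCAGTGCGCTTATCTAGCGAAAAACGTGCAATTTCAAGTGAAAAGGTGGTGGGTTCTCCTTTATGGTGCTGCGCCGTTGATCCGGAT
>TRGVB
TGGACTGAACTACCTAATTTCAGGATTCCGCTAGCGCTAATTCATTGGTTAGACTACAGAGAGAACGTGACGATGCCAACCGCAGATTGTATCAAGCCCTTGGGTAAAAATCAAAATACGCGTGTCCTGAGTTGCATGGAACATTCGCGC
>TRGV9
AAGGCCGTCTCGTGCCCGTACATGCTGGAGCCCGGCGGAGAAGGCTACGATATGATAGACTTATGCCGCATAATACCCTCGGCTAAGGATCGAGACGATTGCTACGCGCCTTGGTTACCGAATTCGCAGAGATGTGCCCTTTGGGAGGTG
>TRGJP
CAAGAGTTGGGCAAGAAGATCAAGGTGTTTGGTCAAGGGTTGATTACT
>TRGJ2
AATTATTATAAGAAGCTGTTTGGTAAAGGGGGATCCGCC
>TRGJ1
AACTACTACAAAAAGCTCTTCGGAAAGGGGCGTTCAGAT
>TRGJP1
CCACCACCGCTGCAGTTAGAAAGCTTTGGTCCAGGGGCAAGAATG
>TRGJP2
CCGCCTACGATTACGGCAACCGTTTGGGGTGCCGGCTCGACTGCT
>TRGC1
TTGCCCATGCGAAAGCCAGGTTCTTTTTGTTACCATTTCCAGGGACAAGAGTAGTATCTGGATGCGCGCTGGTCCGTATTATGGGTTCGGATCACCGTCATCTCCCCGCCGCATGAGTTATGTCGGGGAGCGAAATGTCGTTGATTGGATGGAGCGGCAAATCTACATGTGTAGTTTGTTAGCTCCGGGGGTGAGTCCACCCTGTACGGCGGCGGCCTTAGGGAAAAAGTACTATACGACTGCCCCCTTCTTAACGGGAAGAGGGCGCGATGATTTATCCTTGCTCTTCCGCTTTCGGGCTTGAGGCGCGTATGCAATATAGTCGTCACCTTTTAAGTGACTCCTCATTTGAACAGGTTTTGTTCACATATATTGGATCGGAAGCCGAGGTGGGCACATCGCACCCGGCATGGAGGGCAACTTACGCCGGCAACCAACCCCACGTAGATT
>TRGC2
TTACCCATGCGAATGCCAGGTTGTTTTTGTTACCAGTGCCAGGGACACGAGTAGTATCTTGATGCGCGCTAGCCCGTATTATGTGTTCGGATCACCGTCATCTCACCGCCGCGTGAGTTATGTCGGGGAGCGAAATGTCGTTGATTGGATGGAGCGGCTAATCTACATGTGTAGTTTGTTAGCTCCGGGGGTGAGACCACCCTGTACGGCGGCGGCCTTAGGGAAAAGGTACTATACGACTGCCCCCTTCTTAACGGGAAGAGGGCACGATGAATTATCCTTGCTCTTCCGCTTTCGGGCTTGAGGCGCTTATGCAATATAGTCGTCATCTTTTAAGTGACTCCTCATTTGAACAGGTTTTGTTCACATATATTGGATCGGAAGCCGAGGTGGGCACATCGCACCCGGCATGGAGGGCAACTTACGCCGGCAACCAACCCCAGGAAGATG
>TRDV1
AGCAAAAGTCGCGTGCGAACTCCCTACTCGATCCGCATTTTTCGGCCTTTTTTCCTGGGGTTCGATTCTAAAACCGCCTCTACTACATGCGTTTATAAATGGCAAACAAGCCCTAGTAAGAACAGTGCAGGCTGTAGGGAAATATACATT
>TRDV2
GGATATACTTCTACGGGCGGTCTAGTCCCCTCAGACCTAGACAAACCAGTCCTAAGTACGAATATACCAGTTGCGATTGTGAGAGGACTAGGGAGGCCTCACAGCTTTGAAGCAAACGCGTTACCTGCTACCTGTGCCTGTGACACCGTG
>TRDV3
CGATGCCCTCCTCCATTGCAGCACGCACCAGATCTGGCCCTGCCTCTTCGACCCAAACTGGGTACTTATCGAGTAGAGATCCTAGTTGTTATATGCGAACTTTTTTTAGCATTGGATTCATTGGTGGACCTCTGCGAAGGCTACATTGGC
>TRDV4/TRAV14
AGACTTCCAATTTCGGGGGATCTGATAGTTAGGTCCGGCGCAAACGGACTGTGCTCTCCCACCGAAAAGCCATTCGTGGCGGTAAACGCCACTTTAGATAGTAGCCTCCACGTACTAATAGCTTCGGGCGGATGTCGAACGAATGATTTA
>TRDV5/TRAV29
TCCTACAGGGAGGCGCCCAGCTCTTGGTCGGGTGCCCATTCAGCGACCTTGCGTATAAGGCAAGATATCGCCATGGTGATATGCCATGCTGTTATTTGCGATTACAACGCAGCGAATGACATCATGTTGGGGTGCATCCAGCGGGCGTTG
>TRDV6/TRAV23
CAGTATCTGGCGTCCCCCGCTTTTATTGTGGTCCCCACGTACGCAGCGGGCTTTGCTCCCGGACGTAAAGGCATGGCTTCAGTCTGCTTTCCCATATTAAAACCCCCTTTAAGACGAATGAGGTCAGTAACCTGTTCGTCTTCCCTGCAC
>TRDV7/TRAV36
CCCCCGGCGCGGCCAGCGAGTCCGCCAATGTGTACAGATCCAAACGGTAGATTAGTTAGTCATGGACGTATTCGTCATTCAGCCGACGATGTGCTATGGACCCATCTGAAATGGCCAGCCTCCTATGGGTCGTGTTGTACGACCTACCTT
>TRDV8/TRAV38-2
TTTGGTCCTCTTATCTCGTACACTTACGGTTCTTATCCACTCCTTAGAAGCGATGTATGCAGTATGGATTCCGGGGCTCTCACTTGGTCGAATTATCGCAAATTCCGGGGCGCGGAGGCAAATGTGTGTTGGTGCAATTTGGCAAGCTCG
>TRDD1
TCAGCGCG
>TRDD2
AACCTGGGT
>TRDD3
TCTCCTCAATGCT
>TRDJ1
CATGGCGAAGTCGCTCAAGACTTTGGTAACGGCGATCGCGGA
>TRDJ2
CACGATTGGGCGCAAAGCGGGTTTGGATGGGGGCGTCGGACA
>TRDJ3
TTTGCAAAATGGTGTCTAATGTGGGGAGTGGGGGCCCCCCTG
>TRDJ4
GTGAGACCCCGGAAAGCTTTTGGTACAGGCAGGGCAACT
>TRDC
AAAAACGCCGAGAAGTAGATACCACCTCGTCGGGCTCTTGAAGCCTATAGGTCGACGACCGGGTTGGTGAAACGCTGTGGGAGTGGGGCAGGGCTTCCGGTCTCCAAGATTCGCATCGACGTCATTTTTGCGATCATTTATTAGGGAGGTAAGCAAGTTCTCCTGGTCGTTATTTCCCTCTCGGCCCGCCTGCCAGTTACTAGGAGTTAGGGGGCGGGTCTCTCCTGAGAGCTGACTGTCTTGGCTCGATAAAGCTGGTAACCCCTGCACGTAGTCGAATGGCTGGGTTTAACCTTAACACGCAATACCCTAGCTAATGGCGTAAATATTTGCGTACGCTCTCAACTAGGATGCACGGTATATAATCGCGCTTTACCATCCCCAGCTTGAAGATGCAACGGGCGCCAGTGTCGAACTTATGGAGATCCACCAACACACAT
>TRAC
TAAGCAGTCCGGCCTTGGCGCTCCACCGTCGTGAAGCTGGAATAAGGGTTGCATCAAAGTTTAGACCTGGTATCAACGTAACCGTGTGCGAGGCACAAAAAAGGAGACAAGTCCACCAGGTGCGGTTAGCCGGCTAACCTGGATTAGCGATATGTTTTGGAACGGTATTCCAAGCATACGTGAAGTCAGTCCTCATTTTCTTCTTGTACTCGCCACTCATATCAAGTGAAACAAATTAAAGAACCGCTGCTGAACTCGCGGTGGACCGCAGTACAGGTGGTTGCCACGTGCTAAGTCAAGTGTCCCACATTAAATATAACACTTCTTCTTCTCACTGATATGTAGCGATAACCCGGCTAAGGAAGGTAGGTGAACGGGCAAAAACACCTTTATCATACCCCCTCCAGGCTGAGAAAACCA
>TRBC1
AAAACAAACTATTGAATACACCTTATAGTGCGTCGCGACGTGCAGTTTTTTTGATCTCATTTGAACCGGTTAGAAAGATATCTGAAGGCTCGCCTAGTGTTGGCGATCAATTAGTCGCCCCTCTATGCACATTTCGGAAGCCTCACTTGGATAGGGAAATTCGAAAGATAAAAAACGAGATTACACCCACTTTACCTGTACGCCGGATGTGGGCTCGAAAATACGGACAATCCTACCCACGCCTAAATGTGGTTATTAAGGGTCTTGCTAAGGATCTCACGAATATAAGAGAGAGGCACTGGTACCGTAGGGTCACGGTGCCGCTGATCGTACCTTCACAAACGGTTCCTCTGGTGCTACCGGATGGCACAGCGGTCAACGAACCGATATCCGGCGCATCATGCGAGCCTCGATTAGTCTGGGTGTAACAGGAAGTGGTCTCAGAGACGAGGGGATGGGCCACGGTAGCAAAGGTTGGGGGACGTAGGCAATTAGATACG
>TRBC2
AAAACAAACTATTGAATACACCTTATAGTGCGTCGCGACGTGCAGTTTTTTTGATCTCATTTGCACCGGTTAGAAAGATATCTGAAGGCTCGCCTAGTGTTGGCGATCAATTAGTCGCCCCTCTATGCACATTTCGGAAGCCTCACTTGGATAGGGAAATTCGAAAGATAAAAAACGAGATTACACCCACTTTACCTGTACGCCGGATGTGGGCTCGAAAATACGGACAATCCTACGCACGCCTAAATGTGGTTATTAAGGGTCTTGCTAAGGATCTAACGAATATAAGAGAGAGGCACTGGTACCGTAGGGTCACGGTGCCCCTGATCTTACCTTCACGAACGGTTCCTGGGGTGCTACCGGATGGCACAGCGGTCAACGAACCGATATCCGGCGCATCATGCGAGCCTCGATTAGTCTGGGTGTAACAGGAAGTGGTCTCAGAAACGAGGGGATGCGCCACGGTAGCAAAGGTTGGGGGACGTAAGCAATTAGACACG
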