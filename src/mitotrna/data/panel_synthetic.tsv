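identity	species	sequence	loop_start	loop_end
trnA	sim_sp1	GCTGCTGCTGTTACTCAAAAGACCGTTATGCGCCCAGTTAACTGCCGC	26	33
trnA	sim_sp2	GCGGGTGCTGTAACTTTAAAGACCGTTATGCGCCCAGCTAACTGCCGC	26	33
trnA	sim_sp3	GCGGCTGCCGTTACTTAAAAGACTGTTATGCGCCCAGTTACCTGCCGC	26	33
trnC	sim_sp1	GATATTCGGTGTTAGCACAAGTCAGATTTGTGATTCTTTTTACAAAGATGTTC	12	19
trnC	sim_sp2	GATGGTCGGTGTTAGCACATGTCAGATTTGTCATTCGTTTTACAAAAATGTTT	12	19
trnC	sim_sp3	GATGTTAGGTCTTAGCACAAGTCAGATTTGTCAGCCGTTTTAGAAAGCTGTTC	12	19
trnD	sim_sp1	AACCCGATTTTTGTTCTCGTTAAATATATCCGGTCCACACACTGTATCCTGCTT	30	37
trnD	sim_sp2	AAGGCGGTTTTCTATCCCCATAAAAGTATCCGGTCCACACACTGTAGCCTGCTT	30	37
trnD	sim_sp3	AAGTCGGTTTTAGTTTTCATTAAAAGTATCCGGTCCACACACTGTAGCCTGCTT	30	37
trnE	sim_sp1	TGTGTTGTTAACATTCTGTCTTCGACAGAAGGATACGAACCGCATTCTATGCAACCGACACA	18	25
trnE	sim_sp2	TGTGTTGAGAACTCTCTGTCTTCGACAGAAGGATCCGGTGCGGATTCAATGAAACCAACACA	18	25
trnE	sim_sp3	TGTGTTGACAACTTTCTGTCTTCGACAGAAGCATACGATGCTGATTCTATGCAACTAACACA	18	25
trnF	sim_sp1	TGACGTTATCACAACTGCATATGATTAAAGTAAAAGCGTTTACTTATGACCGCGA	30	37
trnF	sim_sp2	TAACGATATCACAACTGCATAAGATTAAACTAAAAGCGTTTAGTTAAGACCGCGA	30	37
trnF	sim_sp3	TGACGTCATCACAACTGCATATGATTAAACTAAAAGCGTTTCCTTAAGACCGCGA	30	37
trnG	sim_sp1	GTCCGCAGGTGGGCTTATCCTGAGCCGTTGGTCTCAAGTGTGGGTCTGAGGCA	15	22
trnG	sim_sp2	GGACGCAGGAGGGCTTATCCTGAGCCGCTGATCACAAGTTTGGTACTTAGGCC	15	22
trnG	sim_sp3	CGCCGCAGAAGAGCTTATCCTGAGCCGCTGATCTGAAATGTGGTTCTGAGGCC	15	22
trnH	sim_sp1	ACTACATGCCGCTGTATCAGGGCTCTTCTCGTGACGAAGCTAGGCGGTACA	28	35
trnH	sim_sp2	TCGACCGGCCGCAGTCTCAGAGCTCTTCTCGTGACGAAGCTAGGCCGTCCA	28	35
trnH	sim_sp3	TCGACCTGCCGCAGTATCAGGGTTCTTCTCGTGACGCAGCTAGGCGGTCCA	28	35
trnI	sim_sp1	ACATATATTAAAGCACATGGATACTGGGTTTAATAAACTGCCTCCGGATCCAATTTACTGCG	17	24
trnI	sim_sp2	AGATGTATTAAAGCACATGGATACCGGGCTTAATAAAATGCCTCCGGATCCAATTCACTGCG	17	24
trnI	sim_sp3	ACATGTATTAAAGCACATGGATACTGGGCTTAATAAACTGCCTCCGGATCCCATGTACTGCT	17	24
trnK	sim_sp1	GCTCCACTGAACATCTCACAAGATCTTCAGTATACTCGATGTATCAATGGTTG	22	29
trnK	sim_sp2	GATCCATGTACTATCTCACAACATCTTCAGTATCCTCGATGTATTATAGGATC	22	29
trnK	sim_sp3	GATCACTTGACAACCCCACAACATCTTCAGTACAATCGATGTATCCATGGATC	22	29
trnL1	sim_sp1	ACTCTTCAGGTAGTCTATCCTATGGAAGTAGACTCTATAGAGAAAAGT	26	33
trnL1	sim_sp2	ACTCTACAGGTAGACTATCCTATAGCAGTAGACTCTATAGAGAATAGT	26	33
trnL1	sim_sp3	AGTCTTCACGTCGTCTATCCTATAGAAGTAGACTCTATAGAAAAGGGT	26	33
trnL2	sim_sp1	CAAGTCCGACTAACGTAACAGGAGTGTCACATATATGCGAAGAACCG	13	20
trnL2	sim_sp2	CAAGTCGAACTAACGTAACAGGAGTGTCCCATATATGGGAAGAATTG	13	20
trnL2	sim_sp3	CGCATCTAGCTAACGTAACAGGAGTTGCCAATATATGGGAAGGATTG	13	20
trnM	sim_sp1	CTTTTCAGTGTTAGATAGCAACCTGGCCGCATCTGCCACTGTACCTAATAAG	27	34
trnM	sim_sp2	CTTTTCAGTGGAAAATCGCAAACTGGCCGCATCTGCCACTGTAAATAAAAAG	27	34
trnM	sim_sp3	CTTTTCAGTGTAACATAGCAACCTCGCCGCATCTGCCACTGTACCTAATCAG	27	34
trnN	sim_sp1	ACGTTATTAAATATGGAGTCGTTTTCTTCCTCTAACTGGATACGCGTAAGCGTTCGT	18	25
trnN	sim_sp2	GCGTTATTAAATATGGAGTCGTTTTCTACCTCTAACTGGATACGCGCAAGAATTCGT	18	25
trnN	sim_sp3	ACGTTATGAAATATAGAGTCGTTTTCTACCTCTAACTGGTTACGCGTAACAGCTCGT	18	25
trnP	sim_sp1	AATACACACGATTATCTTTGAGTCCACCTGGTAAGGAATATTTTGAATT	26	33
trnP	sim_sp2	AATACACATCATTATTTTTGAGTCCACCTGGTAAGGCATATTTTGAATG	26	33
trnP	sim_sp3	AAGCCACATCATTATCTTTGATTGCACCTGGTAAGGAATATTTTGCATC	26	33
trnQ	sim_sp1	CAAGTGACCTCGAACTTGATGCGGCGGTAGACCGGGGGACGGGCACGTG	13	20
trnQ	sim_sp2	CACGCCGACCCGAACTTGATGCGCCCGTAAGCCGGGGGACGGGCGCGTG	13	20
trnQ	sim_sp3	CACGCGGACACGAACTTGATGCGGCGGTAGGCCCGGGTACGGGCGCGTG	13	20
trnR	sim_sp1	CGTGAGCGATTTCTATCTAGACGTATCGAGCGTCTAATTGATTCTCACA	23	30
trnR	sim_sp2	ATCGAGAAATTCCTATCTAGACGTATCGAGCGTCTAATTGATTCGCACA	23	30
trnR	sim_sp3	AGTAAGAAATGTCTCACCAGTCGTATCGAGCGTCTAATTGATTCTCACA	23	30
trnS1	sim_sp1	GTTAACTTGAACCACGACCACTCCTCGATTACTATTTATAAGGATCTGTT	17	24
trnS1	sim_sp2	TACAACTTGCACTACGACCACTCCTCGATTTCTATTTTTAAGAAGGTCTT	17	24
trnS1	sim_sp3	AACAACTTGAACCACGACCACTCCTCGATTTCTATTTAAAAGAAGGTGGT	17	24
trnS2	sim_sp1	CGAGAGTAACGGTGGAATATCGGTCGGCTATTGAGCACCCGTATAACCCGCG	29	36
trnS2	sim_sp2	CGTGAGAACCGGTGGAATATCGGTCGGCTATTGAGCACTCGTATAACCCACG	29	36
trnS2	sim_sp3	CGTGAGTACAGGTCGAATATCGGTCGGCGATTGAGCACCCGTATAACCGACG	29	36
trnT	sim_sp1	ACTCAGCCCCATGCAAATTTTGGGTCATTGTTGTCCAATCCTATTGGAT	29	36
trnT	sim_sp2	ATTCAGTCGCATGCATATTATGGGTCGTTGTTGTCCAATCTTCCTGCAT	29	36
trnT	sim_sp3	TTTCAGTCCCATGCATATTTTGGGTCATTGTTGTCCAATATTACTCCAT	29	36
trnV	sim_sp1	CTGGATTTTTATTAGGCTGATACAGATCCTGATACTAGCTCGCATTGAATAGAGCTCATCTAG	18	25
trnV	sim_sp2	CTAAATTATTATTAGGATGATACAGATCCTGAAACTAGCACGTTTTGTATGGAGCTCATCTAG	18	25
trnV	sim_sp3	CTACATTTTTATTAGGATGATACAGACCCTGATAGTAGCTCGCATGCTATAGAGCTCCTCTAG	18	25
trnW	sim_sp1	CTACAATGACGTATCAGTGTGGATATAGTCAGGATATGTTGCACTTTTG	26	33
trnW	sim_sp2	TTACAAAGACGTATAAGTACCGATATAGTCAGGATATCTTGTACTTTCG	26	33
trnW	sim_sp3	TCGCGATGACCTATCAGTGTAGATATAGTCAGGATATTTTGTACTTTCG	26	33
trnY	sim_sp1	GTATCCGCGTAGTAAATATTGTATCTATTTTTTAATTAGTTTTACTGTGCATAGGACGTTTCC	18	25
trnY	sim_sp2	GGATCCGGGCAGTACATATTGTATCTATTTTTTAATTAGTTTTGTCGTTCCCACTGCGTTTCC	18	25
trnY	sim_sp3	GGATCCGTCGAGTAGATATTGTATCTATTTTTAGATTAGTTAGACTATTCAATCTACGTTTCC	18	25
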