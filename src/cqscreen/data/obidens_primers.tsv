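name	position	forward	reverse	size	tm
Mar1	Chr: 136,963,139-36,965,341	GTCCTCCTCAGTGAAGTCATTATAC	GCTCCTCCAGATGTTGTAGAGA	201	57
Mar2	Chr1: 36,964,139-36,964,341	TTCGAAAATCTCAGTGCAGC	TTGACAGTGAAGCTCCTCCA	386	57
Mar3	Chr1: 36,964,139-36,964,341	CTCCACCACATTCTGCAGTT	TTTGTGAATTGGCAGGAACA	492	59
Mar4	Chr1: 36,964,139-36,964,341	ACATGCAAGTGTGGCTTTGA	ACATGCAAGTGTGGCTTTGA	793	57
Mar5	Chr1: 36,964,145-36,964,340	CTCACTCTTGTCATGTCCTCCTCA	GAGAGTTGAAGGAAGACAGAAGGAC	195	57
Mar6	Chr8: 33,584,367-33,586,928	CAGGTTGGACTTCAGAACTTACA	ACGCAGAACGAGCAGGAA	267	58
Mar7	Chr8: 33,584,367-33,586,928	AATGCGGAATCTAAGAGCCAAT	CAACTGCCTCGGAAGAACAA	530	58
Mar8	Chr8: 33,584,929-33,587,296	TTCGTGTTGGCTCGGTCTG	AGTTCATCTGTCATTATGGCTATCC	554	58
Mar9	Chr8: 33,584,929-33,587,296	CAGGTTGGACTTCAGAACTTACA	ACGCAGAACGAGCAGGAA	267	56
Mar10	Chr8: 33,585,297-33,587,717	GGATAGCCATAATGACAGATGAACT	AGCACCAGAACGACCAGAC	499	58
Mar11	Chr8: 33,585,367-33,585,928	TTACCAGCAGCTGCACAATC	GGAATGCCAAAGTTATCGGA	428	57
Mar12	Chr8: 33,585,367-33,585,928	AAGGTTTTTGAGCCTGGGTT	GGAATGCCAAAGTTATCGGA	488	56
Mar13	Chr8: 33,585,407-33,586,707	CCGATAACTTTGGCATTCCACTCG	AAGGTATGCCCTGAGTTTCAGACC	326	56
Mar14	Chr8: 33,585,407-33,586,707	TGTAGTGTTCGTGTTGGCTCGG	AGTGTCTGTGGGAGCAGTTCAT	576	58
Mar15	Chr8: 33,585,929-33,586,296	CCACTCGGTAAGTCTGCTCC	CGACAAATGGGAGGAAACAG	370	58
Mar16	Chr8: 33,585,929-33,586,296	GGCATTCCACTCGGTAAGTC	CGACAAATGGGAGGAAACAG	376	57
Mar17	Chr8: 33,586,297-33,586,717	CTGTTTCCTCCCATTTGTCG	GTGTCTGTGGGAGCAGTTCA	490	58
Mar18	Chr8: 33,586,297-33,586,717	CTGTTTCCTCCCATTTGTCG	TCATTATGGCTATCCCGGAC	466	56
Mar19	Chr8: 33,625,278-33,627,696	GAGCGATTCAGAGACCAGAGA	CTTCCAGAGCACAACCATTACTT	566	56
Mar20	Chr8: 33,625,278-33,627,696	CTCTGGAAGCGTCTGAATGC	CCAACCACAACTTAATCTGAACTAC	231	57
Mar21	Chr8: 33,626,278-33,626,696	AGCGCACTGCCTCTCATACT	GCATTTCCCGACCTGTAAAA	358	57
Mar22	Chr8: 33,626,278-33,626,696	AGCGCACTGCCTCTCATACT	CTTGTGAAATATGCCTCGCA	375	56
Mar23	Chr8: 33,626,281-33,626,686	AATGGTTGTGCTCTGGAAGCG	CCTCGCATTTCCCGACCTGTAA	274	58
Mar24	Chr8: 33,626,781-33,627,375	CAAACACAAAAACGACACGC	AAGCGCTTTGGGTGTACAGT	453	58
Mar25	Chr8: 33,626,781-33,627,375	TGTTTCATTCAGGCCTTCCT	TGACTTTGACCTTTGACCCC	500	57
Mar26	Chr8: 33,626,781-33,627,375	GGATGGACTGATGATTCACTACAAC	AAAGCGCTTTGGGTGTACAGT	412	57
Mar27	Chr8: 33,626,781-33,627,375	ACAGTTCCAGTTGTGTCTCCACTT	TCTGATACGGCGCAATGAAGATCC	405	56
Mar28	Chr8: 33,626,816-33,627,324	AGTGATTCAGATTGGATGGACTGA	AACACTATATCCTGCACCGGATT	509	56
Mar29	Chr12: 6,143,157-6,143,771	TGGAGATCTCAAGTGCTCTTCAAG	ATGTGGTATTGCCTGGATGATCTC	451	58
Mar30	Chr14: 16,536,659-16,536,680	CCATAGCAACACCTTAGCAAACAC	GGGCTTTGCAATGGTGGTTAAA	320	59
Mar31	Chr14: 16,536,836-1,653,710	CCAGTAACCACTCAGATCTTCTG	TTAGTTGCTAGAGCATTGCTGTG	220	56
Mar32	Chr14: 16,563,469-16,563,648	TGGTTCATTCACACTGCCAGT	TCCATGCGTGTTCACTATAGTCC	204	58
Mar33	Chr18: 17,827,232-17,827,798	TTGAACGACACTCTGCACCT	TGAAGCTGAAAAAGCCACAA	837	58
Mar34	Chr18: 17,827,232-17,827,798	TTCTGCCAGTCTTTTCCTGG	TTTGAACGACACTCTGCACC	497	57
Mar35	Chr18: 17,827,812-17,828,407	AAGCCATAGCCCCTTTTCAT	ATCGGTGAGTCTGATACGGC	466	58
Mar36	Chr18: 17,827,812-17,828,407	ACAAAGCCATAGCCCCTTTT	ATCGGTGAGTCTGATACGGC	469	59
Mar37	Chr20: 2,906,171-2,906,720	TCAATTTCTCATGCAGTTTGC	AGCGTTGCACAAACACAAAG	402	59
Mar38	Chr20: 2,906,224-2,907,256	CTTTGTGTTTGTGCAACGCTGT	ACACCATGTTGAAATGCTTCCAGT	302	59
Mar39	Chr20: 2,906,721-2,907,377	CATGCAGCATCTTCTCCAAA	ACCAACAACCCAATAACCCA	387	57
Mar40	Chr20: 2,906,721-2,907,377	TCATTGAACCATCGGCTACA	ACCAACAACCCAATAACCCA	462	58
Mar41	Chr21: 10,711,992-10,712,371	TGCACTTCTGTCAATAGATCCTCTT	TCGGTCATCACCATCATCAGAT	401	59
Mar42	Chr38: 4,802,762-4,802,784	TCATCAGTCCACAGAACACTATCC	ACCATAGGAAGCATCATTCGC	350	56
Mar43	Chr38: 4,867,346-4,867,835	ACATTCATTGGACAATCTTGTCGG	AACAAGGAGTGGAATGAATTGCC	469	57
Mar44	Chr38: 4,955,599-4,955,622	TTATCTTGCTCCTTCATCCATCTCC	ACTTAATGAAGACAGGAGGCAATGG	248	57
Mar45	Chr39: 5,164,306-5,164,730	AAGGAAACCGGTATGTGCTG	TGTGCAAAAAGCAGTCTTGG	396	58
Mar46	Chr39: 5,179,355-5,179,609	TTTTGCAGCAAGAGCTTTCA	TTGCCCTTGTGGTAATGACA	423	58
Mar47	Chr39: 5,179,385-5,180,010	GTGCCTTACAAGAATAATGCTCTGA	CTTTGCCCTTGTGGTAATGACA	325	58
Mar48	Chr39: 5,179,610-5,180,093	TGTCATTACCACAAGGGCAA	AGGTATGGGGAAGGTGGAGT	371	56
Mar49	Chr39: 5,179,610-5,180,093	TGTCATTACCACAAGGGCAA	GGTGGAGTGCAGTGAGTCAG	359	56
Mar50	Chr39: 5,180,173-5,180,725	TGTCTTTGTTGCTGACCTTCA	GGCCATCTCTTGTTGGAGTC	399	58
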