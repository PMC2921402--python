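locus_tag	gene	forward_primer	reverse_primer
RNA_42	rnpB	64-AAGTCCGGGCTCCCATATG	135-TGTGGCACTATCCTCACGGTTA
PMM0285	phrA	1000-GGAGAGACCGGAGTACCTATAGTTGA	1088-GCGACTATCATCCTACATCTATTATGCA
PMM0395	sepF	397-GAAAGAGTCGGTGAAAGCATTTTT	470-GCCTCCTCTGGGAAAGAACTAGT
PMM0565	dnaA	492-TGGTGTCGGTCTTGGAAAGAC	568-CTTTCGCATCTGGATCAATTTCT
PMM0937	umuC	762-TCAAGTAAGTAGAAGCTTTGGAAAACC	889-TAGTAATGGCAGATGATTTTAAGCTTTG
PMM1054	ruvC	331-GCAGGCTCTGGCAAAGCA	407-TTTGGTGCACGGGTTAAATTT
PMM1077	sasA	430-CTTTTAAGAATGGTTGCACATGAATT	511-TTTGTCCTAGTTTTTGACTTTGAATAGC
PMM1262	lexA	227-AGATCTTTGAGGGAGTCCCAATT	299-TGGAGGTCGGAAAATGTTTCA
PMM1309	ftsZ	415-GGGATAGTAACCAAGCCATTTTCA	494-TCTGCTAATCTTGCAATCCCTTCT
PMM1342	kaiC	666-AGGAACCGTACATATGAAAGGAGAA	746-CTCATCGCTCCTAAGGCAAAA
PMM1343	kaiB	142-AAACAACCTCAACTTGCTGAAGAA	193-TAACAGGAGGAGGTAAAATCTTTGC
PMM1452	atpD	435-AATCGACCCATCCCTCATTG	512-ATTTGAGAGGCAAGACTAGCATCA
PMM1455	atpH	68-GCCCGGGCCTTGGA	129-AGGTTGGCGGGCAATACC
PMM1562	recA	319-GCTGAACATGCTTTAGATCCAGTCT	398-GTATCTGGCTGCGAAACTAGTAAATTT
PMM1629	rpoD8	726-CAAAGCTGGGCAGCCAGTA	820-CAGTCCATTTCGATTTGCTCATC
PMM1645	mutS	2281-ACAAGAATTGGAGCCGTAGATGA	2366-TGATTTAGTATTGATGCTGTTTCTGACA
PMM1697	rpoD4	746-CTCAAAGTGCTCCATGCGC	848-GATTGTTCTATCCATCCCTTCCA
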