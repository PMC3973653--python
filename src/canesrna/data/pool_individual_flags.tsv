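mirna	sequence	comp1	comp2
miR1439 I	ATTTGGAACGGAGGGAGTACT	+	+
miR156 I	GACAGAAGAGAGTGAGCACA	+	+
miR156 II	TGACAGAAGAGAGCGAGCAC	+	-
miR156 VI	TTGACAGAAGAGAGCGAGCAC	-	+
miR159 II	GGATTGAAGGGAGCTCTG	-	+
miR159 III	GTTGGATTGAAGGGAGCTCTG	+	-
miR159 V	TCTTTGGATTGAAGGGAGCTCTG	-	+
miR159 VII	TGGATTGAAGGGAGCTCTG	+	+
miR159 X	TTGGATTGAAGGGAGCTCTG	+	+
miR159 XI	TTGGATTGAAGGGAGCTCTGC	+	+
miR159 XIII	TTTGGATTGAAGGGAGCT	+	-
miR159 XVI	TTTGGATTGAAGGGAGCTCTG	+	+
miR159 XVII	TTTGGATTGAAGGGAGCTCTGC	+	-
miR162* I	GGGCGCAGTGGTTTATCGATC	-	+
miR164 I	TGGAGAAGCAGGGCACGTGCA	+	+
miR164 II	TGGAGAAGCAGGGCACGTGCT	-	+
miR166 I	TCTCGGACCAGGCTTCATTCC	-	+
miR166 II	TTCGGACCAGGCTTCATTCCC	+	+
miR166* I	AATGTTGTCTGGCTCGAGGTG	+	-
miR166* III	GAATGATGTCCGGTCCGAAGA	+	+
miR166* IV	GGAATGTTGTCTGGCTCGGGGG	+	+
miR167 III	TGAAGCTGCCAGCATGATCTA	+	+
miR167 IV	TGAAGCTGCCAGCATGATCTG	+	+
miR167 V	TGAAGCTGCCAGCATGATCTGA	+	-
miR167 VII	TGAAGCTGCCAGCATGATCTGG	-	+
miR168 I	CCCGCCTTGCACCAAGTGAAT	-	+
miR168 II	TCGCTTGGTGCAGATCGGGAC	+	+
miR169 III	CAGCCAAGGATGACTTGCCGG	-	+
miR172 I	AGAATCTTGATGATGCTGCAT	+	-
miR1878 I	ATTTGTAGTGTTCAGATTGAGTTT	+	-
miR390 I	AAGCTCAGGAGGGATAGCGCC	+	+
miR390 II	AGCTCAGGAGGGATAGCGCC	-	+
miR395 III	TGAAGTGTTTGGGGGAACTC	+	+
miR396 II	TCCACAGGCTTTCTTGAACTG	+	+
miR397 II	TTGAGTGCAGCGTTGATGAGC	-	+
miR398 II	TGTGTTCTCAGGTCGCCCCCG	+	+
miR444 II	TGCAGTTGTTGCCTCAAGCTT	+	-
miR528 I	TGGAAGGGGCATGCAGAGGAG	+	-
miR529 I	AGAAGAGAGAGAGTACAGCCT	-	+
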