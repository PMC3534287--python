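gene	forward	reverse	amplicon_bp
OsSRP-QKG	TGCCCCGAGCCGCATTCTAC	TTGCATCATAACCACGGCGG	359
OsSRP-LGC	GACACCGGCCGCCTCTTCTC	GCGCAGCCAAGGGTCATGAC	383
OsSRP-LRS	AAGCTTCCATACCAGCAAGG	GGAGCTGACCTAAGTGTGATC	395
OsSRP-FRS	GCTTATGGCTTGACCACAAG	CACTGCCTTCCATCACGTAG	451
OsSRP-PTY	ACGACGGCCAGGTCCACTTC	GCTATAGGTCGGGCTGCAAC	398
OsSRP-PLP	AGCAAGGAAAGAATGAAAGG	CAAGCCCATTGATACTGAAG	362
OsSRP-FAS	GCTTGTGTGAGCGCGAGGAC	GAAGGTAAGACAAACCGCGG	399
OsSRP-FLC	GATGGTGGTGACATCACTCC	CAAGAACTTCATCGTGCAGG	423
Actin	TCCATCTTGGCATCTCTCAG	GTACCCGCATCAGGCATCTG	418
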