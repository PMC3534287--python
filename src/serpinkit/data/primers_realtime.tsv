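gene	forward	reverse	amplicon_bp
OsSRP-QKG	ACATGCGGAAGCTGGGCGTGA	TTGCATCATAACCACGGCGGTG	167
OsSRP-LGC	ACAAGACGAACGCGGCGGAGAC	TGGTAGACGGCCGACACGACGA	133
OsSRP-LRS	ACGCGGCAAGTTACTGTCGGGC	TGCAGCAGCAGCCTCAGTCCC	228
OsSRP-FRS	GGCTGCGAAGCTGAACTCTGAAC	TCTCTGGAGAACCCACCATCCCA	197
OsSRP-PTY	AGCGAGCAGGAAGTCTCCCCG	GGCGGCGTGTTCACACTCACA	155
OsSRP-PLP	CCTCCGGGAAGCTGAATTCTCTG	TACTGTTCCAGAGACCTCCTCCC	220
OsSRP-FAS	TCAAGCCGTTCGTGGCGGACC	CGCCGCCGATGCGAAGGTAAG	170
OsSRP-FLC	AAGATGGCAGTGGCGTCGTCCG	CTTCATCGTGCAGGCCGTGG	303
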