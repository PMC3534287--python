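# Packaged curation recipes for the six revised rice serpin gene models.
# One op per line; landmarks are unique 4-6 residue anchors in the
# database-predicted protein.  expect_length is enforced after the last op.
#
# The PSG translated-intron segment has no printed anchor text, so its
# excise landmarks are synthetic stand-ins planted by the conforming-
# sequence builder; the segment they delimit is 30 residues, as documented.

[OsSRP-QKG]
# database model 423 aa; alternative START gives MAPP instead of MAAL (-25)
trim_n_terminal_to MAPP
expect_length 398

[OsSRP-LRS]
# retain 137 aa through FQTK, drop the 72-aa two-exon insertion WLLL..TSGK,
# retain 252 aa through VGHV, then swap the trailing 7 residues per cDNA
excise WLLL TSGK
replace_c_terminal AAEVLGQ VNPLLAA
expect_length 396
note second partial serpin (218 aa, LYFK..LLAV) is carried by a separate cDNA and is not part of this model

[OsSRP-PLP]
# drop the 45-aa N-terminal extension so the model starts at MPTRPW
trim_n_terminal_to MPTRPW
expect_length 394

[OsSRP-PSG]
# remove the 30-aa translated intron and the artefactual 5-Ala run
excise HWDQVN KNHWMD
remove_run A 5
expect_length 417

[OsSRP-PTY]
trim_n_terminal_count 117
expect_length 393

[OsSRP-PGY]
trim_n_terminal_count 126
expect_length 398
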