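# Conflicting locus assignments recorded verbatim from the source tables;
# the packaged locus table follows the reactive-centre comparison table and
# the supplementary locus list.  These conflicts are NOT reconciled.
name	field	value_a	value_b	note
OsSRP-PTY	locus_id	Os04g45110	Os11g12410	Os11g12410 carries code GAA in the comparison table; Os04g45110 is used in two other sections
OsSRP-PGY	locus_id	Os04g45120	Os11g12420	Os11g12420 carries code GRA in the comparison table; Os04g45120 is used in two other sections
OsSRP-LRS	locus_id	Os03g41419	Os04g41419	Os04g41419 appears once in the expression-survey text; Os03g41419 everywhere else
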