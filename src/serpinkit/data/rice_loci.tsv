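locus_id	code	class_label	in_table3
Os01g16200	QKG	inhibitory	1
Os01g56010	LGC	inhibitory	1
Os03g41419	LRS	inhibitory	1
Os03g41438	FRS	inhibitory	1
Os04g45110	PTY	uncertain	0
Os04g45120	PGY	uncertain	0
Os11g11500	PLP	non_inhibitory	0
Os11g11760	PSG	inhibitory	1
Os11g12410	GAA	inhibitory	1
Os11g12420	GRA	inhibitory	1
Os11g12460	FAS	inhibitory	1
Os11g12520	GMS	inhibitory	1
Os11g13530	LLS	inhibitory	1
Os11g13540	FLC	inhibitory	1
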