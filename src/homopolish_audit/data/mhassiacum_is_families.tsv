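family	n_complete	complete_size_bp	n_incomplete_nt	nt_size_bp	n_incomplete_ct	ct_size_bp	closest_organisms
IS110	9	1230	1	660	1	573	M. thermoresistible; Mycobacterium palauense
IS21	4	1623	2	867-1047	2	603-795	M. thermoresistible; M. phocaium; Rhodococcus rhodochrous
IS256	17	1320	2	375-933	6	609	M. smegmatis; M. chlorophenolicum; Mycobacterium avium; Gordonia spp.
IS3	0		8	309	8	861	M. smegmatis; Mycobacterium abscessus
ISL3	9	1329	0		0		M. thermoresistible; M. frederiksbergense; Mycobacterium kansasii; Rhodococcus subtropicis
DDE-t (IS21 family)	2	1362	0		0		Mycobacterium frederiksbergense; Mycobacterium europaeum
IS21 ATPb	6	798	0		0		M. thermoresistible
DDE-ATPb	2	858	0		0		Mycobacterium pseudokansasii
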