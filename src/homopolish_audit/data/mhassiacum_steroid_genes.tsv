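gene_code	enzyme_name	kegg_no	gene_name	size_aa	locus_start	locus_end	note
Mhass_00386	Cholesterol oxidase	1.1.3.6	ChoD	575	420,539	422,266
Mhass_03213	3beta-hydroxysteroid dehydrogenase	1.1.1.145	3beta-HSD	362	3,401,387	3,402,475
Mhass_03703	Cholest-4-en-3-one 26-monooxygenase	1.14.15.28		404	3,927,003	3,928,217
Mhass_01888	Cholest-4-en-3-one 26-monooxygenase	1.14.15.29		420	1,999,888	2,001,150
Mhass_03637	Cholest-4-en-3-one 26-monooxygenase	1.14.15.29		409	3,864,055	3,865,284
Mhass_03739	Cholest-4-en-3-one 26-monooxygenase	1.14.15.29		416	3,994,451	3,995,701
Mhass_03226	Steroid delta-isomerase	5.3.3.1	Ksi	123	3,424,752	3,425,123
Mhass_03651	Steroid delta-isomerase	5.3.3.1		147	3,877,363	3,877,806
Mhass_03730	3-ketosteroid delta-1-dehydrogenase	1.3.99.4	KstD_4	583	3,885,552	3,987,303	table_conflicts_with_body_text_584aa_3985552
Mhass_02476	3-keto-5alpha-steroid-4-dehydrogenase	1.3.99.5		528	2,621,394	2,622,980
Mhass_02479	3-ketosteroid 9alpha-monooxygenase	1.14.15.30	KshA_4	385	2,624,124	2,625,281
Mhass_03697	3-ketosteroid 9alpha-monooxygenase	1.14.15.30	KshA_8	379	3,920,249	3,921,388
Mhass_03711	3-ketosteroid 9alpha-monooxygenase	1.14.15.30	KshA_9	384	3,936,408	3,937,562
Mhass_03780	3-ketosteroid 9alpha-monooxygenase	1.14.15.30	Hmp	353	4,036,126	4,030,187	locus_printed_descending
Mhass_03776	3-hydroxy-9,10-secoandrosta-1,3,5(10)-triene-9,17-dione monooxygenase	1.14.14.12	HsaB	189	4,032,326	4,032,895
Mhass_03779	3-hydroxy-9,10-secoandrosta-1,3,5(10)-triene-9,17-dione monooxygenase	1.14.14.12	HsaA3	394	4,034,724	4,035,908
Mhass_03777	3,4-dihydroxy-9,10-secoandrosta-1,3,5(10)-triene-9,17-dione 4,5-dioxygenase	1.13.11.25	HsaC_2	302	4,032,892	4,033,800
Mhass_03778	4,5:9,10-diseco-3-hydroxy-5,9,17-trioxoandrosta-1(10),2-diene-4-oate hydrolase	3.7.1.17	HsaD_5	304	4,033,797	4,034,711
Mhass_01072	3-[(3aS,4S,7aS)-7a-methyl-1,5-dioxo-octahydro-1H-inden-4-yl]propanoate-CoA ligase	6.2.1.41	FadD3_4	485	1,131,688	1,133,145
Mhass_03132	3-[(3aS,4S,7aS)-7a-methyl-1,5-dioxo-octahydro-1H-inden-4-yl]propanoate-CoA ligase	6.2.1.41		497	3,322,992	3,324,485
Mhass_03765	3-[(3aS,4S,7aS)-7a-methyl-1,5-dioxo-octahydro-1H-inden-4-yl]propanoate-CoA ligase	6.2.1.41	FadD3_6	513	4,019,741	4,021,282
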