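gene_id	gene_class	supporting_hairpins	n_support	n_enriched	n_depleted	n_hairpins_total	ambiguous
G01	lethal	sh_G01_1,sh_G01_2,sh_G01_3,sh_G01_4	4	0	4	4	False
G02	lethal	sh_G02_1,sh_G02_2,sh_G02_3,sh_G02_4	4	0	4	4	False
G03	none		0	0	0	4	False
G04	none		0	0	0	4	False
G05	none		0	0	0	4	False
G06	none		0	0	0	4	False
G07	none		0	0	0	4	False
G08	none		0	0	0	4	False
G09	none		0	0	0	4	False
G10	none		0	0	0	4	False
G11	lethal	sh_G11_1,sh_G11_2,sh_G11_3,sh_G11_4	4	0	4	4	False
G12	none		0	0	0	4	False
G13	none		0	0	0	4	False
G14	none		0	0	0	4	False
G15	none		0	0	0	4	False
G16	none		0	0	0	4	False
G17	none		0	0	0	4	False
G18	none		0	0	0	4	False
G19	none		0	0	0	4	False
G20	none		0	0	0	4	False
G21	none		0	0	0	4	False
G22	protective	sh_G22_1,sh_G22_2,sh_G22_4	3	3	0	4	False
G23	none		0	0	0	4	False
G24	none		0	0	0	4	False
G25	none		0	0	0	4	False
G26	none		0	0	0	4	False
G27	none		0	0	0	4	False
G28	protective	sh_G28_1,sh_G28_3	2	2	0	4	False
G29	none		0	0	0	4	False
G30	none		0	0	0	4	False
G31	none		0	0	0	4	False
G32	none		0	0	0	4	False
G33	none		0	0	0	4	False
G34	none		0	0	0	4	False
G35	protective	sh_G35_1,sh_G35_2,sh_G35_3	3	3	0	4	False
G36	protective	sh_G36_3,sh_G36_4	2	2	0	4	False
G37	lethal	sh_G37_2,sh_G37_3,sh_G37_4	3	0	3	4	False
G38	none		0	0	0	4	False
G39	none		0	0	0	4	False
G40	none		0	0	0	4	False
G41	none		0	0	0	4	False
G42	none		0	0	0	4	False
G43	none		0	0	0	4	False
G44	none		0	0	0	4	False
G45	none		0	0	0	4	False
G46	none		0	0	0	4	False
G47	none		0	0	0	4	False
G48	none		0	0	0	4	False
G49	none		0	0	0	4	False
G50	none		0	0	0	4	False
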