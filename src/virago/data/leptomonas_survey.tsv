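country	city	tryp_pos	tryp_n	dsrna_pos	dsrna_n	isolate	bands_kb	viral_identity	ngs
Belarus	Vitebsk	8	8	1	3	BY-Vi257
Belarus	Vitebsk	8	8	1	3	BY-Vi260	3.5, 2.2	TLV	Yes
Belarus	Vitebsk	8	8	1	3	BY-Vi262
Czechia	Benesov	4	7	0	2	CZ-Be02
Czechia	Benesov	4	7	0	2	CZ-Be04
Czechia	Brno	7	10	2	3	CZ-Br01	3.5, 2.2	TLV
Czechia	Brno	7	10	2	3	CZ-Br02	3.5, 2.2	TLV, OV^a, LBV1/2/4^a	Yes
Czechia	Brno	7	10	2	3	CZ-Br07
Czechia	Ceske Budejovice	16	25	0	4	CZ-CB02
Czechia	Ceske Budejovice	16	25	0	4	CZ-CB03
Czechia	Ceske Budejovice	16	25	0	4	CZ-CB13
Czechia	Ceske Budejovice	16	25	0	4	CZ-CB16
Czechia	Hradec nad Moravici	12	16	9	9	CZ-HM01	3.5, 2.2	TLV, LBV3^a	Yes
Czechia	Hradec nad Moravici	12	16	9	9	CZ-HM02	3.5, 2.2	TLV	Yes
Czechia	Hradec nad Moravici	12	16	9	9	CZ-HM03	3.5, 2.2	TLV
Czechia	Hradec nad Moravici	12	16	9	9	CZ-HM04	3.5, 2.2	TLV	Yes
Czechia	Hradec nad Moravici	12	16	9	9	CZ-HM05	3.5, 2.2	TLV
Czechia	Hradec nad Moravici	12	16	9	9	CZ-HM06	3.5, 2.2	TLV	Yes
Czechia	Hradec nad Moravici	12	16	9	9	CZ-HM07	3.5, 2.3
Czechia	Hradec nad Moravici	12	16	9	9	CZ-HM08	3.5, 2.2	TLV	Yes
Czechia	Hradec nad Moravici	12	16	9	9	CZ-HM09	3.5, 2.2	TLV	Yes
Czechia	Ostrava	24	30	11	13	CZ-Os00	3.5, 2.2	TLV
Czechia	Ostrava	24	30	11	13	CZ-Os01	3.5, 2.2	TLV
Czechia	Ostrava	24	30	11	13	CZ-Os02	3.5, 2.2	TLV
Czechia	Ostrava	24	30	11	13	CZ-Os03	3.5, 2.2	TLV	Yes
Czechia	Ostrava	24	30	11	13	CZ-Os05	3.5, 2.2	TLV
Czechia	Ostrava	24	30	11	13	CZ-Os07	3.5, 2.2	TLV
Czechia	Ostrava	24	30	11	13	CZ-Os08	3.5, 2.2	TLV
Czechia	Ostrava	24	30	11	13	CZ-Os10	3.5, 2.2, 5, 4.2, 4, 3, 2.4, 1.6, 1.3	TLV, OV
Czechia	Ostrava	24	30	11	13	CZ-Os11	3.5, 2.2	TLV	Yes
Czechia	Ostrava	24	30	11	13	CZ-Os12	3.5, 2.2	TLV
Czechia	Ostrava	24	30	11	13	CZ-Os13
Czechia	Ostrava	24	30	11	13	CZ-Os14
Czechia	Ostrava	24	30	11	13	CZ-Os15	3.5, 2.2, 5.0, 4.2, 4.0, 3.0, 2.4, 1.6, 1.3	TLV, OV
Czechia	Prague	12	21	1	3	CZ-Pr02
Czechia	Prague	12	21	1	3	CZ-Pr14	3.5, 2.2, 5.0, 4.2, 4.0, 3.0, 2.4, 1.6, 1.3, 6.2, 1.9, 1.5	TLV, OV, LBV3	Yes
Czechia	Prague	12	21	1	3	Cz-Pr24
Germany	Jena	3	4	1	1	DE-Je02	3.5, 2.2	TLV	Yes
Hungary	Varbo	10	16	2	3	HU-Va04	3.5, 2.2	TLV	Yes
Hungary	Varbo	10	16	2	3	HU-Va05	6.2, 1.9, 1.5	LBV3	Yes
Hungary	Varbo	10	16	2	3	HU-Va09
Italy	Grosseto	11	28	2	3	IT-Gr06	3.5, 2.2	TLV
Italy	Grosseto	11	28	2	3	IT-Gr07	3.5, 2.2	TLV
Italy	Grosseto	11	28	2	3	IT-Gr10
Italy	Rome	8	30	6	8	IT-Ro01	3.5, 2.2	TLV	Yes
Italy	Rome	8	30	6	8	IT-Ro02	3.5, 2.2	TLV
Italy	Rome	8	30	6	8	IT-Ro03
Italy	Rome	8	30	6	8	IT-Ro04	3.5, 2.2	TLV
Italy	Rome	8	30	6	8	IT-Ro05
Italy	Rome	8	30	6	8	IT-Ro06	3.5, 2.2	TLV	Yes
Italy	Rome	8	30	6	8	IT-Ro07	3.5, 2.2	TLV
Italy	Rome	8	30	6	8	IT-Ro08	3.5, 2.2	TLV
Lithuania	Vilnius	8	8	3	3	LT-Vi06	3.5, 2.2	TLV	Yes
Lithuania	Vilnius	8	8	3	3	LT-Vi08	3.5, 2.2	TLV	Yes
Lithuania	Vilnius	8	8	3	3	LT-Vi09	3.5, 2.2, 6.2, 1.9, 1.5	TLV, LBV3	Yes
Poland	Rzeszow	18	20	3	6	PL-Rz05
Poland	Rzeszow	18	20	3	6	PL-Rz06	3.5, 2.2, 5.0, 4.2, 4.0, 3.0, 2.4, 1.6, 1.3, 6.2, 1.9, 1.5	TLV, OV, LBV3	Yes
Poland	Rzeszow	18	20	3	6	PL-Rz11
Poland	Rzeszow	18	20	3	6	PL-Rz12
Poland	Rzeszow	18	20	3	6	PL-Rz13	3.5, 2.2	TLV	Yes
Poland	Rzeszow	18	20	3	6	PL-Rz18	6.2, 1.9, 1.5	LBV3	Yes
Portugal	Lisbon	6	13	4	5	PT-Li02	3.5, 2.2	TLV
Portugal	Lisbon	6	13	4	5	PT-Li03	3.5, 2.2	TLV	Yes
Portugal	Lisbon	6	13	4	5	PT-Li04	3.5, 2.2	TLV
Portugal	Lisbon	6	13	4	5	PT-Li05
Portugal	Lisbon	6	13	4	5	PT-Li06	3.5, 2.2, 6.2, 3.2, 1.8	TLV, LBV4	Yes
Romania	Luncavita	2	6	1	1	RO-Lu01	3.5, 2.2	TLV
Russia	Borisovka	8	8	0	1	RU-Bo01
Russia	Krasnodar	11	11	1	2	RU-Kr01	3.5, 2.2, 6.2, 1.9, 1.5	TLV, LBV3, OV^a	Yes
Russia	Krasnodar	11	11	1	2	RU-Kr02
Russia	Moscow	14	17	4	4	RU-Mo01	3.5, 2.2	TLV	Yes
Russia	Moscow	14	17	4	4	RU-Mo02	3.5, 2.2	TLV	Yes
Russia	Moscow	14	17	4	4	RU-Mo202	3.5, 2.2	TLV
Russia	Moscow	14	17	4	4	RU-Mo203	3.5, 2.2	TLV	Yes
Russia	Pskov	92	92	0	3	RU-Ps01
Russia	Pskov	92	92	0	3	RU-Ps02
Russia	Pskov	92	92	0	3	RU-Ps03
Russia	Suyda	10	11	1	1	RU-Su01	3.5, 2.2	TLV	Yes
Serbia	Dimitrovgrad	12	15	2	4	SE-Dm02
Serbia	Dimitrovgrad	12	15	2	4	SE-Dm03
Serbia	Dimitrovgrad	12	15	2	4	SE-Dm04	3.5, 2.2	TLV	Yes
Serbia	Dimitrovgrad	12	15	2	4	SE-Dm07	3.5, 2.2, 6.2	TLV, LBV^b,c
Serbia	Subotica	10	13	3	7	SE-Sb01
Serbia	Subotica	10	13	3	7	SE-Sb02	3.5, 2.2, 6.2, 1.9, 1.5	TLV, LBV2/3/4	Yes
Serbia	Subotica	10	13	3	7	SE-Sb03
Serbia	Subotica	10	13	3	7	SE-Sb04
Serbia	Subotica	10	13	3	7	SE-Sb06	3.5, 2.2	TLV
Serbia	Subotica	10	13	3	7	SE-Sb07	3.5, 2.2, 6.2, 1.9, 1.5	TLV, QIN^a, LBV2/3/4	Yes
Serbia	Subotica	10	13	3	7	SE-Sb09
Slovakia	Bratislava	25	30	4	5	SK-Br02	3.5, 2.2, 6.2	TLV, LBV2^b	Yes
Slovakia	Bratislava	25	30	4	5	SK-Br05	3.5, 2.2	TLV	Yes
Slovakia	Bratislava	25	30	4	5	SK-Br18	3.5, 2.2	TLV
Slovakia	Bratislava	25	30	4	5	SK-Br20	3.5, 2.2	TLV
Slovakia	Bratislava	25	30	4	5	SK-Br24
Slovakia	Kosice	9	20	0	1	SKK6
Slovakia	Liptovsky Hradok	7	10	0	3	SK-LH01
Slovakia	Liptovsky Hradok	7	10	0	3	SK-LH04
Slovakia	Liptovsky Hradok	7	10	0	3	SK-LH06
Slovakia	Lubochna	18	25	0	4	SK-Lu01
Slovakia	Lubochna	18	25	0	4	SK-Lu10
Slovakia	Lubochna	18	25	0	4	SK-Lu15
Slovakia	Lubochna	18	25	0	4	SK-Lu16
Ukraine	Zaporizhzhia	9	14	3	4	UA-Zp01	3.5, 2.2, 5.0, 4.2, 4.0, 3.0, 2.4, 1.6, 1.3	TLV, OV	Yes
Ukraine	Zaporizhzhia	9	14	3	4	UA-Zp02	3.5, 2.2	TLV, OV^a, QIN^a	Yes
Ukraine	Zaporizhzhia	9	14	3	4	UA-Zp03	3.5, 2.2	TLV	Yes
Ukraine	Zaporizhzhia	9	14	3	4	UA-Zp04
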