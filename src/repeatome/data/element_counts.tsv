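superfamily	lineage	Helianthus annuus	Lactuca sativa	Cynara cardunculus	Artemisia annua	Chrysanthemum seticuspe
Copia	Ale	674	208	55	288	630
Copia	Alesia	9	15	0	0	0
Copia	Angela	312	2278	1	63	70
Copia	Bianca	133	22	0	56	26
Copia	Ikeros	505	5	14	8	2
Copia	Ivana	400	125	56	323	304
Copia	SIRE	4711	2493	176	630	1284
Copia	TAR	61	26	4	57	88
Copia	Tork	182	8	12	129	77
Copia	Copia unclassified	656	246	19	380	602
Gypsy	Chromovirus|CRM	119	46	5	30	47
Gypsy	Chromovirus|Galadriel	3	3	0	0	0
Gypsy	Chromovirus|Reina	235	65	44	123	146
Gypsy	Chromovirus|Tekay	18405	1027	48	35	21
Gypsy	Chromovirus unclassified	424	13	0	5	1
Gypsy	non-Chromovirus|OTA|Athila	2472	213	10	398	168
Gypsy	non-Chromovirus|OTA|Tat	5060	30	0	260	697
Gypsy	non-Chromovirus|OTA unclassified	7	0	0	4	1
Gypsy	non-Chromovirus unclassified	0	0	0	0	0
Gypsy	Gypsy unclassified	84	0	0	1	0
unclassified	LTR-RE unclassified	128	52	4	9	6
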