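superfamily	lineage	Helianthus annuus	Lactuca sativa	Cynara cardunculus	Artemisia annua	Chrysanthemum seticuspe	max_difference
Copia	Ale	0.00	0.00	0.00	0.00	0.17	0.17
Copia	Angela	0.07	16.99	0.01	2.04	4.01	16.99
Copia	Ikeros	0.29	0.00	0.00	0.00	0.00	0.29
Copia	Ivana	0.00	0.00	0.00	0.23	0.10	0.23
Copia	SIRE	5.57	3.88	23.49	16.04	29.91	26.03
Copia	TAR	0.11	0.03	0.01	0.44	0.72	0.71
Copia	Unknown	0.31	0.95	0.00	1.05	0.38	1.05
Copia	Total	6.35	21.86	23.50	19.80	35.28	28.93
Gypsy	Chromovirus	30.42	12.90	9.66	3.62	2.07	28.35
Gypsy	Athila	3.05	0.55	0.95	15.46	9.38	14.90
Gypsy	Tat	5.25	0.01	0.00	0.90	0.80	5.25
Gypsy	Unknown	2.39	0.20	0.00	0.00	0.00	2.39
Gypsy	Total	41.11	13.67	10.61	19.98	12.25	30.50
Unknown	Unknown	4.24	12.59	1.15	3.06	4.79	11.44
TOTAL	TOTAL	51.70	48.12	35.27	42.84	52.32	17.05
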