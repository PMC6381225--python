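dataset	n_strains	method	total	Reference	RefNoisy	Contaminant	ContamNoisy	Other
Zymo	8	uclust	200	8	74	47	1	70
Zymo	8	uparse	69	8	1	35	0	25
Zymo	8	med	57	9	48	0	0	0
Zymo	8	unoise	12	9	1	1	0	1
Zymo	8	deblur	8	8	0	0	0	0
Zymo	8	dada	20	9	2	5	0	4
Kozich	21	uclust	191	20	42	102	4	23
Kozich	21	uparse	101	20	1	75	0	5
Kozich	21	med	46	22	21	3	0	0
Kozich	21	unoise	40	21	1	17	0	1
Kozich	21	deblur	32	20	0	11	0	1
Kozich	21	dada	56	22	1	31	0	2
Schirmer	57	uclust	185	46	68	28	4	39
Schirmer	57	uparse	77	46	1	26	0	4
Schirmer	57	med	65	56	3	6	0	0
Schirmer	57	unoise	78	57	0	20	1	0
Schirmer	57	deblur	71	54	0	16	1	0
Schirmer	57	dada	88	57	2	28	0	1
DAmore	53	uclust	66	42	4	16	0	4
DAmore	53	uparse	58	42	0	15	0	1
DAmore	53	med	55	50	2	3	0	0
DAmore	53	unoise	59	51	0	8	0	0
DAmore	53	deblur	56	48	0	8	0	0
DAmore	53	dada	66	51	0	15	0	0
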