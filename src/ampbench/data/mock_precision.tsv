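dataset	method	recall	overall_precision	technical_precision
Zymo	uclust	100	4	10
Zymo	uparse	100	12	89
Zymo	med	100	16	16
Zymo	unoise	100	75	90
Zymo	deblur	100	100	100
Zymo	dada	100	45	82
Kozich	uclust	95	10	32
Kozich	uparse	95	20	95
Kozich	med	100	48	51
Kozich	unoise	100	53	95
Kozich	deblur	95	63	100
Kozich	dada	100	39	96
Schirmer	uclust	81	25	40
Schirmer	uparse	81	60	98
Schirmer	med	98	86	95
Schirmer	unoise	100	73	100
Schirmer	deblur	95	76	100
Schirmer	dada	100	65	96
DAmore	uclust	79	64	91
DAmore	uparse	79	72	100
DAmore	med	94	91	96
DAmore	unoise	96	86	100
DAmore	deblur	91	86	100
DAmore	dada	96	77	100
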