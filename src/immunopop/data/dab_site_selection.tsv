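site	model	statistic_name	statistic_value	evidence_kind	evidence_value
2	SLAC	normalized_dn_ds	9.02	p_value	0.016
2	REL	e_dn_ds	7.44	bayes_factor	5111.36
2	MEME	beta2	14.88	p_value	0.004
11	REL	e_dn_ds	7.46	bayes_factor	1590.05
11	MEME	beta2	4.68	p_value	0.015
13	MEME	beta2	25.51	p_value	0.021
22	MEME	beta2	6.46	p_value	0.016
23	SLAC	normalized_dn_ds	4.01	p_value	0.026
23	REL	e_dn_ds	7.22	bayes_factor	147.83
23	MEME	beta2	5.28	p_value	0.005
32	REL	e_dn_ds	7.33	bayes_factor	134.56
32	MEME	beta2	4.29	p_value	0.023
41	MEME	beta2	33.73	p_value	0.011
42	SLAC	normalized_dn_ds	7.09	p_value	0.043
42	REL	e_dn_ds	7.43	bayes_factor	1743.83
42	MEME	beta2	73.74	p_value	0.0005
52	SLAC	normalized_dn_ds	7.18	p_value	0.002
52	REL	e_dn_ds	7.49	bayes_factor	1570000
52	MEME	beta2	9.54	p_value	0.0005
55	SLAC	normalized_dn_ds	6.34	p_value	0.042
55	REL	e_dn_ds	7.48	bayes_factor	3020000
55	MEME	beta2	5673.31	p_value	0.0005
59	SLAC	normalized_dn_ds	7.61	p_value	0.0005
59	REL	e_dn_ds	7.53	bayes_factor	1680000
59	MEME	beta2	8.85	p_value	0.0005
60	MEME	beta2	3.68	p_value	0.031
63	SLAC	normalized_dn_ds	7.62	p_value	0.0005
63	REL	e_dn_ds	7.53	bayes_factor	683000
63	MEME	beta2	9.40	p_value	0.0005
71	SLAC	normalized_dn_ds	4.79	p_value	0.010
71	MEME	beta2	22.20	p_value	0.026
72	REL	e_dn_ds	7.19	bayes_factor	205.14
72	MEME	beta2	33.54	p_value	0.0005
73	MEME	beta2	4.71	p_value	0.028
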