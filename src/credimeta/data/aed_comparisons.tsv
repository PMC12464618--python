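# Significant (p < 0.05) pooled genetic comparisons for antiepileptic-drug resistance,
# compiled from published candidate-gene meta-analyses (2007-2025).  One row per
# source meta-analysis x variant x genetic contrast x subgroup.  Parenthesized cells
# were estimated (e.g. recovered from a forest plot); "<x" cells are upper bounds;
# NC = not calculable (fewer than three studies, n_studies given where known).
# bias_concern is the analyst flag feeding the Venice "potential concerns" grade B.
study	drug	gene	variant	contrast	subgroup	model	n_total	n_studies	or_point	ci_low	ci_high	p_value	het_p	i2	egger_p	bias_concern
Chen 2022	AEDs	ABCB1	rs1045642	C vs. T	Overall	R	29116		1.13	1.02	1.25	0.02	0.0001	77	0.838	0
Chen 2022	AEDs	ABCB1	rs1045642	CC vs. CT + TT	Overall	R	14562		1.20	1.03	1.39	0.02	0.00001	71	0.348	0
Chen 2022	AEDs	ABCB1	rs1045642	C vs. T	Caucasian	R	11230		1.24	1.09	1.43	0.002	0.00001	64	(0.164)	0
Chen 2022	AEDs	ABCB1	rs1045642	CC vs. CT + TT	Caucasian	R	2927		1.35	1.11	1.66	0.003	0.001	52	(0.364)	0
Chen 2022	AEDs	ABCB1	rs1045642	CC + CT vs. TT	Caucasian	F	2927		1.26	1.06	1.49	0.008	0.01	43	(0.061)	1
Chen 2022	AEDs	ABCB1	rs1045642	C vs. T	Tunisian	R	506	2	0.31	0.15	0.65	0.002	0.07	70	NC	0
Chen 2022	AEDs	ABCB1	rs1045642	CC vs. CT + TT	Tunisian	F	253	2	0.34	0.20	0.60	0.0001	0.73	0	NC	0
Chen 2022	AEDs	ABCB1	rs1045642	CC + CT vs. TT	Tunisian	R	253	2	0.18	0.04	0.78	0.02	0.07	71	NC	0
Krami 2022	AEDs	ABCB1	rs2032582	GG + GA vs. AA	Overall	F	882		0.56	0.34	0.93	0.02	0.85	0	0.126	0
Krami 2022	AEDs	ABCB1	rs2032582	G vs. A	Caucasian	F	1360		0.45	0.34	0.60	<0.0001	(0.366)	5.4	(0.045)	0
Krami 2022	AEDs	ABCB1	rs2032582	GG vs. GA + AA	Caucasian	F	453		0.24	0.15	0.38	<0.0001	(0.130)	46.9	0.041	0
Yu 2015	AEDs	ABCB1	rs2032582	T + A vs. G	Asian	F	2547		1.12	1.01	1.25	0.039	0.566	0	(0.9285)	0
Wang 2023	AEDs	ABCC2	rs717620	TT vs. CT + CC	Overall	F	4510		1.68	1.27	2.21	(0.0002)	0.418	3.1	0.05	0
Wang 2023	AEDs	ABCC2	rs717620	TT vs. CT + CC	Asian	F	2984		1.70	1.26	2.29	(0.0005)	0.15	29.3	(0.09)	0
Zan 2021	AEDs	ABCC2	rs3740066	CC vs. CT + TT	Overall	R	3341		2.29	1.44	3.64	0.0005	0.05	47.1	0.804	0
Zan 2021	AEDs	ABCC2	rs3740066	CC vs. CT + TT	Asian	R	2660		2.53	1.56	4.08	0.0001	0.09	43.2	0.325	0
Hu 2023	AEDs	GABRG2	rs211037	C vs. T	non-Asian	F	320	2	0.23	0.13	0.39	(<0.0001)	<0.01	0	NC	0
Hu 2023	AEDs	GABRG2	rs211037	CC vs. CT + TT	non-Asian	R	160	2	0.18	0.07	0.47	(0.0005)	<0.01	15	NC	0
Hu 2023	AEDs	GABRG2	rs211037	CC + CT vs. TT	non-Asian	F	160	2	0.08	0.02	0.40	(0.002)	<0.01	0	NC	0
Mohammadi 2025	AEDs	SCN1A	rs2298771	G vs. A	Overall	F	15420		1.20	1.025	1.405	0.023	(0.31)	10.64	0.186	0
Mohammadi 2025	AEDs	SCN1A	rs2298771	GG vs. AA + AG	Overall	F	7710		1.35	1.04	1.75	0.022	(0.46)	0	0.229	0
Zhang 2021	CBZ	SCN1A	rs2298771	GG vs. AA + GA	Asian	F	941		3.19	1.27	8.02	0.013	0.926	0	0.244	0
Mohammadi 2025	AEDs	SCN1A	rs10167228	A vs. G	Overall	F	478	2	1.85	1.18	2.91	0.007	(0.32)	0	NC	0
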