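# Printed FPRP/BFDP cells and Venice grades from the published reappraisal table,
# keyed to the packaged comparisons fixture.  FPRP columns: target OR x prior.
study	variant	contrast	subgroup	fprp_15_05	fprp_15_001	fprp_20_05	fprp_20_001	bfdp_05	bfdp_001	venice_code	venice_label
Chen 2022	rs1045642	C vs. T	Overall	0.251	0.946	0.251	0.946	0.847	0.997	ACC	W
Chen 2022	rs1045642	CC vs. CT + TT	Overall	0.223	0.938	0.222	0.938	0.804	0.995	ACA	W
Chen 2022	rs1045642	C vs. T	Caucasian	0.056	0.757	0.056	0.756	0.539	0.984	ACA	W
Chen 2022	rs1045642	CC vs. CT + TT	Caucasian	0.091	0.840	0.078	0.816	0.627	0.989	ACA	W
Chen 2022	rs1045642	CC + CT vs. TT	Caucasian	0.118	0.876	0.116	0.873	0.688	0.991	ABB	M
Chen 2022	rs1045642	C vs. T	Tunisian	0.633	0.989	0.263	0.949	0.877	0.997	BC-	N/A
Chen 2022	rs1045642	CC vs. CT + TT	Tunisian	0.271	0.951	0.039	0.682	0.692	0.992	BA-	N/A
Chen 2022	rs1045642	CC + CT vs. TT	Tunisian	0.912	0.998	0.829	0.996	0.942	0.999	BC-	N/A
Krami 2022	rs2032582	GG + GA vs. AA	Overall	0.656	0.990	0.416	0.974	0.901	0.998	BBA	M
Krami 2022	rs2032582	G vs. A	Caucasian	0.000	0.014	0.000	0.000	0.002	0.084	AAC	W
Krami 2022	rs2032582	GG vs. GA + AA	Caucasian	0.003	0.149	0.000	0.001	0.008	0.286	BBC	W
Yu 2015	rs2032582	T + A vs. G	Asian	0.450	0.977	0.450	0.977	0.915	0.998	AAA	S
Wang 2023	rs717620	TT vs. CT + CC	Overall	0.019	0.499	0.004	0.189	0.232	0.941	AAC	W
Wang 2023	rs717620	TT vs. CT + CC	Asian	0.043	0.701	0.011	0.359	0.380	0.970	ABA	M
Zan 2021	rs3740066	CC vs. CT + TT	Overall	0.191	0.926	0.030	0.617	0.638	0.989	ABA	M
Zan 2021	rs3740066	CC vs. CT + TT	Asian	0.143	0.898	0.016	0.456	0.545	0.984	ABA	M
Hu 2023	rs211037	C vs. T	non-Asian	0.023	0.556	0.000	0.024	0.088	0.835	BA-	N/A
Hu 2023	rs211037	CC vs. CT + TT	non-Asian	0.701	0.992	0.322	0.962	0.891	0.998	BA-	N/A
Hu 2023	rs211037	CC + CT vs. TT	non-Asian	0.890	0.998	0.757	0.994	0.937	0.999	BA-	N/A
Mohammadi 2025	rs2298771	G vs. A	Overall	0.309	0.959	0.308	0.959	0.859	0.997	AAA	S
Mohammadi 2025	rs2298771	GG vs. AA + AG	Overall	0.350	0.966	0.298	0.957	0.846	0.997	AAA	S
Zhang 2021	rs2298771	GG vs. AA + GA	Asian	0.826	0.996	0.615	0.988	0.927	0.998	BAA	M
Mohammadi 2025	rs10167228	A vs. G	Overall	0.441	0.977	0.185	0.923	0.838	0.996	BA-	N/A
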