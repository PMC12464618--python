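study	Q1	Q2	Q3	Q4	Q5	Q6	Q7	Q8	Q9	Q10	Q11	Q12	Q13	Q14	Q15	Q16
Bournissen 2009	Y	N	Y	PY	Y	Y	PY	Y	N	N	Y	N	PY	Y	PY	Y
Haerian 2010	Y	N	Y	PY	Y	Y	N	Y	N	N	Y	N	N	Y	PY	N
Haerian 2011	Y	N	Y	PY	Y	Y	N	Y	N	N	Y	N	N	Y	PY	Y
Haerian 2013	Y	N	Y	PY	Y	Y	N	Y	N	N	Y	N	N	Y	PY	Y
Grover 2013	Y	N	Y	PY	Y	Y	Y	Y	N	N	Y	N	N	Y	Y	Y
Sun 2014	Y	N	Y	PY	Y	Y	N	Y	N	N	Y	N	N	Y	Y	N
Lv 2014	Y	N	Y	PY	Y	Y	N	Y	N	N	Y	N	N	Y	Y	Y
Li 2014	Y	N	Y	PY	Y	Y	N	Y	N	N	Y	N	N	Y	Y	Y
Cheng 2014	Y	N	Y	PY	Y	Y	N	Y	N	N	Y	N	N	Y	Y	N
Chen 2014	Y	N	Y	PY	Y	Y	Y	Y	N	N	Y	N	N	Y	Y	Y
Wang 2015	Y	N	Y	PY	Y	Y	N	Y	N	N	Y	N	N	Y	Y	N
Yu 2015	Y	N	Y	PY	Y	Y	Y	Y	N	N	Y	N	N	Y	Y	Y
Li 2015a	Y	N	Y	PY	Y	Y	Y	Y	N	N	Y	N	N	Y	Y	N
Li 2015b	Y	N	Y	PY	Y	Y	N	Y	N	N	Y	N	N	Y	Y	Y
Qian 2017	Y	N	Y	PY	Y	Y	Y	Y	N	Y	Y	N	N	Y	Y	Y
Lv 2017	Y	N	Y	PY	Y	Y	N	Y	N	N	Y	N	N	Y	Y	Y
Couchi 2017	Y	N	Y	PY	Y	Y	Y	Y	N	Y	Y	N	N	Y	Y	Y
Bao 2018	Y	N	Y	PY	Y	Y	Y	Y	N	Y	Y	N	N	Y	Y	Y
Wang 2018	Y	N	Y	PY	Y	Y	Y	Y	N	N	Y	N	N	Y	Y	Y
Zhao 2019	Y	N	Y	PY	Y	Y	Y	Y	N	Y	Y	N	N	Y	Y	Y
Zhang 2021	Y	N	Y	PY	Y	Y	Y	Y	N	N	Y	N	N	Y	Y	Y
Fan 2021	Y	N	Y	PY	Y	Y	Y	Y	N	N	Y	N	N	Y	N	Y
Zan 2021	Y	N	Y	PY	Y	Y	N	Y	N	N	Y	N	N	Y	Y	Y
Yang 2021	Y	N	Y	PY	Y	Y	N	Y	N	N	Y	N	N	Y	Y	Y
Li 2021	Y	N	Y	PY	Y	Y	Y	Y	N	Y	Y	N	N	Y	Y	Y
Zhao 2021	Y	N	Y	PY	Y	Y	Y	Y	N	Y	Y	N	N	Y	Y	Y
Chen 2022	Y	N	Y	PY	Y	Y	Y	Y	N	Y	Y	N	N	Y	Y	Y
Zhang 2022	Y	N	Y	PY	Y	Y	Y	Y	N	Y	Y	N	N	Y	Y	Y
Krami 2022	Y	N	Y	PY	Y	Y	Y	Y	N	Y	Y	N	N	Y	Y	Y
Hu 2023	Y	N	Y	PY	Y	Y	Y	Y	Y	N	Y	Y	N	N	Y	Y
Wang 2023	Y	N	Y	PY	Y	Y	Y	Y	N	Y	Y	N	N	Y	Y	Y
Mohammadi 2025	Y	PY	Y	Y	Y	Y	N	Y	N	N	Y	PY	N	Y	Y	Y
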