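rsid	chrom	pos_bp	cm	IBS	YRI	NA
rs62394277	5	169924749	185.487416	0.23	0.39	0.37
rs12033818	1	106368717	134.610925	0.05	0.01	0.94
rs10960270	9	11818115	25.717268	0.19	0.24	0.56
rs2471660	12	75534099	89.727097	0.00	0.79	0.21
rs12627722	21	17918366	7.52177123	0.15	0.70	0.15
rs11653073	17	55687365	83.7730559	0.00	0.41	0.59
rs17025629	3	88354232	109.781656	0.67	0.22	0.11
rs7578180	2	158772058	176.901137	0.10	0.56	0.34
rs75910375	17	11281457	29.8450381	0.01	0.49	0.50
rs74936620	1	55832969	81.3389065	0.12	0.24	0.64
rs77240763	5	145752501	153.573126	0.31	0.31	0.38
rs75970478	3	138843097	150.937494	0.11	0.62	0.26
rs12956301	18	71834423	105.245876	0.00	0.80	0.20
rs10172437	2	174701949	193.753831	0.01	0.60	0.39
rs56919396	14	95350520	95.3439121	0.36	0.16	0.48
rs2567778	13	103742001	103.442192	0.36	0.52	0.12
rs17128958	14	93708224	91.6536648	0.42	0.14	0.44
rs576400715	2	89571430	120.624	0.05	0.30	0.65
rs17089367	13	73011013	70.4386922	0.30	0.60	0.10
rs10948131	6	44291641	69.8263172	0.00	0.57	0.43
rs114354246	3	137295824	149.759253	0.15	0.61	0.24
rs7128963	11	33599446	50.7219531	0.06	0.29	0.66
rs6691697	1	42534375	70.0178338	0.07	0.32	0.61
rs12060034	1	198224252	215.353224	0.28	0.21	0.51
rs12205759	6	122752471	127.395537	0.04	0.43	0.54
rs1611636	6	29836703	50.3216201	0.04	0.32	0.64
rs10512946	3	134916937	148.665958	0.15	0.61	0.23
rs72866243	18	2094235	5.55281054	0.45	0.44	0.11
rs114208611	11	11100541	21.4527621	0.00	0.40	0.60
rs13136539	4	174513213	183.196957	0.47	0.26	0.27
rs77282632	3	121384210	133.9296	0.43	0.30	0.27
rs730489	6	151399891	162.916228	0.29	0.48	0.23
rs528255	8	12878637	33.8526902	0.10	0.51	0.39
rs72834798	17	38217299	64.1399895	0.01	0.56	0.43
rs16883890	5	9950908	22.6794291	0.12	0.08	0.80
rs11996214	8	135211378	159.947948	0.01	0.60	0.39
rs4782152	16	9326011	22.425679	0.01	0.13	0.86
rs13432204	2	107262432	128.94	0.05	0.20	0.74
rs16974292	16	84652644	114.995507	0.03	0.30	0.67
rs116953645	19	46613411	72.3867019	0.01	0.31	0.67
rs2422672	20	1990286	7.8190193	0.10	0.70	0.20
rs17188743	6	30385111	50.6059471	0.05	0.32	0.63
rs973295	14	94372768	92.5873731	0.39	0.15	0.46
rs1889877	6	69729678	84.7215414	0.01	0.48	0.51
rs10114476	9	96631459	113.576597	0.15	0.71	0.14
rs113629052	9	95358140	112.692987	0.14	0.71	0.15
rs62568088	9	6277534	15.8022578	0.12	0.32	0.56
rs4631137	5	52420445	63.8860104	0.04	0.56	0.40
rs2165183	2	4830190	9.36070063	0.11	0.67	0.21
rs675465	4	20543817	36.4528078	0.33	0.27	0.40
rs76887708	5	98125372	109.316657	0.00	0.76	0.24
rs8043824	16	79847142	101.522556	0.01	0.31	0.68
rs17123256	14	87745773	81.7304956	0.45	0.36	0.19
rs115079994	22	45016212	55.6235323	0.01	0.07	0.92
rs113899132	5	156284101	166.222937	0.17	0.31	0.52
rs73142595	20	54320992	85.8174786	0.21	0.22	0.57
rs7700639	5	6606807	16.6711274	0.20	0.01	0.79
rs7714907	5	142145386	149.584982	0.28	0.37	0.35
rs114959453	6	24423918	47.4334264	0.03	0.35	0.62
rs9812688	3	86878962	109.260905	0.67	0.22	0.11
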