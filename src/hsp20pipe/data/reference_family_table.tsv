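gene_name	gene_id	chr	start	end	cds_bp	aa	mw_kda	pi
CtHSP20-1	evm.model.LG01.398	Chr1	2831464	2832277	720	239	25.66	5.88
CtHSP20-2	evm.model.LG01.916	Chr1	6892913	6893731	720	239	26.70	6.02
CtHSP20-3	evm.model.LG01.1036	Chr1	7891976	7892755	654	217	24.40	7.98
CtHSP20-4	evm.model.LG01.1038	Chr1	7909811	7910282	471	156	17.65	6.19
CtHSP20-5	evm.model.LG01.1039	Chr1	7910881	7911343	462	153	17.46	6.19
CtHSP20-6	evm.model.LG01.2241	Chr1	23349398	23350475	987	328	36.62	9.35
CtHSP20-7	evm.model.LG02.592	Chr2	11068319	11068933	531	176	19.47	9.27
CtHSP20-8	evm.model.LG02.965	Chr2	18824494	18841582	768	255	27.84	5.90
CtHSP20-9	evm.model.LG02.1296	Chr2	24091622	24092237	480	159	17.84	5.60
CtHSP20-10	evm.model.LG02.1517	Chr2	27953172	27953787	480	159	17.76	5.82
CtHSP20-11	evm.model.LG02.2172	Chr2	34141399	34141858	459	152	16.93	6.18
CtHSP20-12	evm.model.LG03.433	Chr3	3764103	3764778	558	185	21.25	9.36
CtHSP20-13	evm.model.LG03.713	Chr3	6530821	6531268	447	148	16.47	6.85
CtHSP20-14	evm.model.LG03.714	Chr3	6538664	6539126	462	153	16.60	4.98
CtHSP20-15	evm.model.LG03.715	Chr3	6545759	6546215	456	151	17.05	5.79
CtHSP20-16	evm.model.LG03.716	Chr3	6547591	6548050	459	152	17.08	6.76
CtHSP20-17	evm.model.LG03.994	Chr3	9259177	9259663	486	161	17.76	5.97
CtHSP20-18	evm.model.LG03.3139	Chr3	43298792	43299428	504	167	17.67	8.95
CtHSP20-19	evm.model.LG03.3140	Chr3	43302943	43303924	981	326	35.64	9.08
CtHSP20-20	evm.model.LG04.203	Chr4	1794764	1795298	534	177	19.62	6.85
CtHSP20-21	evm.model.LG04.595	Chr4	5022583	5023333	660	219	23.73	6.35
CtHSP20-22	evm.model.LG04.659	Chr4	5719610	5720150	540	179	19.66	5.41
CtHSP20-23	evm.model.LG04.1562	Chr4	15238517	15239382	537	178	19.64	9.33
CtHSP20-24	evm.model.LG04.1746	Chr4	18664184	18664932	636	211	23.30	8.98
CtHSP20-25	evm.model.LG04.1747	Chr4	18667791	18669012	633	210	22.63	9.76
CtHSP20-26	evm.model.LG04.2200	Chr4	27791470	27792269	696	231	25.21	9.65
CtHSP20-27	evm.model.LG04.2202	Chr4	27841964	27842642	555	184	20.52	6.31
CtHSP20-28	evm.model.LG04.3547	Chr4	40383326	40383791	465	154	17.27	6.44
CtHSP20-29	evm.model.LG04.3818	Chr4	42785564	42785918	354	117	13.20	5.30
CtHSP20-30	evm.model.LG04.3952	Chr4	43822911	43823827	504	167	18.15	6.66
CtHSP20-31	evm.model.LG05.1343	Chr5	44933904	44934507	603	200	21.45	6.01
CtHSP20-32	evm.model.LG05.1634	Chr5	51747665	51786045	444	147	15.45	5.89
CtHSP20-33	evm.model.LG06.1594	Chr6	12730245	12730890	645	214	23.52	5.74
CtHSP20-34	evm.model.LG08.943	Chr8	15904441	15905347	750	249	27.53	8.95
CtHSP20-35	evm.model.LG08.1754	Chr8	24644033	24645368	585	194	21.73	4.90
CtHSP20-36	evm.model.LG08.2303	Chr8	29138893	29139831	828	275	30.77	9.39
CtHSP20-37	evm.model.LG09.715	Chr9	7378771	7379530	633	210	22.79	5.69
CtHSP20-38	evm.model.LG09.716	Chr9	7401085	7401854	633	210	23.17	5.61
CtHSP20-39	evm.model.LG09.717	Chr9	7406158	7406950	660	219	23.86	5.87
CtHSP20-40	evm.model.LG09.718	Chr9	7409020	7409923	774	257	27.67	5.66
CtHSP20-41	evm.model.LG09.852	Chr9	8975686	8976118	432	143	15.68	8.05
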