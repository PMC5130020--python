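protein_id	gene_id	gene_symbol	MLP3-cl	RF12-cl	RF26-cl
ENSMUSP00000002090	20832	Ssr4	1.01	1.71	1.38
ENSMUSP00000002198	67465	Sf3a1	-3.63	-3.02	-4.15
ENSMUSP00000005066	26395	Map2k1	2.42	2.25	1.28
ENSMUSP00000005292	21672	Prdx2	-4.14	-3.35	-3.21
ENSMUSP00000006764	11821	Aprt	2.05	1.24	1.59
ENSMUSP00000007814	16549	Khsrp	-2.04	-1.27	-1.91
ENSMUSP00000015583	13035	Ctsg	2.35	3.54	1.12
ENSMUSP00000016033	16993	Lta4h	1.90	2.00	1.72
ENSMUSP00000016703	15078	H3f3a	-2.36	-3.79	-2.17
ENSMUSP00000020779	17523	Mpo	-6.47	-4.47	-1.85
ENSMUSP00000021028	16416	Itgb3	-4.00	-4.28	-5.29
ENSMUSP00000022169	15212	Hexb	2.02	2.23	4.34
ENSMUSP00000023707	20655	Sod1	-1.77	-2.62	-1.86
ENSMUSP00000025486	16906	Lmnb1	-1.25	-1.19	-1.59
ENSMUSP00000025515	67988	Tmx3	1.94	1.06	1.17
ENSMUSP00000025651	14156	Fen1	-1.58	-1.10	-1.55
ENSMUSP00000028610	12359	Cat	-1.80	-1.57	-2.61
ENSMUSP00000029078	12349	Car2	-8.43	-6.64	-6.64
ENSMUSP00000030069	67103	Ptgr1	3.06	2.87	3.97
ENSMUSP00000030090	17025	Alad	-3.98	-3.31	-4.09
ENSMUSP00000031411	11669	Aldh2	1.64	1.83	1.35
ENSMUSP00000031447	11745	Anxa3	1.32	1.85	1.70
ENSMUSP00000032934	11674	Aldoa	2.16	1.94	1.99
ENSMUSP00000032949	12721	Coro1a	-1.35	-2.95	-6.51
ENSMUSP00000033184	12751	Tpp1	-2.21	-2.50	-3.34
ENSMUSP00000034049	11739	Slc25a4	1.27	3.63	1.61
ENSMUSP00000034756	12306	Anxa2	4.09	2.39	2.13
ENSMUSP00000037930	320011	Uggt1	3.02	1.95	2.23
ENSMUSP00000043092	233016	Blvrb	-2.71	-3.88	-3.01
ENSMUSP00000043926	18950	Pnp	2.47	2.20	1.36
ENSMUSP00000044827	18432	Mybbp1a	2.56	3.00	4.45
ENSMUSP00000044903	21825	Thbs1	-1.73	-2.79	-3.45
ENSMUSP00000047790	14870	Gstp1	-1.79	-2.80	-1.32
ENSMUSP00000048285	56307	Metap2	-1.50	-1.40	-2.06
ENSMUSP00000049355	14751	Gpi1	2.35	1.73	2.12
ENSMUSP00000050497	13861	Epx	-3.50	-5.66	-5.48
ENSMUSP00000052872	14104	Fasn	3.31	3.26	2.09
ENSMUSP00000062030	80838	Hist1h1a	-2.22	-1.98	-2.73
ENSMUSP00000063389	12332	Capg	-1.43	-4.74	-1.64
ENSMUSP00000064755	236539	Phgdh	-1.47	-1.61	-1.03
ENSMUSP00000075690	66222	Serpinb1a	2.31	2.55	1.91
ENSMUSP00000079727	13806	Eno1	2.45	2.16	1.73
ENSMUSP00000080302	18655	Pgk1	2.54	2.07	2.12
ENSMUSP00000081141	110208	Pgd	2.34	3.99	1.49
ENSMUSP00000089801	17105	Lyz2	-2.47	-2.87	-3.65
ENSMUSP00000095166	15288	Hmbs	-3.50	-3.20	-4.87
ENSMUSP00000098997	192176	Flna	-1.60	-2.34	-3.12
ENSMUSP00000099461	56431	Dstn	2.96	2.98	2.13
ENSMUSP00000099664	11637	Ak2	1.66	1.03	1.17
ENSMUSP00000106481	13382	Dld	1.08	4.12	1.24
ENSMUSP00000107653	12796	Camp	-2.64	-5.08	-3.04
ENSMUSP00000112606	108989	Tpr	1.65	1.23	1.42
ENSMUSP00000116466	14229	Fkbp5	3.38	3.09	2.28
ENSMUSP00000118601	15275	Hk1	6.46	2.43	2.80
ENSMUSP00000133099	11983	Atpif1	-1.42	-2.34	-2.23
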