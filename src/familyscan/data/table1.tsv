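name	gene_id	chromosome	start	end	orf_length	exon_count	aa_count	mw_kda	pi
StHsp20-1	PGSC0003DMG400008713	1	6195606	6196992	732	2	243	26.8	5.80
StHsp20-2	PGSC0003DMG400008714	1	6199128	6200118	669	2	222	24.5	8.91
StHsp20-3	PGSC0003DMG400008715	1	6205818	6207478	639	2	212	23.8	9.30
StHsp20-4	PGSC0003DMG400020718	1	79702817	79703750	576	1	191	21.8	6.87
StHsp20-5	PGSC0003DMG400016460	2	36223235	36224237	414	2	137	15.7	4.91
StHsp20-6	PGSC0003DMG400012619	2	47595303	47596399	426	2	141	16.3	8.32
StHsp20-7	PGSC0003DMG400003219	3	46254502	46257461	702	2	233	25.9	6.98
StHsp20-8	PGSC0003DMG400025350	3	53138385	53139192	651	2	216	24.5	4.98
StHsp20-9	PGSC0003DMG400024476	3	53878612	53879610	576	1	191	21.9	6.87
StHsp20-10	PGSC0003DMG400009173	3	61718867	61719420	444	2	147	16.5	7.64
StHsp20-11	PGSC0003DMG400023622	4	8358204	8359541	438	2	145	16.1	6.92
StHsp20-12	PGSC0003DMG400024099	4	60045801	60046965	882	2	293	33.1	6.00
StHsp20-13	PGSC0003DMG400031133	4	61728105	61729376	510	2	169	18.6	5.30
StHsp20-14	PGSC0003DMG400009996	4	71887737	71891840	462	2	153	16.7	7.71
StHsp20-15	PGSC0003DMG400010001	4	71971113	71980699	912	13	303	34.0	9.68
StHsp20-16	PGSC0003DMG400011977	5	11646812	11649618	681	3	226	26.2	9.39
StHsp20-17	PGSC0003DMG400030427	6	56896895	56897612	465	1	154	17.7	5.57
StHsp20-18	PGSC0003DMG400030426	6	56893292	56894077	465	1	154	17.6	5.83
StHsp20-19	PGSC0003DMG400030339	6	56900911	56901677	465	1	154	17.7	6.20
StHsp20-20	PGSC0003DMG400030340	6	56905147	56905872	465	1	154	17.6	7.91
StHsp20-21	PGSC0003DMG400030341	6	56907909	56908742	465	1	154	17.6	5.57
StHsp20-22	PGSC0003DMG401017288	7	50794176	50799268	753	6	250	27.9	9.19
StHsp20-23	PGSC0003DMG400019265	7	54203551	54205245	573	2	190	21.8	5.49
StHsp20-24	PGSC0003DMG400021737	8	34366816	34367720	477	1	158	17.7	6.17
StHsp20-25	PGSC0003DMG400008187	8	34544813	34545655	477	1	158	17.6	6.17
StHsp20-26	PGSC0003DMG400004808	8	52375001	52376265	636	2	211	23.9	6.45
StHsp20-27	PGSC0003DMG400004807	8	52380425	52381599	588	2	195	21.4	8.65
StHsp20-28	PGSC0003DMG400004806	8	52390914	52392554	513	2	170	18.5	5.05
StHsp20-29	PGSC0003DMG400020341	9	829873	831558	486	2	161	19.2	9.77
StHsp20-30	PGSC0003DMG400011719	9	888985	890624	582	2	193	22.7	7.06
StHsp20-31	PGSC0003DMG400002009	9	6945529	6946992	744	2	247	27.5	5.53
StHsp20-32	PGSC0003DMG400011628	9	11636814	11637710	465	1	154	17.5	6.21
StHsp20-33	PGSC0003DMG400011630	9	11675983	11676827	495	1	164	18.8	6.15
StHsp20-34	PGSC0003DMG400011631	9	11678942	11679778	474	1	157	17.9	6.21
StHsp20-35	PGSC0003DMG400011632	9	11684152	11685032	465	1	154	17.5	6.21
StHsp20-36	PGSC0003DMG400014956	9	31436185	31436781	402	1	133	15.3	6.19
StHsp20-37	PGSC0003DMG400017098	9	31745004	31745667	423	1	140	16.2	5.63
StHsp20-38	PGSC0003DMG400019136	10	50699792	50700705	705	1	234	27.3	9.56
StHsp20-39	PGSC0003DMG400019137	10	50704357	50705144	588	1	195	22.5	9.88
StHsp20-40	PGSC0003DMG400007210	10	59676867	59677589	444	2	147	16.5	8.89
StHsp20-41	PGSC0003DMG400009255	11	13518704	13519520	594	1	197	22.4	5.41
StHsp20-42	PGSC0003DMG400018717	11	42985862	42987493	744	2	247	27.5	8.32
StHsp20-43	PGSC0003DMG400002928	12	3139670	3140616	468	1	155	17.7	5.27
StHsp20-44	PGSC0003DMG400039484	12	3142147	3142608	462	1	153	17.3	5.54
StHsp20-45	PGSC0003DMG400047019	12	19504973	19513520	909	9	302	33.8	8.24
StHsp20-46	PGSC0003DMG400028624	12	49808899	49810200	690	2	229	26.2	8.44
StHsp20-47	PGSC0003DMG402010796	12	54506438	54507366	750	2	249	28.2	8.23
StHsp20-48	PGSC0003DMG400029311	12	57570831	57572324	423	6	140	15.5	6.19
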