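# source: 90-microhaplotype panel summary table (79 populations, GRCh37)
name	chrom	start_pos	extent_bp	snp_count	avg_ae	rosenberg_in	in_alfred
mh01KK-172	1	1486834	226	8	3.29	0.354	true
mh01KK-001	1	3743109	283	11	3.62	0.464	true
mh01KK-205	1	18722692	242	9	3.94	0.150	true
mh01KK-212	1	202616547	243	17	9.71	0.883	false
mh01KK-117	1	204633340	189	9	4.22	0.303	true
mh01NK-001	1	230820351	280	5	3.16	0.205	true
mh01KK-213	1	232811740	216	16	4.78	0.393	false
mh02KK-022	2	3172438	249	9	5.37	0.436	false
mh02KK-138	2	46191983	249	8	2.94	0.292	true
mh02KK-029	2	69138957	236	14	5.41	0.354	false
mh02KK-013	2	105833031	221	9	3.65	0.313	false
mh02KK-031	2	123395790	252	14	4.15	0.328	false
mh02KK-134	2	161079411	104	8	4.87	0.344	true
mh02KK-136	2	228092334	198	7	4.74	0.236	true
mh02KK-014	2	228524072	239	16	8.96	0.601	false
mh02KK-015	2	240004773	221	11	4.38	0.433	false
mh03KK-016	3	14377432	201	12	3.11	0.220	false
mh03KK-017	3	37516028	179	7	4.37	0.286	false
mh03KK-047	3	45166218	243	7	3.66	0.214	false
mh03KK-018	3	117156240	224	13	4.75	0.588	false
mh03KK-150	3	131645972	185	9	3.30	0.117	true
mh04KK-010	4	1986720	261	8	2.73	0.172	true
mh04KK-030	4	3666211	284	9	4.07	0.617	true
mh04KK-013	4	68444102	201	8	3.73	0.250	true
mh05KK-169	5	1898501	234	7	4.53	0.303	false
mh05KK-170	5	2447910	256	14	9.75	0.812	true
mh05KK-020	5	38881438	199	7	3.55	0.164	true
mh05KK-178	5	67309764	231	9	4.69	0.295	false
mh06KK-090	6	29937692	280	17	4.73	0.347	false
mh06KK-104	6	165798851	188	5	4.26	0.342	false
mh06KK-008	6	169656029	275	14	4.81	0.661	true
mh07KK-009	7	18861121	182	16	6.82	0.525	false
mh08KK-039	8	3516789	228	18	4.36	0.484	true
mh08KK-131	8	5461399	227	15	3.91	0.262	false
mh08KK-137	8	31083232	195	12	7.38	0.575	false
mh09KK-161	9	344087	289	10	2.99	0.558	true
mh09KK-010	9	2288476	264	10	4.46	0.450	false
mh09KK-145	9	4763309	218	9	5.08	0.388	false
mh09KK-153	9	103969642	247	7	5.69	0.521	true
mh09KK-157	9	135862478	155	7	3.53	0.237	true
mh10KK-162	10	3160652	266	13	5.18	0.356	false
mh10KK-167	10	12545332	222	8	4.73	0.275	false
mh10KK-170	10	78910042	190	7	2.61	0.288	true
mh11KK-180	11	1690714	271	12	5.10	0.567	true
mh11KK-181	11	2819168	128	10	4.27	0.302	false
mh11KK-183	11	20020042	217	12	6.43	0.438	false
mh11KK-190	11	97176319	224	7	4.55	0.301	false
mh11KK-191	11	99880163	190	7	3.52	0.288	true
mh12KK-199	12	12229744	209	8	4.03	0.172	false
mh12KK-201	12	27800327	177	15	8.36	0.804	false
mh12KK-202	12	30170229	154	5	3.07	0.137	true
mh12KK-046	12	118889488	289	8	4.85	0.256	true
mh12KK-209	12	130308483	191	7	4.52	0.255	false
mh13KK-213	13	23765409	273	11	5.09	0.339	true
mh13KK-215	13	36451857	242	10	4.40	0.322	true
mh13KK-217	13	46865888	235	10	5.04	0.387	true
mh13KK-218	13	54060710	263	7	7.62	0.481	true
mh13KK-225	13	66712622	207	7	3.43	0.231	true
mh13KK-221	13	101759088	253	12	6.39	0.681	false
mh13KK-222	13	106642644	252	13	4.56	0.382	false
mh13KK-223	13	110806689	237	11	4.22	0.256	true
mh14KK-227	14	52334089	215	10	4.53	0.297	false
mh14KK-048	14	74250537	194	8	3.22	0.283	true
mh15KK-067	15	46870730	196	7	3.26	0.317	true
mh15KK-066	15	52484819	271	10	3.39	0.259	true
mh16KK-049	16	7209185	250	19	4.64	0.410	true
mh16KK-302	16	7587615	233	10	3.04	0.296	true
mh16KK-255	16	81970352	193	14	3.63	0.342	true
mh16KK-259	16	83973819	248	14	7.85	0.571	false
mh16KK-011	16	84285727	198	11	5.43	0.407	false
mh16KK-262	16	87669318	258	13	4.67	0.330	false
mh17KK-272	17	52942335	260	11	3.74	0.203	true
mh17KK-012	17	77141265	245	13	3.09	0.275	false
mh17KK-013	17	77276404	245	10	3.58	0.233	false
mh17KK-278	17	78761546	187	7	5.48	0.439	false
mh18KK-293	18	76089732	237	7	3.46	0.324	true
mh19KK-299	19	22729500	182	10	4.05	0.281	true
mh19KK-300	19	51451043	182	7	4.25	0.349	false
mh20KK-306	20	895313	219	7	4.89	0.346	false
mh20KK-307	20	16513215	208	8	3.66	0.237	true
mh20KK-058	20	48844260	247	9	2.82	0.198	true
mh21KK-315	21	21880086	184	7	4.46	0.214	true
mh21KK-316	21	27782968	255	7	3.36	0.258	true
mh21KK-318	21	41260129	235	10	4.05	0.291	false
mh21KK-320	21	43062859	271	10	4.95	0.279	true
mh21KK-313	21	43942101	207	8	2.49	0.278	true
mh21KK-324	21	46714536	179	9	4.74	0.404	true
mh22KK-328	22	18518651	244	7	3.92	0.264	false
mh22KK-061	22	44763550	217	10	3.52	0.172	true
mh22KK-340	22	49060976	261	11	5.66	0.422	false
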