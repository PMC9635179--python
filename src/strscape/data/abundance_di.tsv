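chromosome	rat	mouse	gelada	baboon	macaque	gorilla	chimpanzee	bonobo	human
1	81509	59425	24335	23427	24462	23105	23708	23583	24657
2A	74837	53096	21315	20302	21225	11820	11960	11391	26989
2B	0	0	0	0	0	14494	14555	14334	0
3	53642	45464	20710	19973	20552	20939	21179	21039	21633
4	57299	44963	19364	18592	19038	21536	21182	20503	21773
5	52269	48069	22020	21275	22147	17099	17831	19606	20385
6	44993	45325	19921	19397	20070	18575	18391	18196	18995
7A	43219	40052	5832	16963	17870	15988	16727	16130	17275
7B	0	0	11934	0	0	0	0	0	0
8	43242	41103	15903	15390	16164	15837	15875	15718	16245
9	37463	39005	14733	14183	14857	11704	11935	11661	13080
10	40260	40998	10136	9432	9855	14051	14306	14032	14799
11	27685	38212	14360	14487	15187	12678	13988	13842	14189
12	22084	35361	13478	14325	14685	14385	14559	14588	14757
13	38331	35159	11839	11292	11797	11071	11258	11135	11406
14	31923	36644	13605	13243	13885	9549	9465	9386	9798
15	31768	30662	12078	11661	12014	8014	8226	8143	8607
16	28704	29521	8228	8064	8206	7814	8268	7553	8947
17	30312	28209	11002	10457	10942	10456	8056	8006	8355
18	27797	27263	8548	8349	8591	8629	8597	8497	8750
19	21794	18350	5994	5493	5395	4774	6081	5865	6220
20	20191	0	8334	7902	8345	6379	7106	6623	6612
21	0	0	0	0	0	4092	4154	4123	4884
22	0	0	0	0	0	3209	3442	3183	3746
X	36246	38470	18303	16787	17659	17922	18193	17078	18952
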