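chromosome	rat	mouse	gelada	baboon	macaque	gorilla	chimpanzee	bonobo	human
1	25234	18913	16307	15350	15341	14540	15219	15054	14882
2A	22996	17856	13005	12341	11998	6800	6842	6537	14521
2B	0	0	0	0	0	7545	7764	7822	0
3	16869	15022	12749	12518	11938	11473	11744	11637	11631
4	17088	15204	11921	11154	10960	11116	11228	10685	11144
5	16339	15469	13001	12514	12112	10581	9665	10640	10649
6	13495	14332	12150	11743	11380	10364	10504	10445	29430
7A	14317	13760	3937	10991	10871	9342	10117	9744	9995
7B	0	0	7552	0	0	0	0	0	0
8	12701	13518	10032	9524	9682	8752	9096	8645	8890
9	11646	12378	9295	8755	8659	6898	7328	7157	7580
10	12552	13968	7297	6728	6786	8096	8350	8245	8295
11	7987	13232	9615	9578	9403	7801	8668	8458	8352
12	6060	11817	7742	8297	8029	8905	9218	9051	9127
13	10852	11634	7266	6823	6860	5273	5479	5452	5391
14	10325	11865	8869	8583	8253	5473	5771	5785	5706
15	10075	10693	7727	7339	7152	4869	5168	5082	5297
16	8476	9527	6228	5837	5801	5738	6007	5623	6402
17	9502	10045	5908	5737	5684	5666	5859	5914	6091
18	8124	9154	4738	4645	4603	4722	4625	4584	4566
19	6984	6190	5432	4643	4664	3807	5438	5230	5101
20	6445	0	6655	6016	5945	4072	4472	4155	4130
21	0	0	0	0	0	2051	2092	2028	2304
22	0	0	0	0	0	2721	2825	2601	2915
X	10411	13783	11449	10609	10666	9547	9838	9140	10062
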