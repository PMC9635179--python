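chromosome	rat	mouse	gelada	baboon	macaque	gorilla	chimpanzee	bonobo	human
1	53318	47294	90549	87241	83595	77718	79390	79173	82820
2A	46221	45636	71588	67963	64609	35908	35897	34400	78550
2B	0	0	0	0	0	40245	39968	39837	0
3	36364	38493	70736	68688	65836	62398	62713	64472	64027
4	34818	39019	62831	60726	57817	54896	54855	53287	56495
5	36532	38805	66164	64101	61533	60436	48944	54142	56538
6	28617	35751	63104	61642	59150	53872	53769	53420	55185
7A	29411	33649	25699	65267	63438	50898	53882	50792	56257
7B	0	0	42663	0	0	0	0	0	0
8	27353	31938	50576	48446	46757	43593	44212	43618	45220
9	23532	31142	50050	47879	46910	36797	38035	37493	41744
10	31065	34138	41475	39012	37477	44166	44562	44416	46075
11	17071	33869	54287	54284	51654	37218	41059	40757	42217
12	15101	29325	42675	35365	42793	46865	47576	47481	48483
13	21673	29496	40602	39101	38022	27902	28481	28479	29430
14	21835	28835	45820	44693	42677	30311	30659	30595	31460
15	20351	25753	43334	41671	40009	28611	29752	29049	31402
16	15958	24139	41211	39781	37693	29268	31121	28460	34364
17	18458	24234	32308	31285	30378	29884	36791	37010	38947
18	16651	22580	25310	24850	23551	22556	22428	22236	23130
19	14266	16221	35819	32702	30470	23832	31405	30614	32423
20	14475	0	34962	32965	32095	20654	22106	31034	21961
21	0	0	0	0	0	10462	10633	10467	12050
22	0	0	0	0	0	13778	14816	13904	16014
X	25983	40547	52836	49013	47590	43138	43302	41656	46178
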