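allele_id	aa_seq	length	novel	copies_ligustica	copies_buckfast	copies_sicula	copies_carnica	copies_hybrid_carnica	copies_mellifera	copies_cecropia	genbank_ids
1	SSLSNKTIHNNNNYKYNYNNNNYNNNNYNNNYNNNCKKLYYNINYIEQI	49	1	3	0	0	0	0	0	0	
2	SSLSNNYNYNNYNNNYKPLYYNINYIEQI	29	0	2	1	0	0	0	0	0	AAS86659.1,AAS86660.1,AAS86661.1,AAS86663.1,ABD14105.1,ABD14106.1,ABD14107.1,ABD14108.1,AGA84527.1
3	SSLSNNYNSNSYNNYNNNYKKLQYYNIINIEQI	33	0	2	0	0	0	0	0	0	CCF23480.1,QEN96041.1
4	SSLSNNTIHNNNYKYNYNNNYNNYNNYKKLYYNINYIEQI	40	1	1	1	0	0	0	0	0	
5	SSLSNKTIHNNNNYKYNYNNNYNNNNNYSKKLYYNINYIEQI	42	0	3	0	0	0	0	0	0	AQZ41186.1,AQZ41196.1,AQZ41212.1,QEN96050.1
6	SSLSNNYNYSNYNNYNNYNNNYNNYKKLYYNINYIEQI	38	0	2	0	0	0	0	0	0	CCF23508.1
7	SSLSKNTIHNNNYKYNYNNNNNYNNNYKKLQYYNINYIEQI	41	0	2	2	0	0	0	0	0	CCF23518.1
8	SSLSNSCNYSNNYYNKKLYYNIINIEQI	28	0	2	1	0	0	0	0	0	CCF23469.1
9	SSLSNKTIHNNNNYKYNYNNKYNYNNNNYNKKLYYKNYIINIEQI	45	0	1	4	0	0	0	0	0	ABD14097.1,QEN96103.1
10	SSLSNNYNYSNYNNYNNNYNNYKKLYYNINYIEQI	35	0	2	0	0	0	0	0	0	ABV56215.1
11	SSLSNNYISNISNYNNNNNSKKLYYNINYIEQI	33	0	3	0	0	0	0	0	0	AGZ61876.1,CCF23481.1,CCF23482.1
12	SSLSKNTIHNNNYKYNYNNNNYNNSKKLYYNINYIEQI	38	0	2	0	0	0	0	0	0	CCF23507.1
13	SSLSNKTIHNNNNYKYNYNNNNYKNYNNYKKLYYNINYIEQI	42	0	1	1	0	1	0	0	0	AQZ41220.1
14	SSLSNKTIHNNNNYNNYKKLYYNIINIEQI	30	1	2	0	0	0	0	0	0	
15	SSLSNNTIHNNNYKYNNYNNYNKKLYYNIINIEQI	35	0	2	0	0	0	0	0	0	CCF23492.1
16	SSLSNKTIHNNNNYNNNNYNNYKKLYYNINYIEQI	35	1	1	1	0	1	0	0	0	
17	SSLSNNTIHNNNNYNKKLYYNIINIEQI	28	0	1	1	0	0	0	0	0	AGZ61866.1,AGZ61871.1,AGZ61872.1,AGZ61874.1,CCF23470.1
18	SSLSNKTIHNNNNYKYNYNNNCKKLYYNINYIEQI	35	0	1	0	0	0	1	0	0	ABD14096.1,QEN96024.1,QEN96028.1
19	SSLSNNYKYSNYNNYNNNYNNNYNNNYNNNYKKLYKNYIINIEQI	45	0	0	3	0	0	1	0	0	ABD14145.1,ABD14146.1,ADJ57940.1
20	SSLSNNYNSNNYNKYNYNNSKKLYYNINYIEQI	33	0	0	3	0	0	0	0	0	CCF23483.1
21	SSLSNKTIHNNNNYNNNNYNNYKKLYYNIINIEQI	35	0	0	1	0	1	0	0	0	AEI99777.1
22	SSLSNNYKYSNYNNYNNNYNNYNNNYNNNYKKLYYNINYIEQI	43	0	0	1	0	1	0	0	0	CCF23533.1
23	SSLSNHYNYNNNKYNNYNNDYKKLYYNINYIEQI	34	0	2	0	0	0	0	0	0	ADJ57943.1,AQZ41194.1,AQZ41195.1
24	SSLSNKTIHNNNNYKYNYKNYNNSKKLYYNVINIEQI	37	0	0	1	0	0	0	0	1	AEI99780.1,AEI99781.1,AEI99790.1
25	SSLSNKTIHNNNNYNNYKKLYYNINYIEQI	30	0	0	0	0	2	0	0	0	AQZ41206.1,AQZ41207.1,AQZ41208.1,CCF23474.1
26	SSLSNKTIHNNNKYNYNKYNYNNNNYNNYKKLYYNINYIEQI	42	0	0	1	0	1	0	0	0	CCF23526.1
27	SSLSNNYNYNNNNYNNYNNNYNNNYNKKLYYNIINIEQI	39	0	0	2	0	1	0	0	0	AQZ41204.1,AQZ41205.1,CCF23512.1
28	SSLSNKTIHNNNNYKYNYNNNNYNNNYNNNCKKLYYNIINIEQI	44	0	1	0	0	0	0	1	0	AEI99762.1,QEN96035.1
29	SSLSNNYNYNNNNYNNNYNKKLYYNINYIEQI	32	0	1	0	1	0	0	0	0	ADJ57960.1,AEI99714.1,AEI99724.1,AEI99729.1,AEI99733.1,AEI99735.1,AEI99736.1,AEI99738.1,AEI99741.1,AEI99743.1,AEI99744.1,AEI99755.1,AEI99759.1
30	SSLSNNYNSNNYYNYNNNKKLYYKNYIINIEQI	33	1	0	0	2	0	0	0	0	
31	SSLSNKTIHNNNNYKYNYNNKYNYNNNNYNNNNYNKKLYYKNYIINIEQI	50	0	2	0	1	0	0	0	0	AQZ41179.1,AQZ41181.1,AQZ41192.1,AQZ41193.1,QEN96025.1
32	SSLSNSCNYSNNYNNNYNNTKKLYYNINYIEQI	33	0	3	0	0	0	0	0	0	AEI99783.1,AEI99788.1,AEI99792.1,AGZ61869.1
33	SSLSNKTIHNNNNYKNYNYKKLYYNIINIEQI	32	0	1	0	0	0	0	0	0	CCF23479.1
34	SSLSNNYNYSNYNNNNYKQLCYNINYIEQI	30	0	1	0	0	0	0	0	0	ABD14139.1,ABD14141.1,ABD14142.1,ABD14143.1,ABD14144.1,AGA84531.1,AGZ61875.1,QEN96094.1
35	SSLSNNYNYSNYNNYNNYNNNYNNYNNNYNNYKKLYYNINYIEQI	45	0	0	1	0	0	0	0	0	CCF23536.1
36	SSLSNNYNSNSYNNYNNNYYNNKKLQYYNINYIEQI	36	0	1	0	0	0	0	0	0	AGA84533.1,CCF23490.1,QEN96078.1
37	SSLSNKTIHNNNNYNNNNYNNYNNNNYNNYKKLYYNIINIEQI	43	0	0	1	0	0	0	0	0	QEN96087.1
38	SSLSSNYNSNNYNNYNNYKQLCYNINYIEQI	31	0	0	0	0	0	0	1	0	ART88596.1,CCF23477.1
39	SSLSNNYNYNNNKYNYNNNNYKQLCYNINYIEQI	34	0	1	0	0	0	0	0	0	AEI99717.1,AEI99718.1,AEI99720.1,AEI99721.1,AEI99726.1,AEI99732.1,AEI99734.1,AEI99740.1,AEI99742.1,AGA84529.1
40	SSLSNKTIHNNNNYNNNNYNNYNNNNYNNYKKLYYNINYIEQI	43	0	1	0	0	0	0	0	0	CCF23531.1
41	SSLSNNYKYSNYNNYNNNNYNNNNYNNNSKKLYYNIINIEQI	42	0	1	0	0	0	0	0	0	AGA84526.1,CCF23524.1
42	SSLSNKTIHNNNNYNNNNYKKLQYYNINYIEQI	33	0	1	0	0	0	0	0	0	ABV56220.1,AQZ41221.1,QEN96101.1
43	SSLSNNYNYNNNNYNNYNNNYNNNYNKKLYYNINYIEQI	39	0	1	0	0	0	0	0	0	QEN96052.1,QEN96059.1
44	SSLSNKTIHNNNYKYNYYNNNNYKKLQYYNIINIEQI	37	1	1	0	0	0	0	0	0	
45	SSLSNNYNYNNNNYNNYNNYNNYNNNYNKKLYYNINYIEQI	41	0	1	0	0	0	0	0	0	ABV56219.1
46	SSLSNNYKYSNYNNYNNYNKKLYYKNYIINIEQI	34	0	1	0	0	0	0	0	0	ABD14104.1,ADJ57958.1,AGA84523.1,QEN96085.1,QEN96088.1
47	SSLSNNYNYNNNNYNNYNNYNNNYNNNYNKKLYYNINYIEQI	42	1	1	0	0	0	0	0	0	
48	SSLSNNYKYSNYNNNNYNNNSKKLYYNINYIEQI	34	0	1	0	0	0	0	0	0	AQZ41199.1,CCF23485.1
49	SSLSNKTIHNNNNYNNNNYNKKLYYNINYIEQI	33	1	1	0	0	0	0	0	0	
50	SSLSNKTIHNNNNYKYNYNNNNYNNNYNNYKKLYYNINYIEQI	43	0	1	0	0	0	0	0	0	CCF23532.1,QEN96032.1,QEN96033.1,QEN96042.1
51	SSLSNKTIHNNNNYKNYNNYKNYNNYKKLYYNINYIEQI	39	0	0	0	0	1	0	0	0	CCF23513.1
52	SSLSNKTIHNNNNYKYNYNNNNYNNNNYNKKLYYKNYIINIEQI	44	0	1	0	0	0	0	0	0	CCF23527.1
53	SSLSNNTIHNNNYKYNYNNKYNYNNKKLYYNIINIEQI	38	0	0	0	0	1	0	0	0	CCF23510.1,QEN96012.1
54	SSLSNKTIHNNNNYKYNYNNNNYNNNNYNNNYNNNCKKLYYNIINIEQI	49	0	0	1	0	0	0	0	0	AAQ57659.1,QEN96069.1
55	SSLSNNYNSNSYNNNYNNNYYNKKLQYYNINYIEQI	36	0	0	1	0	0	0	0	0	CCF23486.1
56	SSLSNNYKYSNYNNYNNYNNNNYNNYNNYNNKKLYYNIINIEQI	44	1	0	1	0	0	0	0	0	
57	SSLSNKTIHNNNNYKKLYYNINYIEQI	27	0	0	1	0	0	0	0	0	CCF23466.1
58	SSLSNNYNYSNYNNYNNYKKLYYNINYIEQI	31	0	0	1	0	0	0	0	0	CCF23475.1
59	SSLSNNTIHNNNYKYNYNNNNYNNNNYNKKLYYNIINIEQI	41	0	0	1	0	0	0	0	0	ABD14102.1,ABD14103.1,AEI99760.1,AEI99784.1
60	SSLSNNYNYSNYNNYNNNNNYNNYKKLYYNINYIEQI	37	0	1	0	0	0	0	0	0	ABD14109.1,ABD14110.1,ABD14111.1,ABD14112.1,ABD14113.1,ABD14114.1,ABD14115.1,ABD14116.1,AQZ41223.1,QEN96102.1
61	SSLSNNYKYSNYNNYNNNYNNYNNNYKKLYYNINYIEQI	39	0	1	0	0	0	0	0	0	AEI99754.1,AEI99786.1,AEI99787.1,AEI99789.1
62	SSLSSSCNYSNNYNNYYNNNKKLYYNIINIEQI	33	0	1	0	0	0	0	0	0	AGA84525.1,AIS73042.1,AIS73050.1,CCF23484.1,QEN96007.1,QEN96009.1,QEN96018.1,QEN96019.1,QEN96026.1,QEN96061.1,QEN96074.1,QEN96084.1,QEN96097.1,QEN96105.1
63	SSLSNKTIHNNNKYNYNNNYNNNCKKLYYNINYIEQI	37	1	0	0	0	0	0	0	1	
64	SSLSNNRNSNNYNNYNYKKLYYNINYIEQI	30	0	0	1	0	0	0	0	0	ABV56222.1,CCF23473.1
65	SSLSNNYNYSNYNNYNNNYNNNYNNNDYKKLYYKNYIINIEQI	43	0	0	1	0	0	0	0	0	ABV56216.1,QEN96106.1
66	SSLSNNYNYSNYNNYNNNNYNNYKKLYYNINYIEQI	36	0	0	0	0	0	1	0	0	CCF23496.1
67	SSLSNNYNYSNNYNNYYNNNNNYNNYKKLYYNIINIEQI	39	0	0	0	0	0	1	0	0	AEI99727.1,AEI99728.1
68	SSLSKNTIHNNNYNNSKKLYYNIINIEQI	29	0	0	1	0	0	0	0	0	AEI99716.1
69	SSLSNKTIHNNNNYNNNYNNNCKKLYYNIINIEQI	35	1	0	0	0	0	0	1	0	
70	SSLSNKTIHNNNNYNNNNYNNNNYNNNNYKKLQYYNINYIEQI	43	1	0	0	0	0	0	1	0	
71	SSLSNNYKYSNYNNYNNNNYKKLQYYNINYIEQI	34	1	1	0	0	0	0	0	0	
72	SSLSNKTIHNNNNYKYNYNNNNYKPYYNINYIEQI	35	0	1	0	0	0	0	0	0	AEI99745.1
73	SSLSNKTIHNNNNYKYNYNNNYKKLYYKNYIINIEQI	37	1	0	0	1	0	0	0	0	
74	SSLSNKTIHNNNNYKYNYNNNYNNNSKKLQYYYNINYIEQI	41	1	0	0	1	0	0	0	0	
75	SSLSNKTIHNNNYKYNYNNKHNYNKLYYNINYIEQI	36	1	0	0	1	0	0	0	0	
76	SSLSNNYKYSNYNNYNNYNNNSKKLYKNYIINIEQI	36	0	0	0	1	0	0	0	0	AQZ41187.1,AQZ41197.1,AQZ41198.1,ART88598.1,CCF23491.1,QEN96020.1,QEN96040.1
77	SSLSNKTIHNNNNYNNNNYNNYNNNNYNYKKLYYNINYIEQI	42	0	1	0	0	0	0	0	0	CCF23528.1
78	SSLSNKTIHNNNNYKYNYNNNYNNNSKKLYYNINYIEQI	39	0	1	0	0	0	0	0	0	AGA84537.1,CCF23514.1
79	SSLSNNYNYSNYNNYNNNYNNYNKKLYYNINYIEQI	36	0	0	1	0	0	0	0	0	ABD14117.1
80	SSLSNKTIHNNNNYKNYNNYKNYNNYKNYNNYKKLYYNINYIEQI	45	1	0	1	0	0	0	0	0	
81	SSLSNNYNYNNYNNTNNINKQLYYNINYIEQI	32	0	0	1	0	0	0	0	0	ABV56218.1,AQZ41218.1,QEN96077.1,QEN96095.1
82	SSLSNNYSYNNYNNNNYNKKLYYNINYIEQI	31	0	0	1	0	0	0	0	0	CCF23476.1,QEN96068.1
83	SSLSNNYNYNNNNYNNYNNNYNKKLYYNINYIEQI	35	0	0	1	0	0	0	0	0	AQZ41215.1,AQZ41216.1,AQZ41217.1,CCF23487.1
84	SSLSNNYNYSNYNNYNNNNNYNNNNYNYKKLYYNINYIEQI	41	1	0	1	0	0	0	0	0	
85	SSLSNKTIHNNNNNYNNYNKKLYYNIINIEQI	32	1	1	0	0	0	0	0	0	
86	SSLSNNTIHNNNNYKYNYNNNYNNYNNYNNKKLYYNIINIEQI	43	0	0	1	0	0	0	0	0	CCF23529.1
87	SSLSTNTIHNNNNYKYNYNNNYNNYNNKKLYYNINYIEQI	40	1	1	0	0	0	0	0	0	
88	SSLSNNYISNISNYNNNNNYNKKLYYNINYIEQI	34	0	1	0	0	0	0	0	0	AAQ67418.1,ABD14119.1,DAA06292.1,QEN96014.1,QEN96029.1,QEN96031.1,QEN96036.1,QEN96038.1,QEN96045.1,QEN96055.1,QEN96057.1,QEN96079.1
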