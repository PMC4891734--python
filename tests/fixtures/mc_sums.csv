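j,count,sum_zmax,sum_zbar
0,44710,np.float64(30321.121401359167),np.float64(22885.18838221282)
1,13253,np.float64(26905.19556522548),np.float64(16380.22898471009)
2,6701,np.float64(19637.605783612828),np.float64(11149.516450361876)
3,4261,np.float64(15630.903529374707),np.float64(8581.375794848278)
4,3017,np.float64(13014.867123389355),np.float64(7062.287368478505)
5,2200,np.float64(10515.412301651764),np.float64(5630.535666206085)
6,1837,np.float64(9942.365784915839),np.float64(5266.146828853521)
7,1496,np.float64(8737.39349544992),np.float64(4593.583734844912)
8,1228,np.float64(7734.227219413332),np.float64(4038.983794160414)
9,1096,np.float64(7300.28111972195),np.float64(3793.0106903134406)
10,916,np.float64(6556.544265071),np.float64(3377.7042267075008)
11,783,np.float64(5961.167430624936),np.float64(3079.9932954945484)
12,752,np.float64(5869.726849459791),np.float64(3045.333076580244)
13,621,np.float64(5145.7741201061535),np.float64(2647.4001924187673)
14,598,np.float64(5160.152236956493),np.float64(2674.229157352884)
15,517,np.float64(4594.842567305236),np.float64(2358.938877419701)
16,474,np.float64(4402.74443407299),np.float64(2249.3316091914357)
17,467,np.float64(4448.398266799891),np.float64(2257.032397884832)
18,399,np.float64(3888.876749140249),np.float64(1965.6364310009928)
19,383,np.float64(3994.3963584475864),np.float64(2032.8390980290947)
20,310,np.float64(3151.8417010716953),np.float64(1611.0478684858856)
21,312,np.float64(3327.594567811298),np.float64(1688.8938133464785)
22,263,np.float64(2911.3678801799692),np.float64(1491.287050818913)
23,291,np.float64(3288.7941174625867),np.float64(1647.6638566232764)
24,245,np.float64(2778.827092448228),np.float64(1390.877314683906)
25,232,np.float64(2726.5432003565384),np.float64(1368.8520175735587)
26,235,np.float64(2805.978823906165),np.float64(1421.076530648786)
27,209,np.float64(2542.145642961642),np.float64(1290.909340739402)
28,219,np.float64(2710.253308237181),np.float64(1384.9086360026506)
29,204,np.float64(2645.7837780253),np.float64(1327.710510385863)
30,190,np.float64(2441.7901690135322),np.float64(1223.8024445522487)
31,191,np.float64(2569.997776165133),np.float64(1282.6208448503132)
32,182,np.float64(2438.909188130663),np.float64(1252.7742077783448)
33,176,np.float64(2425.3936712185596),np.float64(1215.2923054007667)
34,156,np.float64(2149.8014421625066),np.float64(1089.2317904672475)
35,154,np.float64(2144.5684963007893),np.float64(1111.645122408256)
36,135,np.float64(1977.3799775298187),np.float64(1002.772482951808)
37,135,np.float64(1950.88207872711),np.float64(982.6436151451328)
38,156,np.float64(2263.287722392974),np.float64(1139.4474802369082)
39,121,np.float64(1877.011882430978),np.float64(948.5592167793985)
40,117,np.float64(1792.9098569680746),np.float64(924.0266063708448)
41,123,np.float64(1829.090821690456),np.float64(917.0652469309144)
42,134,np.float64(2111.853283823177),np.float64(1062.227409919966)
43,110,np.float64(1775.4501464522646),np.float64(869.9518165399361)
44,101,np.float64(1585.0720329127348),np.float64(803.1899205757551)
45,113,np.float64(1796.9657400102221),np.float64(919.9751780829117)
46,109,np.float64(1786.292925120983),np.float64(889.234531535162)
47,103,np.float64(1710.2709993481951),np.float64(862.7065096113026)
48,76,np.float64(1308.2933144925662),np.float64(674.1636638031509)
49,96,np.float64(1663.63980000638),np.float64(839.9580884296684)
50,94,np.float64(1570.943227544303),np.float64(803.748779095436)
51,96,np.float64(1607.9378451452417),np.float64(819.1462306945631)
52,79,np.float64(1364.8107150640776),np.float64(695.2728757891045)
53,75,np.float64(1286.9141857777734),np.float64(624.6247631634772)
54,76,np.float64(1301.676754811876),np.float64(648.6812715894557)
55,78,np.float64(1358.1949868625336),np.float64(694.4618839551507)
56,84,np.float64(1449.952023408774),np.float64(745.1731035613035)
57,54,np.float64(990.2734610073712),np.float64(493.4073939603193)
58,86,np.float64(1616.9420252032958),np.float64(799.0056459697078)
59,73,np.float64(1396.0239038929049),np.float64(709.6125168073914)
60,70,np.float64(1326.9583337104211),np.float64(663.2819132536553)
61,70,np.float64(1300.7769969906806),np.float64(662.3062036547872)
62,68,np.float64(1340.1319637683528),np.float64(679.5017787491955)
63,68,np.float64(1245.6632380639742),np.float64(633.2137165256831)
64,59,np.float64(1117.8713756743573),np.float64(545.8944220398888)
65,59,np.float64(1203.5112380510561),np.float64(615.4040900666073)
66,63,np.float64(1305.235052650988),np.float64(678.3608265738504)
67,57,np.float64(1074.3331122006648),np.float64(544.7903147520826)
68,53,np.float64(1013.3870541927262),np.float64(497.06634190694615)
69,71,np.float64(1420.895232549978),np.float64(717.0960692619128)
70,48,np.float64(992.6972757916072),np.float64(509.3126233978711)
71,51,np.float64(1069.8404301077887),np.float64(539.3550543739965)
72,51,np.float64(1040.9189749550258),np.float64(513.8684683153288)
73,56,np.float64(1219.2307430861579),np.float64(594.2988379028598)
74,43,np.float64(899.3754141589815),np.float64(443.2981260095864)
75,51,np.float64(1100.9391481248465),np.float64(570.5434507796447)
76,40,np.float64(907.4838215787311),np.float64(443.5091578821633)
77,63,np.float64(1354.0072869080118),np.float64(676.416965686517)
78,55,np.float64(1227.4797384213462),np.float64(627.854663488833)
79,48,np.float64(1022.4769905198458),np.float64(520.7704523601757)
80,41,np.float64(909.3821285377894),np.float64(461.16612588652583)
81,54,np.float64(1189.6478686145233),np.float64(596.8529983992937)
82,39,np.float64(891.7139583263865),np.float64(458.5253496516904)
83,41,np.float64(865.4751313487083),np.float64(424.3788434461994)
84,49,np.float64(1132.4346451756567),np.float64(571.7036101197522)
85,36,np.float64(775.1221223167986),np.float64(378.6999763842643)
86,44,np.float64(1028.777395210178),np.float64(504.5487061115072)
87,39,np.float64(883.223365981237),np.float64(449.98715727152705)
88,45,np.float64(1021.3921754330153),np.float64(518.176127362643)
89,28,np.float64(648.0451725440352),np.float64(316.06242115786563)
90,20,np.float64(522.5887253850871),np.float64(258.33381946441426)
91,38,np.float64(904.0424825517092),np.float64(443.79595392951154)
92,36,np.float64(828.4871986108776),np.float64(412.1988038100064)
93,29,np.float64(680.8623858459265),np.float64(345.72597538935383)
94,32,np.float64(795.6882694748488),np.float64(392.28542286956593)
95,36,np.float64(898.8781246476601),np.float64(462.0625545602207)
96,35,np.float64(785.4057573208485),np.float64(389.7523844361229)
97,39,np.float64(970.1352386124876),np.float64(493.9700112653683)
98,26,np.float64(647.4336133150904),np.float64(319.45057298867596)
99,36,np.float64(897.3502860139394),np.float64(439.1747304450618)
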