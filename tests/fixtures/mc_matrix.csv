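j,k,count
0,0,43798
0,1,912
1,0,6988
1,1,6139
1,2,126
2,0,1024
2,1,4833
2,2,827
2,3,17
3,0,147
3,1,2654
3,2,1318
3,3,140
3,4,2
4,0,20
4,1,1319
4,2,1385
4,3,274
4,4,19
5,0,2
5,1,669
5,2,1158
5,3,324
5,4,47
6,1,295
6,2,959
6,3,487
6,4,88
6,5,8
7,1,154
7,2,694
7,3,508
7,4,123
7,5,17
8,1,81
8,2,488
8,3,470
8,4,158
8,5,28
8,6,3
9,1,33
9,2,397
9,3,452
9,4,166
9,5,43
9,6,5
10,1,19
10,2,261
10,3,360
10,4,209
10,5,49
10,6,15
10,7,3
11,1,8
11,2,161
11,3,318
11,4,202
11,5,77
11,6,16
11,7,1
12,1,5
12,2,134
12,3,315
12,4,184
12,5,95
12,6,17
12,7,2
13,2,72
13,3,228
13,4,201
13,5,93
13,6,25
13,7,2
14,2,53
14,3,202
14,4,200
14,5,99
14,6,33
14,7,8
14,8,3
15,2,41
15,3,165
15,4,165
15,5,97
15,6,40
15,7,5
15,8,3
15,9,1
16,2,18
16,3,133
16,4,170
16,5,92
16,6,38
16,7,21
16,8,2
17,2,17
17,3,117
17,4,150
17,5,111
17,6,45
17,7,22
17,8,5
18,2,12
18,3,74
18,4,151
18,5,97
18,6,46
18,7,15
18,8,4
19,2,4
19,3,71
19,4,110
19,5,104
19,6,48
19,7,32
19,8,10
19,9,3
19,10,1
20,2,2
20,3,50
20,4,113
20,5,87
20,6,33
20,7,19
20,8,4
20,10,2
21,2,4
21,3,43
21,4,90
21,5,81
21,6,64
21,7,21
21,8,8
21,11,1
22,2,3
22,3,29
22,4,70
22,5,73
22,6,43
22,7,30
22,8,14
22,9,1
23,2,2
23,3,31
23,4,73
23,5,81
23,6,55
23,7,27
23,8,17
23,9,3
23,11,2
24,2,1
24,3,13
24,4,77
24,5,67
24,6,49
24,7,20
24,8,13
24,9,4
24,10,1
25,3,14
25,4,55
25,5,65
25,6,48
25,7,39
25,8,3
25,9,6
25,10,2
26,3,11
26,4,50
26,5,71
26,6,54
26,7,27
26,8,12
26,9,9
26,11,1
27,3,11
27,4,44
27,5,57
27,6,44
27,7,27
27,8,18
27,9,8
28,3,8
28,4,38
28,5,65
28,6,52
28,7,29
28,8,15
28,9,11
28,10,1
29,3,9
29,4,32
29,5,45
29,6,49
29,7,30
29,8,25
29,9,7
29,10,4
29,11,3
30,3,3
30,4,32
30,5,44
30,6,55
30,7,28
30,8,18
30,9,3
30,10,5
30,12,2
31,3,5
31,4,24
31,5,42
31,6,47
31,7,35
31,8,18
31,9,11
31,10,5
31,11,2
31,13,1
31,14,1
32,3,3
32,4,18
32,5,43
32,6,40
32,7,50
32,8,19
32,9,3
32,10,3
32,11,3
33,3,3
33,4,21
33,5,33
33,6,49
33,7,30
33,8,16
33,9,14
33,10,4
33,11,4
33,12,2
34,2,1
34,4,15
34,5,40
34,6,36
34,7,29
34,8,17
34,9,9
34,10,4
34,11,3
34,12,1
34,13,1
35,3,1
35,4,15
35,5,33
35,6,37
35,7,23
35,8,27
35,9,12
35,10,3
35,11,2
35,12,1
36,4,12
36,5,19
36,6,32
36,7,37
36,8,15
36,9,7
36,10,4
36,11,3
36,12,6
37,3,1
37,4,7
37,5,27
37,6,32
37,7,27
37,8,20
37,9,13
37,10,4
37,11,3
37,12,1
38,3,2
38,4,7
38,5,28
38,6,40
38,7,35
38,8,20
38,9,9
38,10,9
38,11,6
39,4,6
39,5,20
39,6,24
39,7,20
39,8,19
39,9,17
39,10,7
39,11,5
39,12,2
39,14,1
40,4,8
40,5,13
40,6,22
40,7,27
40,8,25
40,9,11
40,10,4
40,11,3
40,12,3
40,13,1
41,4,6
41,5,25
41,6,26
41,7,25
41,8,14
41,9,14
41,10,9
41,11,3
41,12,1
42,4,5
42,5,19
42,6,23
42,7,26
42,8,26
42,9,14
42,10,11
42,11,8
42,12,1
42,14,1
43,3,2
43,4,4
43,5,10
43,6,18
43,7,22
43,8,21
43,9,15
43,10,7
43,11,5
43,12,5
43,14,1
44,3,1
44,4,3
44,5,14
44,6,21
44,7,22
44,8,13
44,9,12
44,10,8
44,11,3
44,12,2
44,13,2
45,4,1
45,5,8
45,6,24
45,7,32
45,8,20
45,9,11
45,10,11
45,11,5
45,12,1
46,4,3
46,5,9
46,6,24
46,7,17
46,8,17
46,9,21
46,10,10
46,11,4
46,12,3
46,13,1
47,4,1
47,5,8
47,6,17
47,7,23
47,8,20
47,9,15
47,10,11
47,11,5
47,12,2
47,14,1
48,3,1
48,4,1
48,5,3
48,6,9
48,7,23
48,8,8
48,9,12
48,10,7
48,11,6
48,12,5
48,13,1
49,4,3
49,5,6
49,6,12
49,7,23
49,8,11
49,9,13
49,10,14
49,11,9
49,12,2
49,13,3
50,4,3
50,5,8
50,6,14
50,7,17
50,8,19
50,9,17
50,10,7
50,11,2
50,12,4
50,13,2
50,17,1
51,4,1
51,5,9
51,6,13
51,7,21
51,8,14
51,9,19
51,10,9
51,11,8
51,13,2
52,4,2
52,5,5
52,6,12
52,7,13
52,8,13
52,9,14
52,10,8
52,11,7
52,12,4
52,13,1
53,5,4
53,6,11
53,7,17
53,8,15
53,9,14
53,10,6
53,11,4
53,12,4
54,4,1
54,5,4
54,6,14
54,7,18
54,8,14
54,9,4
54,10,13
54,11,3
54,12,3
54,14,2
55,4,1
55,5,5
55,6,12
55,7,14
55,8,13
55,9,13
55,10,7
55,11,7
55,12,4
55,14,1
55,15,1
56,5,8
56,6,10
56,7,10
56,8,25
56,9,13
56,10,7
56,11,3
56,12,7
56,14,1
57,5,2
57,6,5
57,7,12
57,8,7
57,9,10
57,10,9
57,11,7
57,12,1
57,14,1
58,4,1
58,5,3
58,6,8
58,7,14
58,8,11
58,9,17
58,10,10
58,11,12
58,12,5
58,13,3
58,14,1
58,16,1
59,4,1
59,5,6
59,6,4
59,7,8
59,8,16
59,9,8
59,10,11
59,11,7
59,12,3
59,13,4
59,14,4
59,16,1
60,5,2
60,6,4
60,7,15
60,8,14
60,9,11
60,10,8
60,11,4
60,12,6
60,13,2
60,14,1
60,15,1
60,16,2
61,5,5
61,6,7
61,7,8
61,8,11
61,9,14
61,10,8
61,11,8
61,12,6
61,13,3
62,5,1
62,6,3
62,7,6
62,8,18
62,9,13
62,10,7
62,11,8
62,12,7
62,13,4
62,16,1
63,5,6
63,6,5
63,7,11
63,8,17
63,9,8
63,10,6
63,11,6
63,12,3
63,13,1
63,14,4
63,15,1
64,5,2
64,6,9
64,7,7
64,8,8
64,9,8
64,10,10
64,11,7
64,12,5
64,13,2
64,17,1
65,6,2
65,7,3
65,8,14
65,9,11
65,10,11
65,11,7
65,12,5
65,13,4
65,14,1
65,15,1
66,4,1
66,5,1
66,6,1
66,7,3
66,8,12
66,9,12
66,10,10
66,11,9
66,12,4
66,13,7
66,14,2
66,19,1
67,5,2
67,6,9
67,7,6
67,8,6
67,9,11
67,10,9
67,11,5
67,12,8
67,14,1
68,5,4
68,6,4
68,7,6
68,8,10
68,9,12
68,10,4
68,11,3
68,12,3
68,13,5
68,14,1
68,15,1
69,5,2
69,6,5
69,7,8
69,8,13
69,9,8
69,10,12
69,11,8
69,12,9
69,13,3
69,14,1
69,15,1
69,17,1
70,5,1
70,6,3
70,7,3
70,8,3
70,9,12
70,10,11
70,11,4
70,12,5
70,13,4
70,14,1
70,15,1
71,5,1
71,6,2
71,7,4
71,8,5
71,9,8
71,10,13
71,11,6
71,12,5
71,13,3
71,14,4
72,6,3
72,7,9
72,8,6
72,9,9
72,10,5
72,11,10
72,13,5
72,14,2
72,15,1
72,16,1
73,5,1
73,6,3
73,7,4
73,8,6
73,9,7
73,10,10
73,11,7
73,12,11
73,13,2
73,14,1
73,16,1
73,17,2
73,18,1
74,7,5
74,8,7
74,9,8
74,10,8
74,11,2
74,12,9
74,14,3
74,16,1
75,5,1
75,6,4
75,7,2
75,8,7
75,9,8
75,10,8
75,11,7
75,12,1
75,13,5
75,14,4
75,15,3
75,16,1
76,6,1
76,7,3
76,8,5
76,9,6
76,10,4
76,11,4
76,12,7
76,13,3
76,14,3
76,15,3
76,18,1
77,5,1
77,6,1
77,7,11
77,8,5
77,9,8
77,10,9
77,11,11
77,12,3
77,13,7
77,14,4
77,15,1
77,17,1
77,18,1
78,5,1
78,7,2
78,8,7
78,9,10
78,10,12
78,11,6
78,12,5
78,13,3
78,14,3
78,15,3
78,16,1
78,17,1
78,18,1
79,6,1
79,7,2
79,8,6
79,9,11
79,10,11
79,11,5
79,12,3
79,13,6
79,15,3
80,7,5
80,8,4
80,9,6
80,10,5
80,11,6
80,12,6
80,13,4
80,14,1
80,15,2
80,16,1
80,17,1
81,6,2
81,7,3
81,8,8
81,9,8
81,10,9
81,11,6
81,12,5
81,13,3
81,14,7
81,15,1
81,16,1
81,17,1
82,6,1
82,8,4
82,9,7
82,10,7
82,11,6
82,12,6
82,13,1
82,14,3
82,15,2
82,16,1
82,17,1
83,6,3
83,7,2
83,8,4
83,9,5
83,10,10
83,11,7
83,12,5
83,13,3
83,14,1
83,15,1
84,7,3
84,8,3
84,9,6
84,10,10
84,11,9
84,12,7
84,13,5
84,14,2
84,15,2
84,18,1
84,19,1
85,6,2
85,7,4
85,8,4
85,9,5
85,10,4
85,11,3
85,12,6
85,13,6
85,14,1
85,15,1
86,6,1
86,7,2
86,8,5
86,9,4
86,10,7
86,11,7
86,12,5
86,13,3
86,14,5
86,15,2
86,16,1
86,17,2
87,6,1
87,7,2
87,8,4
87,9,2
87,10,9
87,11,8
87,12,4
87,13,4
87,14,2
87,15,3
88,7,3
88,8,7
88,9,8
88,10,7
88,11,4
88,12,1
88,13,10
88,14,1
88,16,1
88,17,3
89,6,1
89,8,3
89,9,5
89,10,4
89,11,5
89,12,2
89,13,3
89,14,1
89,15,3
89,17,1
90,9,4
90,10,3
90,11,1
90,12,2
90,13,3
90,14,3
90,15,1
90,17,1
90,18,1
90,21,1
91,6,1
91,7,1
91,8,1
91,9,3
91,10,8
91,11,5
91,12,8
91,13,4
91,14,3
91,15,3
91,16,1
92,7,1
92,8,3
92,9,9
92,10,7
92,11,5
92,13,4
92,14,2
92,16,2
92,17,2
92,18,1
93,8,2
93,9,5
93,10,5
93,11,7
93,12,1
93,13,5
93,14,2
93,15,1
93,18,1
94,6,1
94,8,2
94,9,3
94,10,6
94,11,7
94,12,2
94,14,2
94,15,5
94,16,2
94,18,1
94,21,1
95,7,1
95,8,3
95,9,2
95,10,4
95,11,3
95,12,10
95,13,6
95,14,2
95,15,1
95,16,2
95,17,1
95,18,1
96,7,3
96,8,3
96,9,8
96,10,4
96,11,5
96,12,3
96,13,1
96,14,6
96,15,1
96,16,1
97,8,3
97,9,3
97,10,8
97,11,6
97,12,4
97,13,4
97,14,4
97,15,2
97,16,3
97,17,1
97,19,1
98,7,1
98,8,1
98,9,2
98,10,2
98,11,7
98,12,2
98,13,4
98,14,4
98,16,1
98,17,1
98,18,1
99,7,2
99,8,1
99,9,1
99,10,6
99,11,6
99,12,8
99,13,5
99,14,3
99,15,2
99,18,2
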