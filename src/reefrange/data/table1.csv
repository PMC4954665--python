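# Transcription of the published per-fish monitoring summary table (in-paper data).
# fate: ok | disappeared | dead; disappeared fish vanished within the first 15
# monitoring days or departed after translocation; dead fish were flagged by the
# single-receiver constant-depth audit. Empty analysis cells for non-ok fish.
fish_id,length_cm,capture_location,capture_date,n_receptions,dd,tp,depth_min_m,depth_max_m,ri_nt,ri_pr,ri_nr,ca50_km2,hr95_km2,translocated,fate
13,22,TAS,2007-05-23,21767,353,361,0.7,8.6,0.98,0,0,0.08,0.41,0,ok
14,32,TAS,2007-05-23,93053,363,364,3.2,12.9,1,0,0,0.16,0.67,0,ok
16,21,TAS,2007-05-23,9605,193,200,0.2,10.4,0.96,0,0,0.08,0.40,0,ok
17,29,TAS,2007-05-24,28459,353,363,4.0,13.0,0.97,0,0,0.14,0.61,0,ok
19,26,TAS,2007-05-24,48800,357,364,0,15.0,0.98,0,0,0.16,0.67,0,ok
20,33,TAS,2007-05-24,13348,329,356,1.6,17.3,0.92,0,0,0.18,0.76,0,ok
22,26,TAS,2007-05-24,16582,197,199,0,9.1,0.99,0,0,0.19,0.86,0,ok
48,23,TAS,2007-05-24,30983,344,364,0.2,10.1,0.95,0,0,0.18,0.74,0,ok
49,23,TAS,2007-05-24,14388,201,212,0,4.0,0.95,0,0,0.18,0.83,0,ok
21,21,TAS,2007-05-24,850,13,13,,,,,,,,0,disappeared
51,28,TAS,2007-05-24,1835,13,13,,,,,,,,0,disappeared
15,29,POR,2007-05-25,56314,363,364,0.4,9.5,1,0,0,0.14,0.81,0,ok
23,30,POR,2007-05-25,10423,229,239,0,14.2,0.96,0,0,0.08,0.46,0,ok
24,24,POR,2007-05-25,50621,364,366,0.1,9.3,0.99,0,0,0.10,0.57,0,ok
25,26,POR,2007-05-25,46071,361,369,0.4,6.6,0.98,0,0,0.24,1.01,0,ok
26,29,POR,2007-05-25,61909,364,366,0.2,13.6,0.99,0,0,0.11,0.68,0,ok
28,33,POR,2007-05-25,19962,342,356,0.4,6.4,0.96,0,0,0.11,0.51,0,ok
29,32,POR,2007-05-29,23692,356,360,0,7.3,0.99,0,0,0.18,0.74,0,ok
30,26,POR,2007-05-29,32047,356,361,0.3,9.4,0.99,0,0,0.12,0.73,0,ok
31,29,POR,2007-05-29,22679,343,357,0.7,9.9,0.96,0,0,0.25,1.01,0,ok
54,29,ARQ,2008-09-25,3772,45,45,0,14.6,0,1,0,0.05,0.22,0,ok
55,26,ARQ,2008-09-25,2020,47,48,0,5.5,0,0.98,0,0.06,0.27,0,ok
56,35,ARQ,2008-09-25,9859,211,237,0,5.1,0,0.89,0,0.05,0.24,0,ok
57,29,ARQ,2008-09-25,12768,230,235,0.4,9.8,0,0.97,0.04,0.05,0.26,0,ok
58,35,ARQ,2008-09-25,8595,202,235,0.4,15.0,0,0.86,0.02,0.06,0.30,0,ok
74,29,ARQ,2008-09-25,14961,220,228,0,7.3,0,0.96,0.04,0.06,0.28,0,ok
99,29,ARQ,2008-10-17,9003,165,213,0,8.2,0,0.76,0.04,0.06,0.32,0,ok
94,26,ARQ,2008-10-16,7972,165,216,0.4,11.7,0,0.76,0,0.09,0.35,1,ok
96,23,ARQ,2008-10-17,5521,196,215,0.4,9.3,0.03,0.85,0.07,0.06,0.32,1,ok
52,32,ARQ,2008-09-26,10197,31,31,,,,,,,,1,dead
53,28,ARQ,2008-09-26,297,7,7,,,,,,,,1,disappeared
59,25,ARQ,2008-09-26,74,2,2,,,,,,,,1,disappeared
95,23,ARQ,2008-10-17,48957,256,280,,,,,,,,1,dead
97,26,ARQ,2008-10-17,42,2,2,,,,,,,,1,disappeared
40,23,FAL,2008-09-24,14054,244,293,0.6,11.4,0,0.00,0.83,0.05,0.20,0,ok
60,32,FAL,2008-10-21,16194,267,276,0,9.6,0,0.00,0.97,0.04,0.18,0,ok
61,21,FAL,2008-10-21,9938,211,219,0,8.9,0,0.00,0.96,0.04,0.17,0,ok
72,21,FAL,2008-09-24,20098,295,303,0.6,10.6,0,0.00,0.97,0.05,0.21,0,ok
75,24,FAL,2008-09-24,14720,278,301,0.7,14.9,0.01,0.01,0.92,0.06,0.24,0,ok
76,23,FAL,2008-09-24,4013,93,94,1.3,12.8,0,0.00,0.99,0.04,0.16,0,ok
98,35,FAL,2008-09-26,77,3,4,,,,,,,,0,disappeared
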