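age_group,strategy,qalys,cost_thousand,inc_qaly_vs_ns,inc_cost_vs_ns_thousand,icer_vs_ns,inc_qaly_vs_next,inc_cost_vs_next_thousand,icer_vs_next
40-44,no_screening,2064861,105827,,,,,,
40-44,once,2066380,118197,1519,12370,8144,1519,12370,8144
40-44,every_10y,2068402,157206,3541,51379,14509,2022,39009,19289
40-44,every_5y,2070731,195957,5870,90129,15354,2329,38751,16640
40-44,every_3y,2073634,247221,8773,141394,16118,2903,51264,17661
40-44,every_2y,2077090,324338,12229,218510,17868,3457,77117,22310
40-44,annual,2084817,528415,19955,422588,21177,7726,204077,26414
45-49,no_screening,1898860,102463,,,,,,
45-49,once,1900407,114991,1546,12529,8102,1546,12529,8102
45-49,every_10y,1901953,140916,3093,38453,12433,1547,25925,16762
45-49,every_5y,1904293,179431,5432,76968,14169,2339,38515,16465
45-49,every_3y,1907096,230810,8236,128348,15584,2804,51380,18327
45-49,every_2y,1909915,281726,11055,179264,16216,2819,50916,18062
45-49,annual,1917203,459372,18342,356910,19459,7287,177646,24377
50-54,no_screening,1708991,98999,,,,,,
50-54,once,1710812,111232,1821,12233,6718,1821,12233,6718
50-54,every_10y,1712179,137158,3188,38160,11970,1367,25927,18966
50-54,every_5y,1713993,162712,5002,63713,12736,1815,25553,14083
50-54,every_3y,1716414,200786,7423,101787,13713,2420,38074,15730
50-54,every_2y,1719086,251841,10096,152842,15140,2673,51055,19103
50-54,annual,1725353,390775,16362,291776,17832,6267,138934,22171
55-59,no_screening,1499103,91176,,,,,,
55-59,once,1500874,103523,1771,12347,6971,1771,12347,6971
55-59,every_10y,1501662,116451,2559,25276,9877,788,12929,16409
55-59,every_5y,1503318,141995,4216,50819,12055,1657,25544,15418
55-59,every_3y,1505139,167151,6036,75976,12587,1820,25156,13820
55-59,every_2y,1507270,205461,8168,114285,13993,2132,38310,17972
55-59,annual,1512601,318771,13498,227595,16861,5331,113310,21255
60-64,no_screening,1266933,79556,,,,,,
60-64,once,1268627,91684,1695,12127,7156,1695,12127,7156
60-64,every_10y,1269229,104764,2296,25208,10980,601,13080,21758
60-64,every_5y,1270199,117450,3267,37894,11600,971,12686,13067
60-64,every_3y,1271715,143100,4782,63544,13289,1515,25650,16928
60-64,every_2y,1273272,168229,6339,88673,13989,1557,25129,16140
60-64,annual,1277088,243514,10156,163957,16145,3817,75285,19725
65-69,no_screening,1010441,67551,,,,,,
65-69,once,1011915,80082,1474,12531,8501,1474,12531,8501
65-69,every_5y,1012697,92989,2256,25438,11277,782,12907,16512
65-69,every_3y,1013614,105454,3173,37904,11947,917,12465,13593
65-69,every_2y,1014320,118598,3879,51047,13160,706,13143,18615
65-69,annual,1016997,169045,6555,101495,15483,2677,50448,18848
70-74,no_screening,727150,50040,,,,,,
70-74,once,728356,62789,1206,12749,10574,1206,12749,10574
70-74,every_2y,728990,76242,1839,26202,14244,634,13453,21229
70-74,annual,729747,89150,2597,39110,15059,758,12908,17035
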