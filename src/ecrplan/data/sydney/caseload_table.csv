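model_id,hubs,RPA_melbourne,RPA_adelaide,LPH_melbourne,LPH_adelaide,WH_melbourne,WH_adelaide,POW_melbourne,POW_adelaide,RNS_melbourne,RNS_adelaide,total_suburbs,total_patients_melbourne,total_patients_adelaide
3 hospitals-1,RPA;LPH;WH,3439,2013,2559,1487,2561,1498,0,0,0,0,173,8559,4997
3 hospitals-2,RPA;LPH;POW,2425,1415,3105,1808,0,0,1588,933,0,0,153,7118,4156
3 hospitals-3,RPA;LPH;RNS,1759,1043,3148,1833,0,0,0,0,4073,2352,184,8979,5227
3 hospitals-4,RPA;WH;POW,2089,1216,0,0,3581,2088,1721,1010,0,0,150,7390,4313
3 hospitals-5,RPA;POW;RNS,1452,855,0,0,0,0,1578,921,3293,1902,137,6322,3678
3 hospitals-6,LPH;POW;RNS,0,0,3364,1957,0,0,1627,955,3991,2316,184,8982,5228
3 hospitals-7,LPH;WH;POW,0,0,2733,1587,3035,1769,2856,1678,0,0,174,8624,5034
3 hospitals-8,LPH;WH;RNS,0,0,2837,1647,2270,1332,0,0,4185,2433,187,9292,5412
3 hospitals-9,WH;POW;RNS,0,0,0,0,3254,1900,1987,1161,2851,1652,164,8092,4713
4 hospitals-1,RPA;LPH;WH;POW,1976,1151,2516,1462,2561,1498,1588,933,0,0,175,8641,5044
4 hospitals-2,RPA;LPH;WH;RNS,1544,914,2559,1487,2058,1208,0,0,3202,1847,189,9363,5456
4 hospitals-3,RPA;LPH;POW;RNS,1218,720,3105,1808,0,0,1446,844,3293,1902,186,9061,5274
4 hospitals-4,RPA;WH;POW;RNS,1116,656,0,0,3077,1798,1578,921,2422,1398,166,8193,4772
4 hospitals-5,LPH;WH;POW;RNS,0,0,3279,1899,2234,1310,1627,955,2851,1652,200,9991,5815
5 hospitals-1,RPA;LPH;WH;POW;RNS,1003,591,2516,1462,2058,1208,1446,844,2422,1398,191,9445,5503
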