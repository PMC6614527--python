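model_id,hubs,RPA_pct,RPA_suburbs,LPH_pct,LPH_suburbs,WH_pct,WH_suburbs,POW_pct,POW_suburbs,RNS_pct,RNS_suburbs,total_suburbs,total_patients_melbourne,total_patients_adelaide
3 hospitals-1,RPA;LPH;WH,76.1,109,77.6,58,76.3,59,,,,,173,8559,4997
3 hospitals-2,RPA;LPH;POW,57.8,109,71.1,76,,,87.8,41,,,153,7118,4156
3 hospitals-3,RPA;LPH;RNS,100,50,80.9,68,,,,,73.1,108,184,8979,5227
3 hospitals-4,RPA;WH;POW,68,75,,,66.3,92,64.4,59,,,150,7390,4313
3 hospitals-5,RPA;POW;RNS,75.9,54,,,,,45.3,75,63.9,97,137,6322,3678
3 hospitals-6,LPH;POW;RNS,,,83.3,72,,,90.7,43,76.6,111,184,8982,5228
3 hospitals-7,LPH;WH;POW,,,84.2,57,39.1,69,24,100,,,174,8624,5034
3 hospitals-8,LPH;WH;RNS,,,82.3,62,45.7,46,,,79.7,118,187,9292,5412
3 hospitals-9,WH;POW;RNS,,,,,71.2,80,33.8,65,77.8,81,164,8092,4713
4 hospitals-1,RPA;LPH;WH;POW,67.6,74,83,53,76.3,59,90,40,,,175,8641,5044
4 hospitals-2,RPA;LPH;WH;RNS,100,42,81.8,55,90.2,41,,,73.9,88,189,9363,5456
4 hospitals-3,RPA;LPH;POW;RNS,100,38,81.8,66,,,88.9,36,72.1,86,186,9061,5274
4 hospitals-4,RPA;WH;POW;RNS,100,31,,,71.8,74,61.1,55,72.7,66,166,8193,4772
4 hospitals-5,LPH;WH;POW;RNS,,,84.2,57,91.1,45,90.7,43,77.8,81,200,9991,5815
5 hospitals-1,RPA;LPH;WH;POW;RNS,100,30,83,53,90.2,41,88.9,36,72.7,66,191,7023,4106
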