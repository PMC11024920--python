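tag_id,novel_count,familiar_count,strength,site_id,sex,age,immigrant,prior_detections
T00,9,69,0.288,S2,M,adult,True,282
T01,40,42,2.479,S1,M,juvenile,True,340
T02,31,55,2.735,S2,M,adult,False,350
T03,47,46,1.857,S1,F,juvenile,True,296
T04,41,43,1.698,S1,F,adult,True,297
T05,16,70,1.321,S2,F,juvenile,True,303
T06,73,25,3.941,S1,F,juvenile,True,286
T07,10,74,0.937,S2,M,adult,True,262
T08,49,48,1.927,S1,F,adult,True,274
T09,33,62,1.272,S1,F,adult,False,322
T10,28,44,1.071,S1,F,adult,False,283
T11,13,67,1.505,S2,M,adult,True,331
T12,49,47,1.952,S1,F,juvenile,True,299
T13,11,76,1.018,S2,F,juvenile,False,301
T14,29,46,0.631,S1,F,adult,False,314
T15,69,19,4.55,S1,M,juvenile,False,325
T16,29,67,2.58,S2,M,juvenile,False,279
T17,51,32,3.204,S1,M,juvenile,True,268
T18,24,49,2.817,S2,M,juvenile,True,308
T19,48,46,1.625,S1,M,adult,True,290
T20,82,31,3.77,S1,M,adult,True,286
T21,26,51,0.943,S1,F,adult,False,296
T22,9,100,0.65,S2,M,adult,False,305
T23,11,66,1.415,S2,F,adult,False,286
T24,41,35,2.395,S1,M,juvenile,False,318
T25,55,35,5.034,S2,F,juvenile,True,275
T26,32,57,2.428,S2,F,adult,True,304
T27,15,70,1.174,S2,F,juvenile,False,278
T28,35,62,3.907,S2,M,juvenile,False,320
T29,71,26,4.326,S1,M,juvenile,True,323
T30,32,51,0.835,S1,F,juvenile,True,287
T31,16,65,1.157,S2,M,juvenile,False,321
T32,43,35,2.422,S1,M,adult,False,287
T33,18,53,1.856,S2,F,juvenile,True,282
T34,56,27,3.24,S1,M,adult,False,341
T35,14,62,2.032,S2,M,adult,True,324
T36,18,73,1.503,S2,M,juvenile,True,274
T37,16,63,1.321,S2,F,adult,False,280
T38,24,62,1.777,S2,F,juvenile,True,290
T39,60,39,2.651,S1,M,juvenile,True,294
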