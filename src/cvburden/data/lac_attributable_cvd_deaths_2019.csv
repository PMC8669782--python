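subregion,sex,risk_factor,age_scope,estimate,lower,upper
Andean Latin America,men,BMI,all_ages,3299,1605,5687
Andean Latin America,men,BMI,premature,2659,1494,3920
Andean Latin America,men,SBP,all_ages,13590,8107,18597
Andean Latin America,men,SBP,premature,6072,3905,7854
Andean Latin America,men,TC,all_ages,3118,562,7135
Andean Latin America,men,TC,premature,1851,473,3519
Andean Latin America,men,non-HDL,all_ages,6841,2548,11916
Andean Latin America,men,non-HDL,premature,3886,2003,5631
Andean Latin America,women,BMI,all_ages,3124,1602,5450
Andean Latin America,women,BMI,premature,2390,1474,3335
Andean Latin America,women,SBP,all_ages,11216,5757,16342
Andean Latin America,women,SBP,premature,3466,1848,4883
Andean Latin America,women,TC,all_ages,3532,622,8193
Andean Latin America,women,TC,premature,1580,495,2855
Andean Latin America,women,non-HDL,all_ages,6189,2025,11376
Andean Latin America,women,non-HDL,premature,2813,1490,4051
Caribbean,men,BMI,all_ages,6176,2832,10630
Caribbean,men,BMI,premature,5136,2651,7880
Caribbean,men,SBP,all_ages,27503,16887,36885
Caribbean,men,SBP,premature,14327,9244,18297
Caribbean,men,TC,all_ages,6178,1123,13847
Caribbean,men,TC,premature,3828,930,7373
Caribbean,men,non-HDL,all_ages,12863,5229,21835
Caribbean,men,non-HDL,premature,7824,4119,11345
Caribbean,women,BMI,all_ages,5134,2312,9475
Caribbean,women,BMI,premature,3932,2104,5920
Caribbean,women,SBP,all_ages,24135,12787,34567
Caribbean,women,SBP,premature,9617,5259,13180
Caribbean,women,TC,all_ages,7710,1593,17115
Caribbean,women,TC,premature,3697,1248,6596
Caribbean,women,non-HDL,all_ages,13125,4588,23590
Caribbean,women,non-HDL,premature,6342,3397,9102
Central Latin America,men,BMI,all_ages,21147,11158,34447
Central Latin America,men,BMI,premature,17209,10396,24328
Central Latin America,men,SBP,all_ages,81481,53892,107084
Central Latin America,men,SBP,premature,40272,28791,49875
Central Latin America,men,TC,all_ages,16548,3844,35438
Central Latin America,men,TC,premature,10278,3269,18462
Central Latin America,men,non-HDL,all_ages,39095,15439,65842
Central Latin America,men,non-HDL,premature,22925,12156,32755
Central Latin America,women,BMI,all_ages,16734,8649,28854
Central Latin America,women,BMI,premature,12342,7816,16888
Central Latin America,women,SBP,all_ages,67962,40603,93829
Central Latin America,women,SBP,premature,21806,14077,28469
Central Latin America,women,TC,all_ages,20079,4416,43640
Central Latin America,women,TC,premature,8553,3340,14340
Central Latin America,women,non-HDL,all_ages,35646,11593,64701
Central Latin America,women,non-HDL,premature,15098,8294,21297
Southern and Tropical Latin America,men,BMI,all_ages,36418,19372,58019
Southern and Tropical Latin America,men,BMI,premature,29324,17847,41325
Southern and Tropical Latin America,men,SBP,all_ages,155845,121477,187436
Southern and Tropical Latin America,men,SBP,premature,83297,69701,94929
Southern and Tropical Latin America,men,TC,all_ages,30617,9504,58140
Southern and Tropical Latin America,men,TC,premature,19949,7806,33399
Southern and Tropical Latin America,men,non-HDL,all_ages,61208,25953,99449
Southern and Tropical Latin America,men,non-HDL,premature,38343,20426,54830
Southern and Tropical Latin America,women,BMI,all_ages,27466,13672,48261
Southern and Tropical Latin America,women,BMI,premature,19765,12201,27444
Southern and Tropical Latin America,women,SBP,all_ages,121181,81127,158501
Southern and Tropical Latin America,women,SBP,premature,41732,31403,50817
Southern and Tropical Latin America,women,TC,all_ages,32048,7881,66512
Southern and Tropical Latin America,women,TC,premature,14050,5875,22882
Southern and Tropical Latin America,women,non-HDL,all_ages,49151,16381,89467
Southern and Tropical Latin America,women,non-HDL,premature,22272,11925,31983
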