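drug,year,sector,mg_volume,reimbursement_value,patients,currency
INF,2013,ALL,958714,4604000,623,EUR
INF,2014,ALL,1422089,4640000,923,EUR
INF,2015,ALL,1519884,4337000,986,EUR
INF,2016,ALL,1833163,4758000,1393,EUR
INF,2017,ALL,2976943,7553000,1802,EUR
INF,2018,ALL,4006739,9261000,2352,EUR
INF,2019,ALL,4224074,6109000,2393,EUR
INF,2020,ALL,3805104,3260000,2224,EUR
INF,2021,ALL,4291792,2827000,2438,EUR
ETN,2013,ALL,,19418000,2727,EUR
ETN,2014,ALL,,19204000,2664,EUR
ETN,2015,ALL,4296845,18455000,2608,EUR
ETN,2016,ALL,4379420,17098000,2600,EUR
ETN,2017,ALL,4388646,13503000,2655,EUR
ETN,2018,ALL,4818826,10401000,2851,EUR
ETN,2019,ALL,5693550,8635000,3292,EUR
ETN,2020,ALL,5697756,7018000,3250,EUR
ETN,2021,ALL,6621702,7094000,3553,EUR
ADA,2013,ALL,,17946000,2375,EUR
ADA,2014,ALL,,21913000,2940,EUR
ADA,2015,ALL,,26144000,3514,EUR
ADA,2016,ALL,,25081000,3966,EUR
ADA,2017,ALL,,27074000,4462,EUR
ADA,2018,ALL,3304828,31080000,5056,EUR
ADA,2019,ALL,4003127,11457000,5706,EUR
ADA,2020,ALL,4000053,5951000,5837,EUR
ADA,2021,ALL,4818737,4953000,6636,EUR
INF,2013,RMD,164442,790000,106,EUR
INF,2014,RMD,243922,796000,157,EUR
INF,2015,RMD,260696,744000,168,EUR
INF,2016,RMD,352851,916000,313,EUR
INF,2017,RMD,573008,1454000,365,EUR
INF,2018,RMD,645025,1491000,419,EUR
INF,2019,RMD,682132,986000,398,EUR
INF,2020,RMD,633945,543000,332,EUR
INF,2021,RMD,641623,423000,322,EUR
ETN,2013,RMD,,19371000,2717,EUR
ETN,2014,RMD,,19157000,2654,EUR
ETN,2015,RMD,4296845,18411000,2598,EUR
ETN,2016,RMD,4378296,17052000,2587,EUR
ETN,2017,RMD,4387632,13467000,2655,EUR
ETN,2018,RMD,4819160,10377000,2851,EUR
ETN,2019,RMD,5694586,8617000,3292,EUR
ETN,2020,RMD,5670781,6969000,3250,EUR
ETN,2021,RMD,6551574,7002000,3553,EUR
ADA,2013,RMD,,14733000,1914,EUR
ADA,2014,RMD,,17989000,2369,EUR
ADA,2015,RMD,,21463000,2832,EUR
ADA,2016,RMD,,20529000,3124,EUR
ADA,2017,RMD,,22161000,3570,EUR
ADA,2018,RMD,2709788,25484000,4097,EUR
ADA,2019,RMD,3320309,9503000,4699,EUR
ADA,2020,RMD,3355660,4993000,4937,EUR
ADA,2021,RMD,4167892,4284000,5673,EUR
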