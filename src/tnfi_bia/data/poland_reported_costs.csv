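drug,year,cost_per_mg,cost_per_patient
INF,2013,4.80,7390
INF,2014,3.26,5027
INF,2015,2.85,4399
INF,2016,2.59,3416
INF,2017,2.54,4191
INF,2018,2.31,3937
INF,2019,1.45,2553
INF,2020,0.86,1466
INF,2021,0.66,1159
ETN,2013,4.32,7121
ETN,2014,4.38,7208
ETN,2015,4.29,7076
ETN,2016,3.90,6576
ETN,2017,3.07,5063
ETN,2018,2.16,3636
ETN,2019,1.52,2611
ETN,2020,1.23,2143
ETN,2021,1.08,1963
ADA,2013,11.87,7556
ADA,2014,11.70,7453
ADA,2015,11.68,7440
ADA,2016,9.79,6324
ADA,2017,9.42,6068
ADA,2018,9.40,6147
ADA,2019,2.86,2008
ADA,2020,1.49,1021
ADA,2021,1.03,746
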