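energy_keV	S_keV_per_um
0.1	19.2098
0.104231	20.1619
0.108641	21.0051
0.113237	21.7467
0.118028	22.3935
0.123021	22.9521
0.128226	23.4284
0.133651	23.8283
0.139305	24.1572
0.145199	24.4202
0.151342	24.6221
0.157745	24.7674
0.164419	24.8604
0.171375	24.905
0.178625	24.9052
0.186183	24.8644
0.19406	24.7858
0.20227	24.6728
0.210827	24.5282
0.219747	24.3547
0.229044	24.1549
0.238734	23.9313
0.248835	23.6861
0.259362	23.4214
0.270335	23.1393
0.281772	22.8415
0.293694	22.5298
0.306119	22.2059
0.31907	21.8712
0.332569	21.5272
0.34664	21.1751
0.361305	20.8162
0.376591	20.4517
0.392524	20.0825
0.409131	19.7096
0.42644	19.334
0.444482	18.9565
0.463287	18.5778
0.482887	18.1987
0.503317	17.8199
0.524611	17.4419
0.546806	17.0653
0.569941	16.6907
0.594053	16.3184
0.619186	15.9489
0.645383	15.5826
0.672687	15.2198
0.701147	14.8609
0.730811	14.5061
0.76173	14.1558
0.793957	13.81
0.827548	13.4691
0.862559	13.1332
0.899052	12.8025
0.937089	12.477
0.976735	12.157
1.01806	11.8425
1.06113	11.5336
1.10602	11.2303
1.15282	10.9327
1.20159	10.6409
1.25243	10.3549
1.30541	10.0746
1.36064	9.80017
1.41821	9.53148
1.47821	9.26855
1.54075	9.01137
1.60594	8.75988
1.67388	8.51407
1.7447	8.27388
1.81851	8.03926
1.89545	7.81016
1.97564	7.58652
2.05922	7.36827
2.14635	7.15534
2.23715	6.94766
2.3318	6.74516
2.43045	6.54776
2.53328	6.35538
2.64046	6.16794
2.75217	5.98536
2.86861	5.80754
2.98997	5.63442
3.11647	5.46589
3.24832	5.30187
3.38575	5.14228
3.52899	4.98703
3.6783	4.83602
3.83392	4.68917
3.99612	4.5464
4.16519	4.40761
4.34141	4.27271
4.52508	4.14163
4.71653	4.01427
4.91607	3.89055
5.12406	3.77038
5.34085	3.65368
5.56681	3.54037
5.80233	3.43037
6.04781	3.32359
6.30368	3.21996
6.57037	3.11939
6.84835	3.02181
7.13809	2.92715
7.44009	2.83532
7.75486	2.74626
8.08295	2.6599
8.42492	2.57615
8.78136	2.49496
9.15288	2.41625
9.54011	2.33996
9.94373	2.26602
10.3644	2.19437
10.8029	2.12494
11.26	2.05767
11.7364	1.99251
12.2329	1.92939
12.7504	1.86826
13.2899	1.80906
13.8521	1.75173
14.4382	1.69623
15.049	1.64249
15.6857	1.59047
16.3494	1.54012
17.0411	1.49139
17.762	1.44423
18.5135	1.3986
19.2968	1.35445
20.1132	1.31173
20.9641	1.27041
21.8511	1.23044
22.7755	1.19178
23.7391	1.15439
24.7434	1.11824
25.7903	1.08329
26.8814	1.04949
28.0187	1.01682
29.2041	0.985236
30.4397	0.954711
31.7275	0.92521
33.0698	0.896701
34.4689	0.869154
35.9272	0.84254
37.4472	0.816828
39.0315	0.79199
40.6829	0.768
42.4041	0.744831
44.1981	0.722457
46.068	0.700853
48.017	0.679995
50.0485	0.659859
52.166	0.640422
54.373	0.621663
56.6734	0.603559
59.0711	0.58609
61.5703	0.569236
64.1751	0.552977
66.8902	0.537293
69.7202	0.522168
72.6699	0.507582
75.7444	0.493519
78.949	0.479962
82.2891	0.466894
85.7706	0.4543
89.3994	0.442165
93.1816	0.430474
97.1239	0.419212
101.233	0.408367
105.516	0.397923
109.98	0.38787
114.633	0.378194
119.483	0.368882
124.538	0.359924
129.807	0.351308
135.299	0.343023
141.023	0.335058
146.989	0.327403
153.208	0.320049
159.69	0.312985
166.446	0.306202
173.488	0.299692
180.828	0.293445
188.478	0.287454
196.452	0.28171
204.764	0.276205
213.427	0.270933
222.457	0.265884
231.868	0.261053
241.678	0.256432
251.903	0.252015
262.56	0.247796
273.668	0.243768
285.247	0.239925
297.315	0.236261
309.894	0.232771
323.005	0.229449
336.67	0.226291
350.914	0.22329
365.76	0.220442
381.235	0.217743
397.364	0.215187
414.175	0.21277
431.698	0.210487
449.962	0.208335
468.999	0.206309
488.841	0.204405
509.523	0.202619
531.08	0.200948
553.549	0.199388
576.968	0.197935
601.378	0.196586
626.821	0.195337
653.34	0.194185
680.982	0.193127
709.793	0.192159
739.822	0.191279
771.122	0.190484
803.747	0.189771
837.752	0.189136
873.195	0.188577
910.138	0.188092
948.644	0.187678
988.778	0.187331
1030.61	0.187051
1074.21	0.186833
1119.66	0.186677
1167.03	0.186579
1216.41	0.186537
1267.87	0.186549
1321.51	0.186613
1377.42	0.186727
1435.7	0.186889
1496.44	0.187096
1559.75	0.187347
1625.74	0.187641
1694.52	0.187974
1766.21	0.188346
1840.93	0.188755
1918.82	0.189198
2000	0.189675
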