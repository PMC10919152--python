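age,sex,qx
20,male,0.0002899579540645014
21,male,0.000317895258994505
22,male,0.0003485238401490509
23,male,0.0003821028606685317
24,male,0.00041891642130531537
25,male,0.0004592759561429238
26,male,0.0005035228576854012
27,male,0.0005520313531206522
28,male,0.0006052116555999021
29,male,0.0006635134165997592
30,male,0.0007274295078597559
31,male,0.0007975001640255774
32,male,0.0008743175200053299
33,male,0.0009585305801669275
34,male,0.001050850659904734
35,male,0.001152057343786983
36,male,0.0012630050084923017
37,male,0.0013846299630767556
38,male,0.0015179582637926403
39,male,0.0016641142657398689
40,male,0.001824329979088768
41,male,0.0019999553034780737
42,male,0.0021924692205035345
43,male,0.002403492030963794
44,male,0.0026347987307480114
45,male,0.002888333626939854
46,male,0.0031662263038637617
47,male,0.0034708090574208095
48,male,0.0038046359251182604
49,male,0.004170503448665208
50,male,0.004571473315826302
51,male,0.005010897038331352
52,male,0.005492442832916611
53,male,0.006020124882896494
54,male,0.006598335167844138
55,male,0.007231878058769126
56,male,0.007926007885322495
57,male,0.00868646968965825
58,male,0.009519543388180396
59,male,0.010432091566918822
60,male,0.011431611138005504
61,male,0.012526289082793407
62,male,0.013725062500521412
63,male,0.015037683168798943
64,male,0.016474786802031183
65,male,0.01804796716438073
66,male,0.01976985515276153
67,male,0.02165420291008635
68,male,0.023715972956437348
69,male,0.025971432232384184
70,male,0.02843825083010476
71,male,0.03113560503933621
72,male,0.034084284150849964
73,male,0.037306800233605886
74,male,0.04082749982565703
75,male,0.044672676145012025
76,male,0.04887068002589612
77,male,0.05345202730826071
78,male,0.058449499843374775
79,male,0.06389823661487726
80,male,0.06983581070175315
81,male,0.07630228691688423
82,male,0.08334025393312927
83,male,0.09099482355197241
84,male,0.09931358847555805
85,male,0.10834652851573845
86,male,0.11814585362708296
87,male,0.12876577051084492
88,male,0.14026215784693274
89,male,0.15269213353668742
20,female,0.0001699855508188186
21,female,0.00018673771914712312
22,female,0.0002051406533875033
23,female,0.0002253569856965898
24,female,0.0002475653633778885
25,female,0.0002719620244691079
26,female,0.0002987625280277406
27,female,0.0003282036542390232
28,female,0.00036054549093733623
29,female,0.0003960737247343804
30,female,0.0004351021567067237
31,female,0.0004779754645154455
32,female,0.0005250722349338099
33,female,0.0005768082930563967
34,female,0.0006336403569761062
35,female,0.0006960700494580419
36,female,0.0007646483011329863
37,female,0.0008399801829992448
38,female,0.0009227302095828893
39,female,0.0010136281579797846
40,female,0.0011134754522239554
41,female,0.0012231521670084122
42,female,0.0013436247097620146
43,female,0.0014759542454809704
44,female,0.0016213059345554504
45,female,0.001780959060140419
46,female,0.0019563181284358855
47,female,0.0021489250325639198
48,female,0.0023604723786055937
49,female,0.0025928180807880397
50,female,0.002848001341804962
51,female,0.0031282601438230584
52,female,0.0034360503858548164
53,female,0.0037740668138457334
54,female,0.004145265900999617
55,female,0.00455289084747712
56,female,0.005000498880569748
57,female,0.0054919910486483925
58,female,0.0060316447144410645
59,female,0.006624148965298948
60,female,0.007274643169767336
61,female,0.007988758920629335
62,female,0.008772665614174557
63,female,0.0096331199231795
64,female,0.010577519426251514
65,female,0.01161396065789555
66,female,0.012751301840813745
67,female,0.01399923055320973
68,female,0.015368336567615493
69,female,0.016870190072031832
70,female,0.018517425446605174
71,female,0.020323830716840963
72,female,0.022304442734109364
73,female,0.024475648041952902
74,female,0.02685528926777847
75,female,0.029462776728415907
76,female,0.03231920474839145
77,female,0.03544747195423281
78,female,0.03887240451830076
79,female,0.04262088097200778
80,female,0.046721956780192975
81,female,0.05120698635415166
82,female,0.05610973956766341
83,female,0.061466509114909695
84,female,0.06731620419770101
85,female,0.07370042503853058
86,female,0.08066351157351925
87,female,0.08825255837574775
88,female,0.09651738638968499
89,female,0.10551046042317314
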