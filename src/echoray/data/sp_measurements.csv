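subject,group,analyte,value
1,control,SP-D,8.558468
1,copd,SP-D,28.2358871
1,control,SP-A,10.66308
1,copd,SP-A,18.30645
2,control,SP-D,9.707661
2,copd,SP-D,17.71169355
2,control,SP-A,10.40323
2,copd,SP-A,13.41398
3,control,SP-D,21.13911
3,copd,SP-D,69.81854839
3,control,SP-A,10.98566
3,copd,SP-A,66.33513
4,control,SP-D,10.53427
4,copd,SP-D,27.0766129
4,control,SP-A,23.98746
4,copd,SP-A,27.05197
5,control,SP-D,22.06653
5,copd,SP-D,13.61895161
5,control,SP-A,12.06989
5,copd,SP-A,11.36201
6,control,SP-D,11.07863
6,copd,SP-D,9.606854839
6,control,SP-A,17.22222
6,copd,SP-A,15.34213
7,control,SP-D,11.5625
7,copd,SP-D,18.40501792
7,control,SP-A,15.83984
7,copd,SP-A,12.36328
8,control,SP-D,8.183594
8,copd,SP-D,38.58359375
8,control,SP-A,1.601563
8,copd,SP-A,38.28125
9,control,SP-D,0.214844
9,copd,SP-D,35.3125
9,control,SP-A,1.699219
9,copd,SP-A,5.46875
10,control,SP-D,0.234375
10,copd,SP-D,5.2734375
10,control,SP-A,14.16016
10,copd,SP-A,49.02344
11,control,SP-D,11.44531
11,copd,SP-D,51.953125
11,control,SP-A,11.30859
11,copd,SP-A,11.89453
12,control,SP-D,6.425781
12,copd,SP-D,31.651135
12,control,SP-A,7.673081
12,copd,SP-A,17.10645
13,control,SP-D,9.156457
13,copd,SP-D,38.13558708
13,control,SP-A,9.433126
13,copd,SP-A,19.91498
14,control,SP-D,6.502361
14,copd,SP-D,47.51169335
14,control,SP-A,5.915761
14,copd,SP-A,69.13523
15,control,SP-D,19.23321
15,copd,SP-D,61.41154829
15,control,SP-A,21.38143
15,copd,SP-A,37.15297
16,control,SP-D,11.33124
16,copd,SP-D,29.9761129
16,control,SP-A,12.31589
16,copd,SP-A,31.16211
17,control,SP-D,20.07523
17,copd,SP-D,18.61716161
17,control,SP-A,16.66722
17,copd,SP-A,14.14216
18,control,SP-D,13.17813
18,copd,SP-D,29.00685484
18,control,SP-A,14.77684
18,copd,SP-A,32.16358
19,control,SP-D,8.0645
19,copd,SP-D,38.55050179
19,control,SP-A,5.510567
19,copd,SP-A,42.18127
20,control,SP-D,12.18309
20,copd,SP-D,28.48369315
20,control,SP-A,7.641219
20,copd,SP-A,35.56814
21,control,SP-D,1.212254
21,copd,SP-D,55.1167
21,control,SP-A,10.24116
21,copd,SP-A,59.42544
22,control,SP-D,3.274585
22,copd,SP-D,35.2754771
22,control,SP-A,6.104774
22,copd,SP-A,41.69353
23,control,SP-D,14.43545
23,copd,SP-D,59.157179
23,control,SP-A,13.31659
23,copd,SP-A,54.24117
24,control,SP-D,4.445181
24,copd,SP-D,37.154137
24,control,SP-A,6.773082
24,copd,SP-A,33.56458
25,control,SP-D,8.930212
25,copd,SP-D,29.174136
25,control,SP-A,9.149126
25,copd,SP-A,32.48224
26,control,SP-D,18.55847
26,copd,SP-D,38.5158851
26,control,SP-A,20.66308
26,copd,SP-A,48.80245
27,control,SP-D,6.717564
27,copd,SP-D,19.92364355
27,control,SP-A,9.503526
27,copd,SP-A,23.51318
28,control,SP-D,20.63613
28,copd,SP-D,65.41153839
28,control,SP-A,16.18466
28,copd,SP-A,65.12513
29,control,SP-D,20.43428
29,copd,SP-D,47.0911129
29,control,SP-A,23.18145
29,copd,SP-A,44.35127
30,control,SP-D,12.06323
30,copd,SP-D,23.11495168
30,control,SP-A,12.76181
30,copd,SP-A,31.56211
31,control,SP-D,21.02842
31,copd,SP-D,29.50285184
31,control,SP-A,17.34567
31,copd,SP-A,35.39116
32,control,SP-D,12.1635
32,copd,SP-D,28.10601795
32,control,SP-A,15.72944
32,copd,SP-A,22.34319
33,control,SP-D,8.784514
33,copd,SP-D,28.58152374
33,control,SP-A,1.204512
33,copd,SP-A,38.48027
34,control,SP-D,0.894744
34,copd,SP-D,11.51132581
34,control,SP-A,0.662238
34,copd,SP-A,15.56174
35,control,SP-D,10.14732
35,copd,SP-D,41.456112
35,control,SP-A,11.79059
35,copd,SP-A,31.09153
36,control,SP-D,0.291324
36,copd,SP-D,4.2974377
36,control,SP-A,0.169157
36,copd,SP-A,5.156138
37,control,SP-D,17.13341
37,copd,SP-D,64.41551829
37,control,SP-A,21.98242
37,copd,SP-A,67.45217
38,control,SP-D,6.925581
38,copd,SP-D,29.751336
38,control,SP-A,7.875085
38,copd,SP-A,31.00645
39,control,SP-D,4.857157
39,copd,SP-D,38.19658808
39,control,SP-A,6.135127
39,copd,SP-A,36.71597
40,control,SP-D,6.912462
40,copd,SP-D,49.42179236
40,control,SP-A,5.516562
40,copd,SP-A,55.57521
41,control,SP-D,10.03727
41,copd,SP-D,34.65609291
41,control,SP-A,13.71881
41,copd,SP-A,37.56976
42,control,SP-D,16.98298
42,copd,SP-D,28.67110678
42,control,SP-A,13.11093
42,copd,SP-A,24.5721
43,control,SP-D,9.673159
43,copd,SP-D,29.76651275
43,control,SP-A,11.90128
43,copd,SP-A,33.57092
44,control,SP-D,18.0645
44,copd,SP-D,38.75305505
44,control,SP-A,5.997651
44,copd,SP-A,43.59561
45,control,SP-D,10.45172
45,copd,SP-D,29.27614836
45,control,SP-A,8.261964
45,copd,SP-A,32.40166
46,control,SP-D,0.891537
46,copd,SP-D,15.29851164
46,control,SP-A,1.860124
46,copd,SP-A,19.73824
47,control,SP-D,2.105975
47,copd,SP-D,25.72642754
47,control,SP-A,5.27501
47,copd,SP-A,31.47027
48,control,SP-D,12.72664
48,copd,SP-D,59.772115
48,control,SP-A,13.66063
48,copd,SP-A,55.73892
49,control,SP-D,4.697945
49,copd,SP-D,38.002715
49,control,SP-A,6.308153
49,copd,SP-A,37.79076
50,control,SP-D,8.159302
50,copd,SP-D,29.708174
50,control,SP-A,9.097149
50,copd,SP-A,32.88905
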