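A_g00001	1374
A_g00002	2247
A_g00003	1847
A_g00004	1289
A_g00005	1607
A_g00006	2178
A_g00007	1939
A_g00008	1045
A_g00009	2851
A_g00010	908
A_g00011	2246
A_g00012	2842
A_g00013	1336
A_g00014	1731
A_g00015	1567
A_g00016	1139
A_g00017	1191
A_g00018	1320
A_g00019	2511
A_g00020	2347
A_g00021	1459
A_g00022	1292
A_g00023	2915
A_g00024	1883
A_g00025	2181
A_g00026	1888
A_g00027	2574
A_g00028	1876
A_g00029	2341
A_g00030	1688
A_g00031	906
A_g00032	2957
A_g00033	1776
A_g00034	1379
A_g00035	2833
A_g00036	1182
A_g00037	1122
A_g00038	1392
A_g00039	1249
A_g00040	2674
A_g00041	2720
A_g00042	1341
A_g00043	1422
A_g00044	1330
A_g00045	2541
A_g00046	2753
A_g00047	2054
A_g00048	2489
A_g00049	1048
A_g00050	1735
A_g00051	1866
A_g00052	2211
A_g00053	2162
A_g00054	1090
A_g00055	2991
A_g00056	1006
A_g00057	2847
A_g00058	2024
A_g00059	2668
A_g00060	1651
B_g00001	1651
B_g00002	2668
B_g00003	2024
B_g00004	2847
B_g00005	1006
B_g00006	2991
B_g00007	1090
B_g00008	2162
B_g00009	2211
B_g00010	1866
B_g00011	1735
B_g00012	1048
B_g00013	2489
B_g00014	2054
B_g00015	2753
B_g00016	2541
B_g00017	1330
B_g00018	1731
B_g00019	1336
B_g00020	2574
B_g00021	1876
B_g00022	2341
B_g00023	1688
B_g00024	906
B_g00025	2957
B_g00026	1776
B_g00027	1379
B_g00028	2833
B_g00029	1182
B_g00030	1122
B_g00031	1392
B_g00032	1249
B_g00033	2674
B_g00034	2720
B_g00035	1341
B_g00036	1422
B_g00037	1567
B_g00038	1139
B_g00039	1191
B_g00040	2347
B_g00041	2511
B_g00042	1320
B_g00043	1459
B_g00044	1292
B_g00045	2915
B_g00046	1883
B_g00047	2181
B_g00048	1888
B_g00049	2842
B_g00050	2246
B_g00051	908
B_g00052	2851
B_g00053	1045
B_g00054	1939
B_g00055	2178
B_g00056	1607
B_g00057	1289
B_g00058	1847
B_g00059	2247
B_g00060	1374
C_g00001	2574
C_g00002	1336
C_g00003	1731
C_g00004	1866
C_g00005	1735
C_g00006	1048
C_g00007	2489
C_g00008	2054
C_g00009	2753
C_g00010	2541
C_g00011	1330
C_g00012	1422
C_g00013	1341
C_g00014	2720
C_g00015	2674
C_g00016	1249
C_g00017	1392
C_g00018	1122
C_g00019	1182
C_g00020	2833
C_g00021	1379
C_g00022	1776
C_g00023	2957
C_g00024	906
C_g00025	2851
C_g00026	1045
C_g00027	1939
C_g00028	2178
C_g00029	2347
C_g00030	2511
C_g00031	1320
C_g00032	1191
C_g00033	1139
C_g00034	1567
C_g00035	2211
C_g00036	2162
C_g00037	1090
C_g00038	2991
C_g00039	1006
C_g00040	2847
C_g00041	2024
C_g00042	2668
C_g00043	1651
C_g00044	908
C_g00045	2246
C_g00046	2842
C_g00047	1888
C_g00048	2181
C_g00049	1883
C_g00050	2915
C_g00051	1292
C_g00052	1459
C_g00053	1607
C_g00054	1289
C_g00055	1374
C_g00056	2247
C_g00057	1847
C_g00058	1876
C_g00059	2341
C_g00060	1688
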