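id,rxy_max,m_max,rmse_acf,rmse_zc,rmse_ps,rmse_fft,rr_zc_tfm,rr_zc_rad
1,0.952,14,0.224,0.921,2.855,0.063,7.92,8.28
2,0.938,-2,0.919,0.511,1.422,0.407,12.25,12.38
3,0.958,40,0.246,0.575,1.130,0.210,4.77,4.62
4,0.975,17,1.274,0.106,1.078,0.161,10.86,10.86
5,0.979,-12,0.038,0.364,1.580,1.389,8.95,8.99
6,0.916,9,3.866,2.591,4.603,4.173,11.54,12.59
7,0.845,21,2.451,1.245,2.973,0.286,6.01,6.48
8,0.953,5,3.061,1.169,4.424,3.389,13.08,13.52
9,0.940,30,2.754,1.075,1.523,0.299,8.83,9.08
10,0.905,7,0.087,0.100,0.601,0.131,11.99,11.99
11,0.986,19,0.048,0.998,1.114,0.107,17.08,17.26
12,0.937,15,0.095,0.472,0.995,0.151,9.75,9.65
13,0.990,-6,1.570,0.043,1.994,0.640,11.02,11.03
14,0.887,12,0.059,0.083,0.058,0.141,13.35,13.38
15,0.965,8,0.983,0.232,0.230,0.123,8.38,8.45
16,0.965,7,0.052,0.160,0.114,0.100,15.27,15.25
17,0.775,31,1.035,1.026,2.497,3.423,13.81,13.50
18,0.837,18,2.774,2.114,1.332,4.000,12.88,12.53
19,0.940,0,0.760,0.853,1.418,0.903,13.25,13.36
20,0.968,14,0.116,0.139,0.111,0.123,10.52,10.48
21,0.979,0,0.113,0.409,8.527,0.045,17.83,17.91
22,0.472,8,5.149,4.087,5.615,6.619,16.79,13.84
23,0.988,12,0.701,0.068,0.068,0.104,8.68,8.67
24,0.884,17,0.127,0.575,0.107,0.195,13.21,13.10
25,0.914,59,0.949,0.487,3.098,0.957,12.52,12.43
26,0.978,10,1.282,0.085,4.323,0.086,12.48,12.46
27,0.983,12,0.107,0.053,1.616,0.100,10.63,10.61
28,0.972,21,0.380,0.874,2.694,0.436,6.32,5.96
29,0.884,46,0.300,1.005,0.738,0.293,10.37,10.54
30,0.768,10,3.163,2.429,4.391,4.172,11.04,11.81
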