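id,f1,sensitivity,precision,tp,fp,fn,n_rpeaks_ecg,n_pred_hb,meas_time_s
1,95.91,95.97,95.84,691,30,29,729,721,607.6
2,98.27,98.13,98.41,682,11,13,721,694,622.4
3,96.86,95.80,97.94,570,12,25,597,583,601.4
4,98.00,98.00,98.00,685,14,14,702,699,603.1
5,78.81,77.81,79.84,491,124,140,643,617,610.1
6,97.24,97.33,97.15,546,16,15,571,563,610.9
7,74.46,74.10,74.83,452,152,158,647,604,634.9
8,99.04,98.95,99.12,565,5,6,588,572,618.6
9,98.73,98.31,99.15,581,5,10,641,586,649.4
10,85.56,85.28,85.84,394,65,68,491,459,639.1
11,96.60,95.73,97.49,583,15,26,660,601,648.9
12,83.79,83.65,83.92,522,100,102,675,622,648.5
13,99.56,99.50,99.62,791,3,4,801,794,725.6
14,50.06,49.81,50.32,395,390,398,798,785,603.5
15,99.14,99.06,99.22,635,5,6,696,641,648.5
16,97.78,97.58,97.98,484,10,12,504,495,610.6
17,84.92,89.06,81.15,521,121,64,589,643,603.3
18,83.41,83.41,83.41,538,107,107,686,645,636.0
19,95.94,95.64,96.24,461,18,21,484,481,603.1
20,99.84,99.67,100.00,610,0,2,653,610,640.2
21,91.01,90.80,91.21,602,58,61,678,662,613.9
22,95.37,95.20,95.54,535,25,27,619,560,659.8
23,99.68,99.51,99.84,614,1,3,634,616,678.9
24,99.93,99.85,100.00,678,0,1,690,678,610.5
25,98.97,98.97,98.97,671,7,7,697,678,616.9
26,99.29,99.29,99.29,704,5,5,746,711,821.0
27,100.00,100.00,100.00,593,0,0,619,593,627.9
28,97.87,97.49,98.25,505,9,13,528,514,611.9
29,100.00,100.00,100.00,598,0,0,615,598,615.9
30,98.33,97.85,98.82,501,6,11,536,507,626.6
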