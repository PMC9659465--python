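diet_id,abw,fi,adg,fcr,amei,nei,thp,hi,re,rq,ame,amen,ne,ame_ge,amen_ge,ne_ame,ne_amen
exp1_ref,462.16,64.16,62.52,1.04,1.62,1.13,0.94,0.49,0.68,0.99,14.72,14.28,10.26,76.67,74.38,69.71,71.86
ref,414.34,56.37,38.64,1.53,1.38,0.85,0.98,0.53,0.41,1.00,13.29,13.06,8.20,72.73,71.45,62.04,63.15
diet_wheat_1,440.66,51.43,42.50,1.48,1.34,0.77,1.02,0.57,0.32,1.01,12.55,12.35,7.22,65.91,65.80,56.84,57.73
diet_wheat_2,450.63,71.08,43.58,1.65,1.66,1.02,1.09,0.64,0.57,0.98,12.40,12.16,8.05,65.83,65.69,60.81,62.21
diet_wheat_3,429.38,68.27,37.86,1.82,1.58,1.02,1.02,0.57,0.57,0.98,12.91,12.63,8.33,59.36,59.25,60.22,61.61
diet_wheat_4,425.96,65.59,45.08,1.46,1.57,1.00,1.03,0.58,0.55,0.99,12.63,12.37,8.47,65.54,65.39,62.95,64.44
diet_wheat_5,407.04,56.29,31.86,1.83,1.27,0.78,0.94,0.49,0.33,0.99,12.49,12.24,7.60,66.97,66.83,60.76,61.99
diet_bran_1,362.32,57.04,37.29,1.72,1.23,0.70,0.97,0.53,0.25,0.99,11.22,11.03,6.38,58.89,58.78,57.07,58.11
diet_bran_2,368.65,56.43,35.24,1.65,1.21,0.65,1.00,0.55,0.21,0.98,10.88,10.67,5.72,55.81,55.70,54.16,55.26
diet_bran_3,354.59,56.42,37.56,1.57,1.19,0.60,1.04,0.59,0.16,1.01,11.05,10.88,5.82,57.55,57.45,52.16,52.98
diet_bran_4,358.69,55.17,45.00,1.28,1.24,0.67,1.02,0.57,0.22,0.99,11.33,11.13,5.88,59.79,59.68,51.29,52.19
diet_bran_5,321.40,50.42,34.87,1.57,1.20,0.64,1.01,0.56,0.19,0.99,11.12,10.95,6.07,58.73,58.63,53.41,54.25
exp3_wheat,445.21,59.38,32.08,1.86,1.35,0.91,0.89,0.44,0.46,0.94,12.94,12.34,8.65,70.39,67.10,66.79,70.04
exp3_bran,347.33,53.28,38.51,1.39,1.23,0.66,1.02,0.57,0.21,1.01,11.04,10.89,8.19,63.85,63.00,74.20,75.22
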