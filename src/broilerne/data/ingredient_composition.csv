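ingredient_id,kind,dm,cp,ee,cf,ndf,adf,st,ge
wheat_1,wheat,88.60,14.75,1.92,2.71,39.39,4.63,646.73,
wheat_2,wheat,91.20,14.01,1.75,2.30,35.31,3.62,627.19,
wheat_3,wheat,89.30,14.78,2.02,2.13,33.93,3.25,665.17,
wheat_4,wheat,83.20,14.53,2.04,2.28,40.26,3.73,682.69,
wheat_5,wheat,85.00,14.21,2.24,2.82,39.18,3.53,672.94,
wheat_v,wheat,87.80,14.45,2.05,3.53,38.15,4.78,602.51,
bran_1,wheat_bran,88.10,18.04,4.43,14.07,48.01,15.32,149.83,
bran_2,wheat_bran,87.90,17.23,4.31,14.30,48.58,16.00,145.29,
bran_3,wheat_bran,87.20,18.17,4.43,14.19,48.69,15.44,150.23,
bran_4,wheat_bran,88.80,18.30,4.20,13.96,46.77,15.78,143.02,
bran_5,wheat_bran,88.10,18.02,4.31,14.07,48.47,16.91,140.75,
bran_v,wheat_bran,87.70,17.868,4.33,14.03,49.03,15.85,161.92,
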