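ingredient_id,kind,ame,amen,ne,ame_ge,amen_ge,ne_ame,ne_amen
wheat_1,wheat,12.93,12.70,9.34,70.90,69.62,72.24,73.57
wheat_2,wheat,13.10,12.83,10.02,71.33,69.85,76.48,78.10
wheat_3,wheat,13.09,12.81,10.27,72.02,70.52,78.51,80.18
wheat_4,wheat,13.75,13.50,11.33,73.25,71.93,82.38,83.89
wheat_5,wheat,13.32,13.06,10.49,72.47,71.04,78.74,80.33
wheat_v,wheat,13.79,13.21,10.48,69.71,66.77,75.96,79.32
bran_1,wheat_bran,7.72,7.49,5.37,60.62,58.88,69.61,71.67
bran_2,wheat_bran,7.09,6.88,5.17,58.46,56.79,72.98,75.12
bran_3,wheat_bran,6.97,6.79,4.87,59.60,58.02,69.83,71.73
bran_4,wheat_bran,6.93,6.73,5.06,57.21,55.49,72.93,75.19
bran_5,wheat_bran,6.85,6.66,4.88,58.11,56.58,71.27,73.20
bran_v,wheat_bran,6.90,6.75,4.82,61.16,59.79,70.01,71.63
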