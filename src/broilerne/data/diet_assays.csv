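diet_id,dm,ge,cp
exp1_ref,88.26,16.94,20.65
ref,93.63,18.27,21.04
diet_wheat_1,92.84,17.68,18.34
diet_wheat_2,94.25,17.76,19.96
diet_wheat_3,93.81,17.79,19.53
diet_wheat_4,92.60,17.85,20.43
diet_wheat_5,93.99,17.52,20.10
diet_bran_1,93.44,17.80,20.42
diet_bran_2,92.74,17.62,20.46
diet_bran_3,92.40,17.75,20.11
diet_bran_4,94.27,17.86,20.60
diet_bran_5,95.25,18.05,20.98
exp3_wheat,90.10,18.39,20.06
exp3_bran,92.10,17.28,20.59
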