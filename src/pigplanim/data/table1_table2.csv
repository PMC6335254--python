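posture,n_images,n_female,n_male_neutered,weight_mean,weight_sd,weight_min,weight_max,area_mean,area_sd,area_min,area_max
A,185,99,86,109.09,11.23,76.00,133.00,0.288,0.026,0.203,0.344
AS,138,79,59,110.58,10.39,76.50,133.00,0.294,0.023,0.222,0.363
B,154,76,78,108.13,11.57,76.00,133.00,0.298,0.029,0.215,0.356
BS,108,75,33,110.98,10.14,76.50,133.00,0.307,0.026,0.226,0.358
C,181,95,86,109.07,11.92,75.00,133.00,0.316,0.030,0.236,0.376
CS,151,86,65,111.22,10.59,76.50,133.00,0.324,0.026,0.229,0.383
D,201,107,94,108.08,11.38,75.00,131.00,0.326,0.030,0.234,0.388
DS,156,86,70,108.62,11.45,75.00,131.00,0.328,0.030,0.240,0.391
E,112,51,61,106.26,12.52,75.00,131.00,0.325,0.033,0.235,0.395
ES,68,37,31,110.48,11.82,75.00,133.00,0.335,0.030,0.246,0.398
LBC,50,26,24,108.21,11.62,86.00,132.50,0.428,0.032,0.360,0.522
LSL,49,25,24,106.89,10.36,86.00,131.00,0.442,0.039,0.357,0.538
LL,30,13,17,107.50,10.54,86.00,132.50,0.486,0.040,0.384,0.578
Total,1583,,,109.01,11.45,75.00,133.00,,,,
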