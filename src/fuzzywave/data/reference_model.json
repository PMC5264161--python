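{
 "n_inputs": 5,
 "n_rules": 8,
 "input_names": [
  "pH",
  "DMP_in",
  "DO",
  "ORP",
  "MLSS"
 ],
 "centers": [
  [
   -0.5389,
   -0.7172,
   0.349,
   -0.2469,
   -0.5437
  ],
  [
   -0.7848,
   -1.848,
   -0.7183,
   -1.7457,
   -0.6529
  ],
  [
   -0.5258,
   0.8699,
   0.684,
   0.5744,
   1.0631
  ],
  [
   -1.5954,
   0.9924,
   1.3793,
   3.2149,
   0.0144
  ],
  [
   0.3623,
   -0.0754,
   0.5229,
   1.7393,
   -0.0959
  ],
  [
   -0.0739,
   -0.0404,
   -0.5956,
   -0.1936,
   -0.3236
  ],
  [
   0.3164,
   -1.3487,
   2.465,
   3.3962,
   -0.0233
  ],
  [
   0.4617,
   -2.3481,
   0.0942,
   1.1412,
   0.25
  ]
 ],
 "spreads": [
  [
   0.8539,
   1.8252,
   2.0263,
   2.3372,
   10.4541
  ],
  [
   1.1428,
   -0.2853,
   3.2959,
   4.1071,
   4.9547
  ],
  [
   1.1863,
   1.1137,
   1.6768,
   -1.723,
   -3.3109
  ],
  [
   -4.0123,
   1.0084,
   -11.0373,
   -5.0486,
   6.8924
  ],
  [
   1.2555,
   0.5307,
   1.2107,
   123.1388,
   1.5124
  ],
  [
   2.4957,
   0.5781,
   3.347,
   -3.1294,
   2.1482
  ],
  [
   1.6734,
   1.3379,
   3.8458,
   6.7531,
   1.5783
  ],
  [
   0.6413,
   26.4292,
   2.6414,
   291.9978,
   1.4563
  ]
 ],
 "dilations": [
  [
   0.1645,
   2.1958,
   -0.148,
   -1.8523,
   37.3451
  ],
  [
   1.8295,
   0.4551,
   1.8514,
   3.2568,
   1.4103
  ],
  [
   5.3467,
   -2.9073,
   -1.0283,
   -0.0282,
   -1.296
  ],
  [
   1.4598,
   3.036,
   3.2318,
   -3.4982,
   -0.4079
  ],
  [
   1.6957,
   1.4816,
   -3.01,
   1.9316,
   -0.413
  ],
  [
   -0.0362,
   5.5159,
   5.5763,
   1.9583,
   1.8806
  ],
  [
   1.7613,
   4.9113,
   -0.6543,
   3.9411,
   -1.5826
  ],
  [
   -0.2095,
   -0.4166,
   0.2922,
   -3.1274,
   0.2126
  ]
 ],
 "translations": [
  [
   2.3704,
   2.5965,
   3.7188,
   -8.5249,
   479.7433
  ],
  [
   2.5098,
   -4.577,
   -8.3325,
   2.1585,
   7.6682
  ],
  [
   4.6311,
   -37.5183,
   -5.8732,
   -3.8119,
   -22.6885
  ],
  [
   15.2528,
   0.2599,
   -0.2844,
   -2.7673,
   8.6046
  ],
  [
   2.6433,
   1.3972,
   -6.3009,
   4.2983,
   -2.8903
  ],
  [
   -2.1006,
   8.0701,
   4.7896,
   -11.49,
   -9.9694
  ],
  [
   25.9841,
   3.0967,
   5.1786,
   0.322,
   -25.5946
  ],
  [
   -8.3017,
   -8.1186,
   -2.3139,
   -43.2687,
   -2.5354
  ]
 ],
 "weights": [
  0.3637,
  -1.6482,
  1.4141,
  2.3637,
  0.1636,
  2.3659,
  -4.0472,
  1.161
 ],
 "aggregation": "normalized",
 "wavelet": "mexican_hat"
}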