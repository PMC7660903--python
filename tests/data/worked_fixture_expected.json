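{
 "n_sequences": 36,
 "expected_clusters": {
  "c01_f1": [
   "c01_f1_m1",
   "c01_f1_m2",
   "c01_f1_m3",
   "c01_f1_m4"
  ],
  "c01_f2": [
   "c01_f2_m1",
   "c01_f2_m2",
   "c01_f2_m3",
   "c01_f2_m4"
  ],
  "c01_f3": [
   "c01_f3_m1",
   "c01_f3_m2",
   "c01_f3_m3",
   "c01_f3_m4"
  ],
  "c02_f1": [
   "c02_f1_m1",
   "c02_f1_m2",
   "c02_f1_m3",
   "c02_f1_m4"
  ],
  "c02_f2": [
   "c02_f2_m1",
   "c02_f2_m2",
   "c02_f2_m3",
   "c02_f2_m4"
  ],
  "c02_f3": [
   "c02_f3_m1",
   "c02_f3_m2",
   "c02_f3_m3",
   "c02_f3_m4"
  ],
  "c03_f1": [
   "c03_f1_m1",
   "c03_f1_m2",
   "c03_f1_m3",
   "c03_f1_m4"
  ],
  "c03_f2": [
   "c03_f2_m1",
   "c03_f2_m2",
   "c03_f2_m3",
   "c03_f2_m4"
  ],
  "c03_f3": [
   "c03_f3_m1",
   "c03_f3_m2",
   "c03_f3_m3",
   "c03_f3_m4"
  ]
 },
 "split_seed": 11,
 "split_sets": {
  "c01_f1_m1": "4D",
  "c01_f1_m2": "4D",
  "c01_f1_m3": "4D",
  "c01_f1_m4": "4D",
  "c01_f2_m1": "5D",
  "c01_f2_m2": "5D",
  "c01_f2_m3": "5D",
  "c01_f2_m4": "5D",
  "c01_f3_m1": "6D",
  "c01_f3_m2": "6D",
  "c01_f3_m3": "6D",
  "c01_f3_m4": "6D",
  "c02_f1_m1": "1D",
  "c02_f1_m2": "1D",
  "c02_f1_m3": "1D",
  "c02_f1_m4": "1D",
  "c02_f2_m1": "TEST",
  "c02_f2_m2": "TEST",
  "c02_f2_m3": "TEST",
  "c02_f2_m4": "TEST",
  "c02_f3_m1": "2D",
  "c02_f3_m2": "2D",
  "c02_f3_m3": "2D",
  "c02_f3_m4": "2D",
  "c03_f1_m1": "10D",
  "c03_f1_m2": "10D",
  "c03_f1_m3": "10D",
  "c03_f1_m4": "10D",
  "c03_f2_m1": "TEST",
  "c03_f2_m2": "TEST",
  "c03_f2_m3": "TEST",
  "c03_f2_m4": "TEST",
  "c03_f3_m1": "9D",
  "c03_f3_m2": "9D",
  "c03_f3_m3": "9D",
  "c03_f3_m4": "9D"
 }
}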