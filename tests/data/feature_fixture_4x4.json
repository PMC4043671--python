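{
 "T": [
  [
   20.0,
   21.0,
   22.0,
   23.0
  ],
  [
   24.0,
   25.5,
   26.0,
   27.5
  ],
  [
   28.0,
   29.0,
   30.5,
   31.0
  ],
  [
   32.0,
   33.5,
   34.0,
   35.0
  ]
 ],
 "L": [
  [
   0.1,
   0.2,
   0.3,
   0.4
  ],
  [
   0.5,
   0.6,
   0.7,
   0.8
  ],
  [
   0.9,
   1.0,
   0.25,
   0.75
  ],
  [
   0.45,
   0.55,
   0.65,
   0.35
  ]
 ],
 "a": [
  [
   -40.0,
   -38.0,
   18.0,
   20.0
  ],
  [
   -36.0,
   -42.0,
   22.0,
   16.0
  ],
  [
   -39.0,
   -41.0,
   19.0,
   21.0
  ],
  [
   -40.0,
   -40.0,
   20.0,
   20.0
  ]
 ],
 "b": [
  [
   5.0,
   12.0,
   7.0,
   3.0
  ],
  [
   9.0,
   4.0,
   11.0,
   6.0
  ],
  [
   2.0,
   8.0,
   10.0,
   1.0
  ],
  [
   13.0,
   0.0,
   6.5,
   7.5
  ]
 ],
 "expected": {
  "mu_LT": 15.109375,
  "mu_a": -10.0,
  "mu_b": 6.5625,
  "sigma_nT": 0.04390823812049047,
  "mu_aT": 26.625,
  "sigma_aT": 4.574043615882997,
  "mu_T": 27.625,
  "sigma_T": 4.648588495446763
 },
 "note": "synthetic 4x4 grids; expected values computed by direct enumeration with population-std convention"
}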