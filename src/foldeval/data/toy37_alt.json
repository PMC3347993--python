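{
 "meta": {
  "name": "toy37_alt",
  "RT": 0.6163
 },
 "stack": {
  "AU": {
   "AU": -2.16,
   "CG": -2.5,
   "GC": -2.5,
   "GU": -1.82,
   "UA": -2.16,
   "UG": -1.82
  },
  "CG": {
   "AU": -2.5,
   "CG": -2.84,
   "GC": -2.84,
   "GU": -2.16,
   "UA": -2.5,
   "UG": -2.16
  },
  "GC": {
   "AU": -2.5,
   "CG": -2.84,
   "GC": -2.84,
   "GU": -2.16,
   "UA": -2.5,
   "UG": -2.16
  },
  "GU": {
   "AU": -1.82,
   "CG": -2.16,
   "GC": -2.16,
   "GU": -1.48,
   "UA": -1.82,
   "UG": -1.48
  },
  "UA": {
   "AU": -2.16,
   "CG": -2.5,
   "GC": -2.5,
   "GU": -1.82,
   "UA": -2.16,
   "UG": -1.82
  },
  "UG": {
   "AU": -1.82,
   "CG": -2.16,
   "GC": -2.16,
   "GU": -1.48,
   "UA": -1.82,
   "UG": -1.48
  }
 },
 "hairpin_len": [
  0.0,
  0.0,
  0.0,
  5.7,
  6.25,
  6.67,
  7.02,
  7.31,
  7.56,
  7.79,
  7.99,
  8.17,
  8.33,
  8.49,
  8.63,
  8.76,
  8.88,
  9.0,
  9.1,
  9.21,
  9.3,
  9.4,
  9.49,
  9.57,
  9.65,
  9.73,
  9.8,
  9.87,
  9.94,
  10.01,
  10.07
 ],
 "bulge_len": [
  0.0,
  3.6,
  4.92,
  5.69,
  6.23,
  6.66,
  7.0,
  7.3,
  7.55,
  7.77,
  7.97,
  8.16,
  8.32,
  8.47,
  8.61,
  8.75,
  8.87,
  8.98,
  9.09,
  9.19,
  9.29,
  9.38,
  9.47,
  9.56,
  9.64,
  9.72,
  9.79,
  9.86,
  9.93,
  10.0,
  10.06
 ],
 "internal_len": [
  0.0,
  0.0,
  1.9,
  2.67,
  3.22,
  3.64,
  3.99,
  4.28,
  4.53,
  4.76,
  4.96,
  5.14,
  5.3,
  5.46,
  5.6,
  5.73,
  5.85,
  5.97,
  6.07,
  6.18,
  6.27,
  6.37,
  6.46,
  6.54,
  6.62,
  6.7,
  6.77,
  6.85,
  6.91,
  6.98,
  7.05
 ],
 "multiloop": {
  "a": 4.0,
  "b": 0.3,
  "c": 0.2
 },
 "terminal_au": 0.7,
 "ln_coeff": 1.3
}
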