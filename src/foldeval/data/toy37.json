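{
 "meta": {
  "name": "toy37",
  "RT": 0.6163
 },
 "stack": {
  "AU": {
   "AU": -2.2,
   "CG": -2.6,
   "GC": -2.6,
   "GU": -1.8,
   "UA": -2.2,
   "UG": -1.8
  },
  "CG": {
   "AU": -2.6,
   "CG": -3.0,
   "GC": -3.0,
   "GU": -2.2,
   "UA": -2.6,
   "UG": -2.2
  },
  "GC": {
   "AU": -2.6,
   "CG": -3.0,
   "GC": -3.0,
   "GU": -2.2,
   "UA": -2.6,
   "UG": -2.2
  },
  "GU": {
   "AU": -1.8,
   "CG": -2.2,
   "GC": -2.2,
   "GU": -1.4,
   "UA": -1.8,
   "UG": -1.4
  },
  "UA": {
   "AU": -2.2,
   "CG": -2.6,
   "GC": -2.6,
   "GU": -1.8,
   "UA": -2.2,
   "UG": -1.8
  },
  "UG": {
   "AU": -1.8,
   "CG": -2.2,
   "GC": -2.2,
   "GU": -1.4,
   "UA": -1.8,
   "UG": -1.4
  }
 },
 "hairpin_len": [
  0.0,
  0.0,
  0.0,
  5.4,
  5.86,
  6.22,
  6.51,
  6.76,
  6.97,
  7.16,
  7.33,
  7.48,
  7.62,
  7.75,
  7.86,
  7.98,
  8.08,
  8.18,
  8.27,
  8.35,
  8.44,
  8.51,
  8.59,
  8.66,
  8.73,
  8.79,
  8.86,
  8.92,
  8.97,
  9.03,
  9.08
 ],
 "bulge_len": [
  0.0,
  3.8,
  4.91,
  5.56,
  6.02,
  6.38,
  6.67,
  6.91,
  7.13,
  7.32,
  7.48,
  7.64,
  7.78,
  7.9,
  8.02,
  8.13,
  8.24,
  8.33,
  8.42,
  8.51,
  8.59,
  8.67,
  8.75,
  8.82,
  8.88,
  8.95,
  9.01,
  9.07,
  9.13,
  9.19,
  9.24
 ],
 "internal_len": [
  0.0,
  0.0,
  1.7,
  2.35,
  2.81,
  3.17,
  3.46,
  3.7,
  3.92,
  4.11,
  4.28,
  4.43,
  4.57,
  4.69,
  4.81,
  4.92,
  5.03,
  5.12,
  5.22,
  5.3,
  5.38,
  5.46,
  5.54,
  5.61,
  5.68,
  5.74,
  5.8,
  5.86,
  5.92,
  5.98,
  6.03
 ],
 "multiloop": {
  "a": 3.4,
  "b": 0.4,
  "c": 0.1
 },
 "terminal_au": 0.5,
 "ln_coeff": 1.08
}
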