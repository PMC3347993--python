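{
 "description": "Published multi-class RNA secondary-structure benchmark results: per-class mean F-measures of six predictor/parameter-set combinations on the MT dataset, the MT within-class mean normalized structure similarities, selected MA-dataset values, and 95% bootstrap percentile confidence intervals on the MA and S-Full datasets.",
 "classes": ["16S_rRNA", "23S_rRNA", "5S_rRNA", "GroupI_intron", "GroupII_intron", "RNaseP", "SRP_RNA", "tRNA"],
 "mt": {
  "class_sizes": [88, 27, 309, 16, 3, 6, 91, 484],
  "similarity": [0.60, 0.53, 0.88, 0.63, 0.70, 0.74, 0.71, 0.96],
  "f_per_class": {
   "ubcMEA_BL": [0.649, 0.711, 0.739, 0.705, 0.720, 0.471, 0.641, 0.718],
   "ubcMFE_BL": [0.621, 0.683, 0.743, 0.650, 0.739, 0.460, 0.621, 0.775],
   "gC-g1_BL": [0.640, 0.693, 0.725, 0.674, 0.683, 0.519, 0.633, 0.727],
   "gC-pMFmeas_BL": [0.659, 0.733, 0.746, 0.708, 0.750, 0.495, 0.637, 0.782],
   "rsMEA_Turner99": [0.574, 0.681, 0.625, 0.627, 0.744, 0.517, 0.518, 0.726],
   "rsMFE_Turner99": [0.539, 0.646, 0.642, 0.599, 0.703, 0.522, 0.557, 0.727]
  },
  "printed_averages": {
   "unweighted": {"ubcMEA_BL": 0.669, "ubcMFE_BL": 0.662, "gC-g1_BL": 0.662, "gC-pMFmeas_BL": 0.689, "rsMEA_Turner99": 0.627, "rsMFE_Turner99": 0.617},
   "weighted": {"ubcMEA_BL": 0.710, "ubcMFE_BL": 0.732, "gC-g1_BL": 0.707, "gC-pMFmeas_BL": 0.743, "rsMEA_Turner99": 0.660, "rsMFE_Turner99": 0.665},
   "s_weighted": {"ubcMEA_BL": 0.670, "ubcMFE_BL": 0.652, "gC-g1_BL": 0.660, "gC-pMFmeas_BL": 0.684, "rsMEA_Turner99": 0.612, "rsMFE_Turner99": 0.598}
  }
 },
 "ma": {
  "f_rnasep_ubcMEA_BL": 0.643,
  "mt_rnasep_ubcMEA_BL": 0.471
 },
 "confidence_intervals": {
  "columns": ["ubcMEA", "ubcMFE", "rsMEA", "rsMFE", "gC-pMFmeas"],
  "per_class": {
   "16S_rRNA": [[0.611, 0.639], [0.630, 0.660], [0.548, 0.574], [0.507, 0.536], [0.652, 0.679]],
   "23S_rRNA": [[0.609, 0.677], [0.607, 0.677], [0.556, 0.618], [0.530, 0.593], [0.633, 0.693]],
   "5S_rRNA": [[0.754, 0.807], [0.751, 0.806], [0.573, 0.657], [0.586, 0.671], [0.758, 0.804]],
   "GroupI_intron": [[0.605, 0.680], [0.594, 0.666], [0.540, 0.611], [0.513, 0.587], [0.634, 0.704]],
   "RNaseP": [[0.629, 0.659], [0.588, 0.618], [0.602, 0.628], [0.561, 0.588], [0.665, 0.690]],
   "SRP_RNA": [[0.708, 0.750], [0.698, 0.742], [0.583, 0.635], [0.599, 0.651], [0.685, 0.728]],
   "tRNA": [[0.683, 0.723], [0.742, 0.785], [0.707, 0.747], [0.705, 0.748], [0.754, 0.791]]
  },
  "large_sets": {
   "MA": [[0.664, 0.680], [0.673, 0.691], [0.610, 0.627], [0.591, 0.609], [0.700, 0.715]],
   "S-Full": [[0.673, 0.688], [0.678, 0.694], [0.615, 0.631], [0.598, 0.616], [0.704, 0.718]]
  }
 }
}
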