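{
 "description": "SYNTHETIC tissue-surrogate inserts for the two-size multi-insert cylindrical phantom (nominal compositions; vendor data are proprietary). bone_200/bone_800 carry nominal 200/800 mg/cm3 hydroxyapatite loadings.",
 "inserts": {
  "lung_inhale": {
   "density_g_cm3": 0.2,
   "mass_fractions": {
    "H": 0.103833,
    "O": 0.738149,
    "C": 0.120498,
    "N": 0.02592,
    "S": 0.0031,
    "Na": 0.0018,
    "Mg": 0.0005,
    "Cl": 0.003,
    "K": 0.0027,
    "Fe": 0.0005
   }
  },
  "lung_exhale": {
   "density_g_cm3": 0.5,
   "mass_fractions": {
    "H": 0.103833,
    "O": 0.738149,
    "C": 0.120498,
    "N": 0.02592,
    "S": 0.0031,
    "Na": 0.0018,
    "Mg": 0.0005,
    "Cl": 0.003,
    "K": 0.0027,
    "Fe": 0.0005
   }
  },
  "adipose": {
   "density_g_cm3": 0.96,
   "mass_fractions": {
    "H": 0.113271,
    "O": 0.239125,
    "C": 0.627284,
    "N": 0.00972,
    "S": 0.0021,
    "Na": 0.0018,
    "Mg": 0.0005,
    "Cl": 0.003,
    "K": 0.0027,
    "Fe": 0.0005
   }
  },
  "breast": {
   "density_g_cm3": 0.99,
   "mass_fractions": {
    "H": 0.109066,
    "O": 0.402122,
    "C": 0.458172,
    "N": 0.01944,
    "S": 0.0027,
    "Na": 0.0018,
    "Mg": 0.0005,
    "Cl": 0.003,
    "K": 0.0027,
    "Fe": 0.0005
   }
  },
  "water": {
   "density_g_cm3": 1.0,
   "mass_fractions": {
    "H": 0.111894,
    "O": 0.888106
   }
  },
  "muscle": {
   "density_g_cm3": 1.06,
   "mass_fractions": {
    "H": 0.103191,
    "O": 0.701515,
    "C": 0.154334,
    "N": 0.02916,
    "S": 0.0033,
    "Na": 0.0018,
    "Mg": 0.0005,
    "Cl": 0.003,
    "K": 0.0027,
    "Fe": 0.0005
   }
  },
  "liver": {
   "density_g_cm3": 1.07,
   "mass_fractions": {
    "H": 0.102258,
    "O": 0.685816,
    "C": 0.170966,
    "N": 0.02916,
    "S": 0.0033,
    "Na": 0.0018,
    "Mg": 0.0005,
    "Cl": 0.003,
    "K": 0.0027,
    "Fe": 0.0005
   }
  },
  "bone_200": {
   "density_g_cm3": 1.16,
   "mass_fractions": {
    "H": 0.090068,
    "O": 0.673844,
    "C": 0.11988,
    "N": 0.01296,
    "S": 0.0011,
    "P": 0.03182,
    "Ca": 0.068628,
    "Na": 0.00036,
    "Mg": 0.0001,
    "Cl": 0.0006,
    "K": 0.00054,
    "Fe": 0.0001
   }
  },
  "bone_800": {
   "density_g_cm3": 1.53,
   "mass_fractions": {
    "H": 0.050661,
    "O": 0.534599,
    "C": 0.09186,
    "N": 0.0162,
    "S": 0.0013,
    "P": 0.0962,
    "Ca": 0.20748,
    "Na": 0.00036,
    "Mg": 0.0001,
    "Cl": 0.0006,
    "K": 0.00054,
    "Fe": 0.0001
   }
  }
 }
}
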