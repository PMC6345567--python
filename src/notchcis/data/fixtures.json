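{
  "all_ones": {
    "note": "Every production, degradation and binding rate equal to 1; the reference point for hand-checked arithmetic and oracle cross-checks.",
    "params": {
      "alpha_N": 1.0,
      "alpha_D": 1.0,
      "gamma_N": 1.0,
      "gamma_D": 1.0,
      "gamma_Cplus": 1.0,
      "gamma_Cminus": 1.0,
      "k_Cplus_on": 1.0,
      "k_Cplus_off": 1.0,
      "k_Cminus_on": 1.0,
      "k_Cminus_off": 1.0,
      "D_trans": 0.0
    }
  },
  "m2c_nonmonotonic": {
    "note": "First Latin-Hypercube draw of the default seed-0 ensemble for model M2c; its cis-only C+ profile peaks at grid position 5 with fractional incline 0.568 and decline 0.925 under default scan settings.",
    "params": {
      "alpha_N": 48.384842963682885,
      "alpha_D": 1.0,
      "gamma_N": 0.8326973186415841,
      "gamma_D": 46.27812996886441,
      "gamma_Cplus": 2.082945600774963,
      "gamma_Cminus": 0.07317907158568975,
      "k_Cplus_on": 3.0423381574905926,
      "k_Cplus_off": 0.029618641245970797,
      "k_Cminus_on": 37.79014188863498,
      "k_Cminus_off": 0.03815601566733015,
      "D_trans": 0.0
    }
  },
  "no_binding": {
    "note": "Degenerate set with both association rates zero: free species settle at alpha/gamma and every complex concentration is exactly 0.",
    "params": {
      "alpha_N": 2.0,
      "alpha_D": 3.0,
      "gamma_N": 0.5,
      "gamma_D": 1.5,
      "gamma_Cplus": 1.0,
      "gamma_Cminus": 1.0,
      "k_Cplus_on": 0.0,
      "k_Cplus_off": 1.0,
      "k_Cminus_on": 0.0,
      "k_Cminus_off": 1.0,
      "D_trans": 0.0
    }
  }
}
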