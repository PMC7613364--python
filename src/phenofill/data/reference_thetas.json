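{
  "description": "Precalculated SE-kernel hyperparameters for nine common crop types plus a global (all-crop) average, derived from per-pixel training on Sentinel-2 LAI time series over an agricultural region; usable as defaults when no local training is possible.",
  "epoch": "2016-01-01",
  "per_crop": {
    "wheat":     {"log_inv_l": -3.9432, "log_sigma_f": -0.6151, "log_sigma_n": -2.0441},
    "corn":      {"log_inv_l": -3.6245, "log_sigma_f": -0.1381, "log_sigma_n": -1.5917},
    "barley":    {"log_inv_l": -3.6819, "log_sigma_f": -0.6275, "log_sigma_n": -2.0289},
    "sunflower": {"log_inv_l": -3.6563, "log_sigma_f": -1.4275, "log_sigma_n": -2.1427},
    "rape":      {"log_inv_l": -3.8655, "log_sigma_f": -0.0032, "log_sigma_n": -1.3874},
    "pea":       {"log_inv_l": -3.2352, "log_sigma_f": -0.9412, "log_sigma_n": -2.1000},
    "alfalfa":   {"log_inv_l": -3.6324, "log_sigma_f": -0.9359, "log_sigma_n": -1.8461},
    "beet":      {"log_inv_l": -3.7147, "log_sigma_f":  0.2405, "log_sigma_n": -1.0593},
    "potato":    {"log_inv_l": -3.4294, "log_sigma_f":  0.1128, "log_sigma_n": -1.4976}
  },
  "global": {"log_inv_l": -3.6430, "log_sigma_f": -0.4817, "log_sigma_n": -1.7442}
}
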