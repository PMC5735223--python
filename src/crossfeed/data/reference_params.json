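{
  "comment": "Reference parameter library for the four-species FOS consortium. Interaction values are the reported pairwise ef estimates; kinetic slots are documented defaults tuned so the packaged scenarios reproduce the reported qualitative outcomes (dominance ordering, product yields, acid cross-feeding).",
  "species": {
    "Bi": {
      "name": "Bi",
      "mu_max": 1.0, "K_s": 0.05, "Y_sx": 0.25,
      "Y_a": 0.30, "Y_l": 0.20,
      "I_a": 8.0, "I_l": 6.0,
      "k_d": 0.02, "t_lag": 1.0,
      "mu_maxA": 0.0, "K_sA": 0.5, "Y_sxA": 0.0,
      "mu_maxL": 0.0, "K_sL": 0.5, "Y_sxL": 0.0,
      "K_rep": 0.05, "m_s": 0.0,
      "capabilities": {
        "produces_acetate": true, "produces_lactate": true,
        "consumes_acetate": false, "consumes_lactate": false
      }
    },
    "Bv": {
      "name": "Bv",
      "mu_max": 0.50, "K_s": 0.06, "Y_sx": 0.20,
      "Y_a": 0.25, "Y_l": 0.0,
      "I_a": 10.0, "I_l": 8.0,
      "k_d": 0.02, "t_lag": 1.0,
      "mu_maxA": 0.0, "K_sA": 0.5, "Y_sxA": 0.0,
      "mu_maxL": 0.0, "K_sL": 0.5, "Y_sxL": 0.0,
      "K_rep": 0.05, "m_s": 0.0,
      "capabilities": {
        "produces_acetate": true, "produces_lactate": false,
        "consumes_acetate": false, "consumes_lactate": false
      }
    },
    "Ec": {
      "name": "Ec",
      "mu_max": 0.45, "K_s": 0.04, "Y_sx": 0.22,
      "Y_a": 0.21, "Y_l": 0.0,
      "I_a": 6.0, "I_l": 5.0,
      "k_d": 0.02, "t_lag": 1.0,
      "mu_maxA": 0.08, "K_sA": 0.5, "Y_sxA": 0.18,
      "mu_maxL": 0.08, "K_sL": 0.5, "Y_sxL": 0.18,
      "K_rep": 0.05, "m_s": 0.0,
      "capabilities": {
        "produces_acetate": true, "produces_lactate": false,
        "consumes_acetate": true, "consumes_lactate": true
      }
    },
    "La": {
      "name": "La",
      "mu_max": 0.60, "K_s": 0.05, "Y_sx": 0.20,
      "Y_a": 0.0, "Y_l": 0.63,
      "I_a": 5.0, "I_l": 2.0,
      "k_d": 0.02, "t_lag": 2.0,
      "mu_maxA": 0.0, "K_sA": 0.5, "Y_sxA": 0.0,
      "mu_maxL": 0.0, "K_sL": 0.5, "Y_sxL": 0.0,
      "K_rep": 0.05, "m_s": 0.0,
      "capabilities": {
        "produces_acetate": false, "produces_lactate": true,
        "consumes_acetate": false, "consumes_lactate": false
      }
    }
  },
  "interactions": {
    "order": ["Bi", "Bv", "Ec", "La"],
    "ef": [
      [null, 99.99, 16.33, 45.05],
      [-40.52, null, 0.16, 1.99],
      [-37.56, -57.14, null, -26.61],
      [-70.23, -32.74, -99.99, null]
    ],
    "ef_limit": 100.0,
    "ef_min": 0.01
  },
  "inoculum_g_per_l": {
    "default": 0.01,
    "overrides": {"Ec": 0.05, "Bv": 0.002}
  },
  "calibrations": {
    "Bi": {"genome_size": 2832748, "copies_16s": 4, "cells_per_gram": 1e12},
    "Bv": {"genome_size": 5163189, "copies_16s": 7, "cells_per_gram": 1e12},
    "Ec": {"genome_size": 4641652, "copies_16s": 7, "cells_per_gram": 1e12},
    "La": {"genome_size": 1993560, "copies_16s": 4, "cells_per_gram": 1e12}
  }
}
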