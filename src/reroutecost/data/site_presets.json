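{
  "colorectal": {
    "site": "colorectal",
    "p_ep_base": 0.315,
    "confounding_coefs": {"age": 0.35, "imd": 0.25, "cci": 0.4},
    "weibull_shape": 1.0,
    "weibull_scale_ep": 17.1436,
    "aft_route_factor": 2.9239,
    "covariate_coefs_survival": {"age": -0.2, "imd": -0.05, "cci": -0.15},
    "cost_params": {
      "diagnosis_spike_mean": 2500.0,
      "baseline_mean": 450.0,
      "terminal_spike_mean": 2200.0,
      "predx_mean_ep": 110.0,
      "predx_mean_gp": 55.0,
      "route_intensity_ratio": 1.25,
      "gamma_shape": 0.8,
      "p_zero": 0.35
    },
    "entry_window_months": 36.0,
    "admin_cutoff_month": 72.0
  },
  "breast": {
    "site": "breast",
    "p_ep_base": 0.067,
    "confounding_coefs": {"age": 0.45, "imd": 0.25, "cci": 0.4},
    "weibull_shape": 0.9,
    "weibull_scale_ep": 20.4826,
    "aft_route_factor": 14.3092,
    "covariate_coefs_survival": {"age": -0.2, "imd": -0.05, "cci": -0.15},
    "cost_params": {
      "diagnosis_spike_mean": 1800.0,
      "baseline_mean": 200.0,
      "terminal_spike_mean": 1500.0,
      "predx_mean_ep": 90.0,
      "predx_mean_gp": 45.0,
      "route_intensity_ratio": 1.25,
      "gamma_shape": 0.8,
      "p_zero": 0.35
    },
    "entry_window_months": 36.0,
    "admin_cutoff_month": 72.0
  },
  "prostate": {
    "site": "prostate",
    "p_ep_base": 0.108,
    "confounding_coefs": {"age": 0.45, "imd": 0.25, "cci": 0.4},
    "weibull_shape": 0.8,
    "weibull_scale_ep": 26.8464,
    "aft_route_factor": 17.897,
    "covariate_coefs_survival": {"age": -0.2, "imd": -0.05, "cci": -0.15},
    "cost_params": {
      "diagnosis_spike_mean": 2000.0,
      "baseline_mean": 160.0,
      "terminal_spike_mean": 1000.0,
      "predx_mean_ep": 120.0,
      "predx_mean_gp": 40.0,
      "route_intensity_ratio": 1.6,
      "gamma_shape": 0.8,
      "p_zero": 0.35
    },
    "entry_window_months": 36.0,
    "admin_cutoff_month": 72.0
  },
  "lung": {
    "site": "lung",
    "p_ep_base": 0.44,
    "confounding_coefs": {"age": 0.3, "imd": 0.2, "cci": 0.35},
    "weibull_shape": 1.1,
    "weibull_scale_ep": 6.3637,
    "aft_route_factor": 2.0301,
    "covariate_coefs_survival": {"age": -0.15, "imd": -0.05, "cci": -0.12},
    "cost_params": {
      "diagnosis_spike_mean": 2000.0,
      "baseline_mean": 600.0,
      "terminal_spike_mean": 2500.0,
      "predx_mean_ep": 130.0,
      "predx_mean_gp": 70.0,
      "route_intensity_ratio": 1.25,
      "gamma_shape": 0.8,
      "p_zero": 0.35
    },
    "entry_window_months": 24.0,
    "admin_cutoff_month": 48.0
  }
}
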