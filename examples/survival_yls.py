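"""Weibull accelerated-failure-time survival by route to diagnosis.

Fits the AFT model on a synthetic cohort whose true GP/TWW time ratio is
the colorectal preset's 2.92, then reports the route time-ratio, the
5-year survival-probability gain, and restricted years of life saved.
"""

from reroutecost import (add_cci_count, fit_weibull_aft, simulate_cohort,
                         site_preset, survival_prob, years_of_life_saved)

cfg = site_preset("colorectal", n_patients=8000, seed=6)
cohort = simulate_cohort(cfg)
cohort.patients = add_cci_count(cohort.patients)

fit = fit_weibull_aft(cohort, covariates=("age", "imd_income", "cci_count"))
pop = cohort.patients
s_gp = survival_prob(fit, "GPTWW", 60, pop)
s_ep = survival_prob(fit, "EP", 60, pop)
yls = years_of_life_saved(fit, 60.0, pop)

print(f"route time-ratio: {fit.route_time_ratio:.2f} "
      f"(true {cfg.aft_route_factor})")
print(f"S(60) GP/TWW {s_gp:.3f}  EP {s_ep:.3f}  delta {s_gp - s_ep:.3f}")
print(f"years of life saved (RMST difference / 12): {yls:.2f}")
# A time ratio of ~2.9 means rerouted patients live ~2.9x longer; the RMST
# difference truncates that gain at the 5-year follow-up horizon.
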