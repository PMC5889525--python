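import numpy as np
import pandas as pd
import pytest

from reroutecost.simulate import (CostParams, EmptyCohortError,
                                  SimulationConfig, simulate_cohort,
                                  site_preset, true_effect_curve, true_effects)


def null_config(n=2000, seed=0):
    """Both routes share the same survival and cost laws."""
    cp = CostParams(route_intensity_ratio=1.0, predx_mean_ep=80.0,
                    predx_mean_gp=80.0)
    return SimulationConfig(n_patients=n, seed=seed, aft_route_factor=1.0,
                            cost_params=cp)


def test_seed_determinism():
    a = simulate_cohort(SimulationConfig(n_patients=300, seed=11))
    b = simulate_cohort(SimulationConfig(n_patients=300, seed=11))
    pd.testing.assert_frame_equal(a.patients, b.patients)
    pd.testing.assert_frame_equal(a.costs, b.costs)


def test_empty_cohort_rejected():
    with pytest.raises(EmptyCohortError):
        simulate_cohort(SimulationConfig(n_patients=0))


def test_ep_share_unconfounded_matches_baseline():
    n = 20_000
    cfg = SimulationConfig(n_patients=n, seed=2, p_ep_base=0.3,
                           confounding_coefs={})
    cohort = simulate_cohort(cfg)
    share = (cohort.patients["route"] == "EP").mean()
    se = np.sqrt(0.3 * 0.7 / n)
    assert abs(share - 0.3) < 3 * se


def test_exponential_survival_closed_form():
    # k = 1, lambda_EP = 20 months, no covariate effects on survival
    n = 20_000
    cfg = SimulationConfig(n_patients=n, seed=3, weibull_shape=1.0,
                           weibull_scale_ep=20.0, aft_route_factor=1.0,
                           covariate_coefs_survival={},
                           entry_window_months=1.0, admin_cutoff_month=1000.0)
    cohort, latents = simulate_cohort(cfg, return_latents=True)
    surv12 = (latents["death_time"] > 12).mean()
    expected = np.exp(-12 / 20)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(surv12 - expected) < 3 * se


def test_null_config_effects_are_exactly_zero():
    te = true_effects(null_config(), n_oracle=20_000)
    assert te["total_cost_effect"] == 0.0
    assert te["survival_effect"] == 0.0
    assert te["intensity_effect"] == 0.0
    assert te["delta_surv_prob"] == 0.0
    assert te["yls"] == 0.0


def test_survival_only_config_has_zero_intensity_effect():
    cp = CostParams(route_intensity_ratio=1.0, predx_mean_ep=80.0,
                    predx_mean_gp=80.0)
    cfg = SimulationConfig(n_patients=1000, seed=4, aft_route_factor=2.0,
                           cost_params=cp)
    te = true_effects(cfg, n_oracle=20_000)
    assert te["intensity_effect"] == 0.0
    assert te["total_cost_effect"] > 0  # longer GP survival accrues cost


def test_decomposition_identity_holds_for_any_config():
    for site in ("colorectal", "lung"):
        te = true_effects(site_preset(site), n_oracle=10_000)
        assert te["survival_effect"] + te["intensity_effect"] == pytest.approx(
            te["total_cost_effect"], abs=1e-9)


def test_censoring_independent_of_survival_error():
    cfg = SimulationConfig(n_patients=20_000, seed=6)
    _, latents = simulate_cohort(cfg, return_latents=True)
    corr = np.corrcoef(latents["censor_time"], latents["log_err"])[0, 1]
    assert abs(corr) < 3 / np.sqrt(len(latents))


def test_costs_only_in_alive_months_and_u_shape():
    cfg = site_preset("colorectal", n_patients=2000, seed=8)
    cohort = simulate_cohort(cfg)
    cohort.validate()  # includes the no-cost-after-event invariant
    costs = cohort.costs
    post = costs[costs["month_index"] >= 0]
    by_month = post.groupby("month_index")["cost_gbp"].sum()
    n_alive = pd.Series({
        m: (cohort.patients["time_to_event"] > m).sum()
        for m in range(cfg.horizon)})
    per_alive = by_month.reindex(n_alive.index, fill_value=0) / n_alive
    # diagnosis spike: months 0-2 cost more per alive patient than months 6-9
    assert per_alive.loc[0:2].mean() > 1.5 * per_alive.loc[6:9].mean()


def test_preset_twelve_month_survival_ranks_match_registry_pattern():
    surv = {}
    for site in ("colorectal", "breast", "prostate", "lung"):
        cfg = site_preset(site, n_patients=8000, seed=9)
        cohort, latents = simulate_cohort(cfg, return_latents=True)
        ep = cohort.patients["route"] == "EP"
        t = latents["death_time"]
        surv[site] = ((t[ep.to_numpy()] > 12).mean(),
                      (t[~ep.to_numpy()] > 12).mean())
    for site, (s_ep, s_gp) in surv.items():
        assert s_ep < s_gp  # EP patients die sooner everywhere
    assert surv["lung"][0] < surv["colorectal"][0] < surv["prostate"][0]


def test_true_effect_curve_monotone_months():
    cfg = site_preset("colorectal", n_patients=100, seed=1)
    curve = true_effect_curve(cfg, [6, 12, 36, 60], n_oracle=20_000)
    assert list(curve["month"]) == [6, 12, 36, 60]
    # intensity savings accumulate; survival costs accumulate
    assert curve["survival_effect"].is_monotonic_increasing
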