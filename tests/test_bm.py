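import numpy as np
import pandas as pd
import pytest

from reroutecost.bm import (AlignmentError, GridError, bootstrap_curves,
                            build_grid, decompose_effect,
                            expected_cumulative_cost, fit_bm,
                            prediag_cost_effect)
from reroutecost.simulate import (CostParams, SimulationConfig,
                                  simulate_cohort)

from conftest import constant_cost_table, make_cohort, make_patients


# ---------------------------------------------------------------------------
# interval grid

@pytest.mark.parametrize("horizon,scheme,expected", [
    (60, "monthly", 60),
    (36, "monthly", 36),
    (36, "monthly12_then_quarterly", 20),
    (60, "monthly12_then_quarterly", 28),
])
def test_grid_interval_counts(horizon, scheme, expected):
    grid = build_grid(horizon, scheme)
    assert len(grid) == expected
    assert grid.boundaries[0] == 0 and grid.horizon == horizon


def test_grid_rejects_unsupported_horizon():
    with pytest.raises(GridError):
        build_grid(48, "monthly")


# ---------------------------------------------------------------------------
# degenerate and closed-form fits

def immortal_cohort(n=12, monthly_cost=250.0):
    patients = make_patients([60.0] * n, [0] * n, ["EP", "GPTWW"] * (n // 2))
    costs = constant_cost_table(patients, monthly_cost)
    return make_cohort(patients, costs)


def test_no_deaths_gives_zero_hazard_and_empirical_means():
    cohort = immortal_cohort()
    grid = build_grid(60, "monthly")
    fit = fit_bm(cohort, grid, covariates=())
    X = fit.design.matrix(cohort.patients)
    for j, part in enumerate(fit.parts):
        assert part.hazard is None
        assert np.allclose(fit.hazard(j, X), 0.0)
        assert np.allclose(part.survivor_cost.predict(X), 250.0)


def test_constant_cost_cohort_recovers_c_times_upto():
    cohort = immortal_cohort(monthly_cost=100.0)
    grid = build_grid(60, "monthly")
    fit = fit_bm(cohort, grid, covariates=())
    for upto in (12, 36, 60):
        for route in ("EP", "GPTWW"):
            mu = expected_cumulative_cost(fit, route, upto, cohort.patients)
            assert mu == pytest.approx(100.0 * upto, abs=1e-8)


def test_all_zero_costs_give_zero_everywhere():
    patients = make_patients([60.0] * 10, [0] * 10, ["EP", "GPTWW"] * 5)
    cohort = make_cohort(patients)
    fit = fit_bm(cohort, build_grid(60, "monthly"), covariates=())
    assert expected_cumulative_cost(fit, "EP", 60, cohort.patients) == 0.0


def test_saturated_intercept_hazard_is_death_fraction():
    # 10 at risk in month (0,1], 5 die in it, the rest live to the horizon
    tte = [0.5] * 5 + [60.0] * 5
    patients = make_patients(tte, [1] * 5 + [0] * 5, ["EP"] * 10)
    cohort = make_cohort(patients)
    fit = fit_bm(cohort, build_grid(60, "monthly"), covariates=(),
                 min_decedents=1)
    X = fit.design.matrix(patients)
    np.testing.assert_allclose(fit.hazard(0, X), 0.5)
    assert fit.parts[0].n_at_risk == 10 and fit.parts[0].n_decedents == 5


def test_upto_must_align_with_grid():
    cohort = immortal_cohort()
    fit = fit_bm(cohort, build_grid(60, "monthly12_then_quarterly"),
                 covariates=())
    with pytest.raises(AlignmentError):
        expected_cumulative_cost(fit, "EP", 13, cohort.patients)


def test_uncensored_estimator_equals_empirical_mean(uncensored_cohort30):
    cohort = uncensored_cohort30
    fit = fit_bm(cohort, build_grid(60, "monthly"), covariates=(),
                 min_decedents=1)
    for route in ("EP", "GPTWW"):
        arm = (cohort.patients["route"] == route).to_numpy()
        empirical = cohort.interval_costs(0, 60)[arm].mean()
        estimated = expected_cumulative_cost(fit, route, 60, cohort.patients)
        assert estimated == pytest.approx(empirical, rel=1e-12, abs=1e-8)


def test_fitted_hazards_match_weibull_closed_form():
    # k = 1, lambda = 20, both arms identical, no censoring before horizon
    n = 10_000
    cfg = SimulationConfig(n_patients=n, seed=13, weibull_shape=1.0,
                           weibull_scale_ep=20.0, aft_route_factor=1.0,
                           covariate_coefs_survival={},
                           entry_window_months=1.0, admin_cutoff_month=1000.0)
    cohort = simulate_cohort(cfg)
    fit = fit_bm(cohort, build_grid(60, "monthly"), covariates=())
    X = fit.design.matrix(cohort.patients)
    true_h = 1.0 - np.exp(-1.0 / 20.0)  # exponential: constant interval hazard
    for j in range(12):
        n_risk = fit.parts[j].n_at_risk
        se = np.sqrt(true_h * (1 - true_h) / n_risk)
        assert abs(fit.hazard(j, X).mean() - true_h) < 3 * se


# ---------------------------------------------------------------------------
# decomposition

class _Const:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


class _RouteProb:
    """Hazard that reacts only to the route column of the design."""

    def __init__(self, p_ep, p_gp):
        self.p_ep, self.p_gp = p_ep, p_gp

    def predict(self, X):
        return np.where(X[:, 1] > 0, self.p_gp, self.p_ep)


def test_route_free_cost_models_give_zero_intensity_effect():
    cohort = immortal_cohort()
    fit = fit_bm(cohort, build_grid(60, "monthly12_then_quarterly"),
                 covariates=())
    for part in fit.parts:  # different hazards, identical cost models
        part.hazard = _RouteProb(0.10, 0.02)
        part.decedent_cost = _Const(900.0)
        part.survivor_cost = _Const(300.0)
    curves = decompose_effect(fit, cohort.patients)
    np.testing.assert_allclose(curves.intensity, 0.0, atol=1e-10)
    assert curves.total[-1] > 0  # survival channel alone drives the effect


def test_route_free_hazards_give_zero_survival_effect():
    cohort = immortal_cohort()
    fit = fit_bm(cohort, build_grid(60, "monthly12_then_quarterly"),
                 covariates=())
    for part in fit.parts:  # identical hazards, route-dependent costs
        part.hazard = _RouteProb(0.05, 0.05)
        part.decedent_cost = _RouteProb(1500.0, 900.0)
        part.survivor_cost = _RouteProb(500.0, 300.0)
    curves = decompose_effect(fit, cohort.patients)
    np.testing.assert_allclose(curves.survival, 0.0, atol=1e-10)
    assert curves.total[-1] < 0


def test_additivity_exact_on_fitted_curves(recovery_setup):
    cfg, cohort, _ = recovery_setup
    fit = fit_bm(cohort, build_grid(60, "monthly12_then_quarterly"),
                 covariates=("age", "imd_income"))
    curves = decompose_effect(fit, cohort.patients)
    np.testing.assert_allclose(curves.total,
                               curves.survival + curves.intensity,
                               rtol=0, atol=1e-9)


# ---------------------------------------------------------------------------
# pre-diagnosis contrast

def test_prediag_effect_recovers_known_difference():
    cp = CostParams(predx_mean_ep=100.0, predx_mean_gp=55.0)
    cfg = SimulationConfig(n_patients=20_000, seed=17, cost_params=cp,
                           confounding_coefs={})
    cohort = simulate_cohort(cfg)
    est = prediag_cost_effect(cohort, covariates=())
    y = cohort.interval_costs(-12, 0)
    ep = (cohort.patients["route"] == "EP").to_numpy()
    se = np.sqrt(y[ep].var() / ep.sum() + y[~ep].var() / (~ep).sum())
    assert abs(est - (-540.0)) < 3 * se
    assert est < 0  # EP patients cost more pre-diagnosis by construction


def test_prediag_requires_prediagnosis_months():
    patients = make_patients([60.0] * 4, [0] * 4, ["EP", "GPTWW"] * 2)
    cohort = make_cohort(patients, constant_cost_table(patients, 10.0))
    from reroutecost.bm import EstimationError
    with pytest.raises(EstimationError):
        prediag_cost_effect(cohort)


# ---------------------------------------------------------------------------
# bootstrap

def _null_cohort(n, seed):
    cp = CostParams(route_intensity_ratio=1.0, predx_mean_ep=80.0,
                    predx_mean_gp=80.0, baseline_mean=400.0)
    cfg = SimulationConfig(n_patients=n, seed=seed, site="lung",
                           aft_route_factor=1.0, weibull_scale_ep=10.0,
                           cost_params=cp, confounding_coefs={},
                           entry_window_months=12.0, admin_cutoff_month=40.0)
    return simulate_cohort(cfg)


def test_bootstrap_bands_are_seed_deterministic():
    cohort = _null_cohort(150, seed=21)
    grid = build_grid(36, "monthly12_then_quarterly")
    a = bootstrap_curves(cohort, grid, n_reps=2, seed=5)
    b = bootstrap_curves(cohort, grid, n_reps=2, seed=5)
    np.testing.assert_array_equal(a.lo, b.lo)
    np.testing.assert_array_equal(a.hi, b.hi)


def test_bootstrap_band_covers_zero_under_the_null():
    cohort = _null_cohort(400, seed=22)
    grid = build_grid(36, "monthly12_then_quarterly")
    curves = bootstrap_curves(cohort, grid, n_reps=60, seed=1)
    h = -1
    assert curves.lo[h] <= 0.0 <= curves.hi[h]


def test_bootstrap_band_narrows_with_sample_size():
    grid = build_grid(36, "monthly12_then_quarterly")
    widths = []
    for n in (300, 1200):
        curves = bootstrap_curves(_null_cohort(n, seed=23), grid,
                                  n_reps=40, seed=2)
        widths.append(curves.hi[-1] - curves.lo[-1])
    assert widths[1] < widths[0]


# ---------------------------------------------------------------------------
# censoring robustness

def test_censoring_leaves_estimate_within_sampling_error():
    cp = CostParams(route_intensity_ratio=1.2, baseline_mean=500.0)
    base = dict(n_patients=4000, seed=29, weibull_scale_ep=18.0,
                aft_route_factor=2.2, cost_params=cp)
    uncensored = simulate_cohort(SimulationConfig(
        **base, entry_window_months=1.0, admin_cutoff_month=1000.0))
    censored = simulate_cohort(SimulationConfig(
        **base, entry_window_months=42.0, admin_cutoff_month=72.0))
    assert (censored.patients["event"] == 0).mean() > 0.2
    grid = build_grid(60, "monthly12_then_quarterly")
    deltas = []
    for cohort in (uncensored, censored):
        fit = fit_bm(cohort, grid, covariates=())
        deltas.append(decompose_effect(fit, cohort.patients).at(60)["total"])
    y = uncensored.interval_costs(0, 60)
    ep = (uncensored.patients["route"] == "EP").to_numpy()
    se = np.sqrt(y[ep].var() / ep.sum() + y[~ep].var() / (~ep).sum())
    assert abs(deltas[0] - deltas[1]) < 3 * se
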