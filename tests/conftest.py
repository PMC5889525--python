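import numpy as np
import pandas as pd
import pytest

from reroutecost.cohort import CCI_COLUMNS, CohortTable, horizon_for_site
from reroutecost.simulate import (CostParams, SimulationConfig,
                                  simulate_cohort, true_effects)


def make_patients(tte, event, route, site="colorectal", sex=None, age=70.0,
                  **overrides):
    """Schema-complete patient table from the columns tests care about."""
    n = len(tte)
    if sex is None:
        sex = "M" if site == "prostate" else "F"
    df = pd.DataFrame({
        "patient_id": [f"T{i:04d}" for i in range(n)],
        "site": site,
        "route": route,
        "age": age,
        "sex": sex,
        "imd_income": 0.1,
        "region": "R1",
        "n_codiag": 0,
        "surgery_12m": 0,
        "time_to_event": np.asarray(tte, float),
        "event": np.asarray(event, int),
    })
    for col in CCI_COLUMNS:
        df[col] = 0
    for key, val in overrides.items():
        df[key] = val
    return df


def make_cohort(patients, costs=None, validate=True):
    if costs is None:
        costs = pd.DataFrame({"patient_id": pd.Series(dtype=object),
                              "month_index": pd.Series(dtype=int),
                              "cost_gbp": pd.Series(dtype=float)})
    horizon = horizon_for_site(patients["site"].iloc[0]) if len(patients) else 60
    return CohortTable(patients=patients, costs=costs, horizon_months=horizon,
                       validate_on_init=validate)


def constant_cost_table(patients, monthly_cost, horizon=60):
    """One cost row per alive month per patient, all equal to monthly_cost."""
    rows = []
    for pid, tte in zip(patients["patient_id"], patients["time_to_event"]):
        for m in range(int(np.ceil(min(tte, horizon)))):
            if m < tte:
                rows.append((pid, m, float(monthly_cost)))
    return pd.DataFrame(rows, columns=["patient_id", "month_index", "cost_gbp"])


@pytest.fixture(scope="session")
def uncensored_cohort30():
    """30 patients, no censoring before the horizon, stochastic costs."""
    cfg = SimulationConfig(n_patients=30, seed=7, entry_window_months=1.0,
                           admin_cutoff_month=1000.0)
    return simulate_cohort(cfg)


RECOVERY_CONFIG = SimulationConfig(
    n_patients=10_000, site="colorectal", p_ep_base=0.32, seed=42,
    weibull_shape=1.0, weibull_scale_ep=18.0, aft_route_factor=2.5,
    cost_params=CostParams(diagnosis_spike_mean=2000.0, baseline_mean=600.0,
                           terminal_spike_mean=1500.0, predx_mean_ep=100.0,
                           predx_mean_gp=55.0, route_intensity_ratio=1.15,
                           gamma_shape=0.8, p_zero=0.35),
    entry_window_months=42.0, admin_cutoff_month=72.0)


@pytest.fixture(scope="session")
def recovery_setup():
    """Censored 10k-patient cohort with known laws plus its Monte-Carlo truth."""
    cohort = simulate_cohort(RECOVERY_CONFIG)
    oracle = true_effects(RECOVERY_CONFIG, n_oracle=200_000, seed=999)
    return RECOVERY_CONFIG, cohort, oracle
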