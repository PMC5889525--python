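"""Synthetic registry-like cancer cohorts.

Emulates the statistical structure of an English cancer-registry/hospital
linkage without any patient data: two routes to diagnosis (emergency
presentation EP vs GP/two-week-wait referral) with confounded assignment,
route-dependent Weibull accelerated-failure-time survival, staggered-entry
administrative censoring, and U-shaped monthly cost trajectories with a
diagnosis spike and a terminal spike.

The generative model
--------------------
* Covariates: age ~ N(72, 10) clipped to [18, 100]; income deprivation
  ~ Beta(2, 12); eleven Charlson flags with fixed prevalences; co-diagnoses
  ~ Poisson(2); surgery within 12 months ~ Bernoulli(0.5) independent of
  route (it is a control variable downstream, not a mediator here).
* Route: P(EP) follows a logistic model with intercept logit(p_ep_base) and
  log-odds coefficients on standardised age, deprivation and Charlson count.
* Death time: log T = log(weibull_scale_ep) + beta'z
  + 1{route=GPTWW} * log(aft_route_factor) + (1/k) * log E,  E ~ Exp(1),
  i.e. Weibull with shape ``k`` and route-accelerated scale.
* Censoring: entry uniform on [0, entry_window_months]; administrative
  censoring at admin_cutoff_month - entry (and at the follow-up horizon),
  independent of T given covariates.
* Monthly costs: unconditional mean = baseline + diagnosis spike (months
  0-2) + terminal spike (the three months preceding the latent death time,
  anchored to death even when censoring truncates observation), all
  multiplied by ``route_intensity_ratio`` for EP patients; pre-diagnosis
  months -12..-1 have route-specific means.  Draws are zero with
  probability ``p_zero`` and otherwise gamma with the configured shape, so
  the unconditional mean equals the configured mean.

Standardisation of covariates uses fixed population constants (not sample
moments), so the data-generating law does not depend on the realised sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import CCI_COLUMNS, CohortTable, horizon_for_site

# Fixed covariate-population constants used for standardisation.
AGE_MEAN, AGE_SD = 72.0, 10.0
IMD_A, IMD_B = 2.0, 12.0
IMD_MEAN = IMD_A / (IMD_A + IMD_B)
IMD_SD = float(np.sqrt(IMD_A * IMD_B / ((IMD_A + IMD_B) ** 2 * (IMD_A + IMD_B + 1))))
CCI_PREVALENCE = np.array(
    [0.08, 0.07, 0.06, 0.07, 0.05, 0.12, 0.04, 0.03, 0.03, 0.15, 0.05])
CCI_MEAN = float(CCI_PREVALENCE.sum())
CCI_SD = float(np.sqrt((CCI_PREVALENCE * (1 - CCI_PREVALENCE)).sum()))
REGIONS = tuple(f"R{i}" for i in range(1, 10))


class EmptyCohortError(ValueError):
    """Raised when a simulation is requested with no patients."""


@dataclass
class CostParams:
    """Monthly-cost law parameters (GBP, unconditional means)."""

    diagnosis_spike_mean: float = 2000.0   # added to months 0-2
    baseline_mean: float = 500.0           # every alive post-diagnosis month
    terminal_spike_mean: float = 1800.0    # added to the 3 months before death
    predx_mean_ep: float = 100.0           # months -12..-1, EP arm
    predx_mean_gp: float = 55.0            # months -12..-1, GP/TWW arm
    route_intensity_ratio: float = 1.3     # EP multiplier on post-dx means
    gamma_shape: float = 0.8               # shape of the positive-cost gamma
    p_zero: float = 0.35                   # probability of a zero-cost month

    def validate(self) -> None:
        for name in ("diagnosis_spike_mean", "baseline_mean",
                     "terminal_spike_mean", "predx_mean_ep", "predx_mean_gp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.route_intensity_ratio <= 0:
            raise ValueError("route_intensity_ratio must be > 0")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if not 0 <= self.p_zero < 1:
            raise ValueError("p_zero must be in [0, 1)")


@dataclass
class SimulationConfig:
    """Full parameterisation of a synthetic cohort."""

    n_patients: int = 2000
    site: str = "colorectal"
    p_ep_base: float = 0.3
    confounding_coefs: dict = field(
        default_factory=lambda: {"age": 0.35, "imd": 0.25, "cci": 0.4})
    weibull_shape: float = 1.0
    weibull_scale_ep: float = 17.14        # months
    aft_route_factor: float = 2.92         # GP/TWW time ratio vs EP
    covariate_coefs_survival: dict = field(
        default_factory=lambda: {"age": -0.20, "imd": -0.05, "cci": -0.15})
    cost_params: CostParams = field(default_factory=CostParams)
    entry_window_months: float = 36.0
    admin_cutoff_month: float = 72.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise EmptyCohortError("n_patients must be positive")
        if not 0 < self.p_ep_base < 1:
            raise ValueError("p_ep_base must be in (0, 1)")
        if self.weibull_shape <= 0 or self.weibull_scale_ep <= 0:
            raise ValueError("Weibull shape and scale must be > 0")
        if self.aft_route_factor <= 0:
            raise ValueError("aft_route_factor must be > 0")
        if self.admin_cutoff_month <= self.entry_window_months:
            raise ValueError("admin_cutoff_month must exceed entry_window_months")
        self.cost_params.validate()

    @property
    def horizon(self) -> int:
        return horizon_for_site(self.site)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if isinstance(d.get("cost_params"), dict):
            d["cost_params"] = CostParams(**d["cost_params"])
        return cls(**d)


def site_preset(site: str, n_patients: int = 2000, seed: int = 0) -> SimulationConfig:
    """Load the shipped per-site preset, calibrated so that arm-level
    12-month survival approximates the registry descriptive statistics
    (e.g. colorectal EP ~ 0.497, GP/TWW ~ 0.787)."""
    with resources.files("reroutecost.data").joinpath("site_presets.json").open() as fh:
        presets = json.load(fh)
    if site not in presets:
        raise KeyError(f"no preset for site {site!r}")
    cfg = SimulationConfig.from_dict(presets[site])
    cfg.n_patients = n_patients
    cfg.seed = seed
    return cfg


# ---------------------------------------------------------------------------
# covariate and survival draws

def _draw_covariates(rng: np.random.Generator, n: int, site: str) -> pd.DataFrame:
    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, n), 18.0, 100.0)
    imd = rng.beta(IMD_A, IMD_B, n)
    cci = (rng.random((n, len(CCI_PREVALENCE))) < CCI_PREVALENCE).astype(int)
    if site == "breast":
        sex = np.full(n, "F")
    elif site == "prostate":
        sex = np.full(n, "M")
    else:
        sex = np.where(rng.random(n) < 0.45, "F", "M")
    df = pd.DataFrame({
        "age": age,
        "sex": sex,
        "imd_income": imd,
        "region": rng.choice(REGIONS, n),
        "n_codiag": rng.poisson(2.0, n),
        "surgery_12m": (rng.random(n) < 0.5).astype(int),
    })
    for j, col in enumerate(CCI_COLUMNS):
        df[col] = cci[:, j]
    return df


def _standardised(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "age": (df["age"].to_numpy() - AGE_MEAN) / AGE_SD,
        "imd": (df["imd_income"].to_numpy() - IMD_MEAN) / IMD_SD,
        "cci": (df[list(CCI_COLUMNS)].sum(axis=1).to_numpy() - CCI_MEAN) / CCI_SD,
    }


def _linear(coefs: dict, z: dict[str, np.ndarray]) -> np.ndarray:
    out = np.zeros_like(z["age"])
    for key, val in coefs.items():
        out = out + val * z[key]
    return out


def _latent_death_times(cfg: SimulationConfig, z: dict, is_gp: np.ndarray,
                        log_err: np.ndarray) -> np.ndarray:
    """T = scale_ep * exp(beta'z) * factor^{GP} * E^{1/k} with log E = log_err."""
    log_t = (np.log(cfg.weibull_scale_ep)
             + _linear(cfg.covariate_coefs_survival, z)
             + is_gp * np.log(cfg.aft_route_factor)
             + log_err / cfg.weibull_shape)
    return np.exp(log_t)


def _expected_monthly_profile(T: np.ndarray, horizon: int, is_ep: np.ndarray,
                              cp: CostParams) -> np.ndarray:
    """Expected cumulative post-diagnosis cost to ``horizon`` given latent
    death time ``T`` (vectorised closed form; months are whole bins, with the
    month containing death included)."""
    alive = np.ceil(np.minimum(T, horizon)).astype(int)  # months observed
    base = cp.baseline_mean * alive
    dx = cp.diagnosis_spike_mean * np.minimum(alive, 3)
    term_start = np.clip(np.ceil(T - 3.0).astype(int), 0, alive)
    term = cp.terminal_spike_mean * (alive - term_start)
    total = base + dx + term
    return np.where(is_ep, cp.route_intensity_ratio * total, total)


def _monthly_means(months: np.ndarray, T: np.ndarray, is_ep: np.ndarray,
                   cp: CostParams) -> np.ndarray:
    """Unconditional mean for each (patient-month) pair; months >= 0 only."""
    mean = np.full(months.shape, cp.baseline_mean, dtype=float)
    mean[months < 3] += cp.diagnosis_spike_mean
    mean[months >= T - 3.0] += cp.terminal_spike_mean
    mean[is_ep] *= cp.route_intensity_ratio
    return mean


def _zero_inflated_gamma(rng: np.random.Generator, mean: np.ndarray,
                         shape: float, p_zero: float) -> np.ndarray:
    """Draws with unconditional mean ``mean``: zero w.p. ``p_zero``, else
    gamma with mean ``mean / (1 - p_zero)``."""
    positive = rng.random(mean.shape) >= p_zero
    draws = rng.gamma(shape, np.maximum(mean, 1e-12) / ((1 - p_zero) * shape))
    out = np.where(positive, draws, 0.0)
    out[mean == 0] = 0.0
    return out


def simulate_cohort(config: SimulationConfig, return_latents: bool = False):
    """Generate a cohort under ``config``; identical seeds give identical output.

    Returns a :class:`~reroutecost.cohort.CohortTable`, or a
    ``(cohort, latents)`` pair when ``return_latents`` is true; ``latents``
    carries the latent death time, the censoring time, and the log survival
    error, which parameter-recovery tests use.
    """
    config.validate()
    n, horizon = config.n_patients, config.horizon
    rng = np.random.default_rng(config.seed)

    pat = _draw_covariates(rng, n, config.site)
    pat.insert(0, "patient_id", [f"P{i:06d}" for i in range(n)])
    pat.insert(1, "site", config.site)
    z = _standardised(pat)

    # confounded route assignment
    logit_p = (np.log(config.p_ep_base / (1 - config.p_ep_base))
               + _linear(config.confounding_coefs, z))
    p_ep = 1.0 / (1.0 + np.exp(-logit_p))
    is_ep = rng.random(n) < p_ep
    pat.insert(2, "route", np.where(is_ep, "EP", "GPTWW"))

    # survival and censoring
    log_err = np.log(rng.exponential(1.0, n))
    T = _latent_death_times(config, z, (~is_ep).astype(float), log_err)
    entry = rng.uniform(0.0, config.entry_window_months, n)
    censor = np.minimum(config.admin_cutoff_month - entry, float(horizon))
    tte = np.minimum(T, censor)
    tte = np.maximum(tte, 1e-6)
    event = (T <= censor).astype(int)
    pat["time_to_event"] = tte
    pat["event"] = event

    # post-diagnosis monthly costs: months m with m < tte
    n_months = np.ceil(tte).astype(int)
    idx = np.repeat(np.arange(n), n_months)
    months = np.concatenate([np.arange(k) for k in n_months]) \
        if n_months.sum() else np.array([], dtype=int)
    means = _monthly_means(months, T[idx], is_ep[idx], config.cost_params)
    post_cost = _zero_inflated_gamma(rng, means, config.cost_params.gamma_shape,
                                     config.cost_params.p_zero)

    # pre-diagnosis months -12..-1
    pre_idx = np.repeat(np.arange(n), 12)
    pre_months = np.tile(np.arange(-12, 0), n)
    pre_means = np.where(is_ep[pre_idx], config.cost_params.predx_mean_ep,
                         config.cost_params.predx_mean_gp).astype(float)
    pre_cost = _zero_inflated_gamma(rng, pre_means, config.cost_params.gamma_shape,
                                    config.cost_params.p_zero)

    pid = pat["patient_id"].to_numpy()
    costs = pd.DataFrame({
        "patient_id": np.concatenate([pid[pre_idx], pid[idx]]),
        "month_index": np.concatenate([pre_months, months]),
        "cost_gbp": np.concatenate([pre_cost, post_cost]),
    })
    costs = costs[costs["cost_gbp"] > 0].reset_index(drop=True)

    cohort = CohortTable(patients=pat, costs=costs, horizon_months=horizon)
    if return_latents:
        latents = pd.DataFrame({"patient_id": pid, "death_time": T,
                                "censor_time": censor, "log_err": log_err})
        return cohort, latents
    return cohort


# ---------------------------------------------------------------------------
# Monte-Carlo ground truth

def _oracle_population(config: SimulationConfig, n_oracle: int, seed: int):
    rng = np.random.default_rng(seed)
    pat = _draw_covariates(rng, n_oracle, config.site)
    z = _standardised(pat)
    log_err = np.log(rng.exponential(1.0, n_oracle))
    t_ep = _latent_death_times(config, z, np.zeros(n_oracle), log_err)
    t_gp = t_ep * config.aft_route_factor
    return t_ep, t_gp


def true_effects(config: SimulationConfig, horizon: int | None = None,
                 n_oracle: int = 100_000, seed: int = 12345) -> dict:
    """Monte-Carlo ground truth for the route effect on post-diagnosis costs.

    Simulates an uncensored population under each route with common random
    numbers (covariates and survival errors shared between arms) and returns

    * ``total_cost_effect`` — E[cost | GP/TWW] - E[cost | EP], cumulative to
      ``horizon`` (post-diagnosis months only; the pre-diagnosis contrast is
      the separate closed form 12*(predx_mean_gp - predx_mean_ep));
    * ``intensity_effect`` — the cost difference holding EP survival fixed
      and swapping in the GP/TWW cost law;
    * ``survival_effect`` — the residual, so the decomposition is additive
      by construction;
    * ``delta_surv_prob`` — S_GP(horizon) - S_EP(horizon);
    * ``yls`` — restricted years of life saved, [E min(T_GP, h) -
      E min(T_EP, h)] / 12.
    """
    config.validate()
    h = config.horizon if horizon is None else horizon
    cp = config.cost_params
    t_ep, t_gp = _oracle_population(config, n_oracle, seed)
    ones = np.ones(n_oracle, dtype=bool)
    mu_ep = _expected_monthly_profile(t_ep, h, ones, cp).mean()
    mu_gp = _expected_monthly_profile(t_gp, h, ~ones, cp).mean()
    mu_mix = _expected_monthly_profile(t_ep, h, ~ones, cp).mean()  # EP survival, GP cost law
    total = mu_gp - mu_ep
    intensity = mu_mix - mu_ep
    return {
        "total_cost_effect": float(total),
        "survival_effect": float(total - intensity),
        "intensity_effect": float(intensity),
        "delta_surv_prob": float((t_gp > h).mean() - (t_ep > h).mean()),
        "yls": float((np.minimum(t_gp, h).mean() - np.minimum(t_ep, h).mean()) / 12.0),
    }


def true_effect_curve(config: SimulationConfig, months,
                      n_oracle: int = 100_000, seed: int = 12345) -> pd.DataFrame:
    """Ground-truth cumulative effect curves evaluated at several months."""
    config.validate()
    cp = config.cost_params
    t_ep, t_gp = _oracle_population(config, n_oracle, seed)
    ones = np.ones(n_oracle, dtype=bool)
    rows = []
    for m in months:
        mu_ep = _expected_monthly_profile(t_ep, m, ones, cp).mean()
        mu_gp = _expected_monthly_profile(t_gp, m, ~ones, cp).mean()
        mu_mix = _expected_monthly_profile(t_ep, m, ~ones, cp).mean()
        rows.append({"month": m, "total_effect": mu_gp - mu_ep,
                     "intensity_effect": mu_mix - mu_ep,
                     "survival_effect": (mu_gp - mu_ep) - (mu_mix - mu_ep)})
    return pd.DataFrame(rows)
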