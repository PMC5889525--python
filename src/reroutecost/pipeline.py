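"""End-to-end pipeline: simulate -> cost estimator -> survival -> ledger -> policy.

`run_pipeline` chains the stages on a (typically synthetic) cohort and
writes the decomposition curves CSV, the ledger JSON, the policy JSON, a
cumulative-effect figure, and a run log with the configuration hash, stage
timings and package versions, so reruns with the same configuration are
reproducible.  `verify_tables` rebuilds every derived value of the published
per-patient ledger and policy scale-up from their printed components, which
needs no external data.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .aft import fit_weibull_aft, restricted_mean_survival, survival_prob, \
    years_of_life_saved
from .bm import bootstrap_curves, build_grid, decompose_effect, fit_bm, \
    prediag_cost_effect
from .cohort import CohortTable, add_cci_count, read_cohort, write_cohort
from .ledger import ReferralEconomics, build_ledger, load_printed_table2, \
    load_printed_table3, rebuild_from_printed, economics_from_printed, \
    SiteLedger, round_gbp
from .policy import benchmark_share, rerouted_counts, scale_policy, \
    synthetic_ccg_table
from .simulate import SimulationConfig, simulate_cohort, site_preset

DEFAULT_COVARIATES = ("age", "imd_income", "cci_count", "n_codiag",
                      "surgery_12m")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str
    site: str = "colorectal"
    # either a simulation config, or paths to patient/cost CSVs
    sim: SimulationConfig | None = None
    patients_path: str | None = None
    costs_path: str | None = None
    grid_scheme: str = "monthly12_then_quarterly"
    covariates: tuple = DEFAULT_COVARIATES
    bootstrap_reps: int = 0
    econ: ReferralEconomics | None = None
    seed: int = 0

    def digest(self) -> str:
        d = asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_cohort(config: RunConfig) -> CohortTable:
    if config.sim is not None:
        return simulate_cohort(config.sim)
    if config.patients_path and config.costs_path:
        return read_cohort(config.patients_path, config.costs_path)
    raise ValueError("RunConfig needs either sim or patient/cost paths")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline and write all artifacts under ``config.out_dir``.

    Returns a bundle with the curves, ledger, policy entry and run log.  Any
    stage failure raises with the stage named; artifacts written before the
    failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"config_hash": config.digest(), "seed": config.seed,
           "versions": {"reroutecost": __version__, "numpy": np.__version__},
           "stages": {}}
    bundle = {"log": log}

    def stage(name):
        t0 = time.perf_counter()

        def done():
            log["stages"][name] = round(time.perf_counter() - t0, 3)
        return done

    try:
        tick = stage("cohort")
        cohort = _load_cohort(config)
        cohort.patients = add_cci_count(cohort.patients)
        horizon = cohort.horizon_months
        tick()

        tick = stage("fit-bm")
        grid = build_grid(horizon, config.grid_scheme)
        if config.bootstrap_reps >= 2:
            curves = bootstrap_curves(cohort, grid, config.covariates,
                                      n_reps=config.bootstrap_reps,
                                      seed=config.seed)
        else:
            curves = decompose_effect(fit_bm(cohort, grid, config.covariates),
                                      cohort.patients)
        cdf = curves.to_frame()
        cdf.insert(0, "config_hash", config.digest())
        cdf.to_csv(out / "curves.csv", index=False, float_format="%.12g")
        bundle["curves"] = curves
        tick()

        tick = stage("fit-survival")
        aft = fit_weibull_aft(cohort, covariates=[c for c in config.covariates
                                                  if c != "region"])
        surv = {
            "delta_surv": survival_prob(aft, "GPTWW", horizon, cohort.patients)
            - survival_prob(aft, "EP", horizon, cohort.patients),
            "yls": years_of_life_saved(aft, horizon, cohort.patients),
            "route_time_ratio": aft.route_time_ratio,
        }
        bundle["aft"], bundle["surv"] = aft, surv
        tick()

        tick = stage("ledger")
        econ = config.econ or economics_from_printed(
            load_printed_table2()[config.site])
        prediag = prediag_cost_effect(cohort, config.covariates)
        ledger = build_ledger(econ, prediag, curves, surv, horizon)
        payload = {"config_hash": config.digest(), **ledger.report()}
        (out / "ledger.json").write_text(json.dumps(payload, indent=2))
        bundle["ledger"] = ledger
        tick()

        tick = stage("policy")
        ccg = synthetic_ccg_table(seed=config.seed)
        bench = benchmark_share(ccg)
        rerouted = rerouted_counts(ccg, bench, config.site)
        entry = scale_policy(ledger, econ, rerouted)
        payload = {"config_hash": config.digest(),
                   "benchmark_share": bench, **entry.report()}
        (out / "policy.json").write_text(json.dumps(payload, indent=2))
        bundle["policy"] = entry
        tick()

        tick = stage("plot")
        plot_curves(curves, out / "fig_cumulative_effect.png",
                    title=f"{config.site}: cumulative cost effect of rerouting")
        tick()
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {len(log['stages'])} failed: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return bundle


def plot_curves(curves, path, title="Cumulative cost effect of rerouting"):
    """Cumulative total/survival/intensity effect figure (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(curves.months, curves.total, "k-", lw=2, label="total effect")
    ax.plot(curves.months, curves.survival, "b-", label="survival effect")
    ax.plot(curves.months, curves.intensity, "r-", label="intensity effect")
    if curves.lo is not None:
        ax.fill_between(curves.months, curves.lo, curves.hi, color="grey",
                        alpha=0.3, label="95% bootstrap band")
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("months since diagnosis")
    ax.set_ylabel("GP/TWW minus EP, cumulative GBP per patient")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def verify_tables() -> dict:
    """Rebuild the published per-patient ledger and policy aggregates from
    their printed components; returns recomputed and printed values side by
    side per site.  Pure arithmetic — runs offline in well under a second."""
    t2, t3 = load_printed_table2(), load_printed_table3()
    out = {}
    for site, entry in t2.items():
        rebuilt = rebuild_from_printed(entry)
        # scale the printed totals themselves: fold the sub-pound rounding
        # of the printed components into the intensity terms so the ledger's
        # totals equal the published rows exactly
        led = SiteLedger(a=entry["a"], b=entry["b"], c1=entry["c"],
                         d1=entry["total_1yr"] - entry["a"] - entry["b"]
                         - entry["c"],
                         C5=entry["C"],
                         D5=entry["total_5yr"] - entry["a"] - entry["b"]
                         - entry["C"],
                         delta_surv=entry["delta_surv"], yls=entry["yls"],
                         horizon=entry["horizon"])
        pol = scale_policy(led, economics_from_printed(entry),
                           t3[site]["rerouted"])
        out[site] = {
            "ledger_rebuilt": rebuilt,
            "ledger_printed": {"a": entry["a"], "total_1yr": entry["total_1yr"],
                               "total_h": entry["total_5yr"],
                               "cost_per_survivor": entry["cost_per_survivor"],
                               "cost_per_yls": entry["cost_per_yls"]},
            "policy_rebuilt": {"total_cost_1yr": round_gbp(pol.total_cost_1yr),
                               "total_cost_horizon": round_gbp(pol.total_cost_horizon),
                               "survivors": pol.survivors_at_horizon,
                               "yls_total": pol.yls_total},
            "policy_printed": {"total_cost_1yr": t3[site]["total_1yr"],
                               "total_cost_horizon": t3[site]["total_5yr"],
                               "survivors": t3[site]["survivors"],
                               "yls_total": t3[site]["yls_total"]},
        }
    return out
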