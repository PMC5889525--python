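"""Referral economics: from estimator outputs to cost per rerouted patient.

A two-week-wait (TWW) referral pathway converts only a fraction r of
referrals into a positive cancer diagnosis; the diagnostic tests of the
(1 - r)/r negative referrals per positive case are a cost of achieving one
extra GP/TWW diagnosis.  The site ledger aggregates, per rerouted patient,

    a  non-conversion cost per converted case, c_test * (1 - r) / r
    b  pre-diagnosis cost variation (12 months before diagnosis)
    c, d  survival / intensity cost variation 1 year post diagnosis
    C, D  survival / intensity cost variation at the follow-up horizon
          (5 years, 3 for lung)

into totals a+b+c+d (1 year) and a+b+C+D (horizon), and divides the horizon
total by the survival-probability gain and by the years of life saved to get
cost per additional survivor and cost per year of life saved.  All
quantities are GBP at 2010 prices, undiscounted; amounts are rounded
half-away-from-zero to the nearest pound only at reporting time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

from .bm import CostEffectCurves

__all__ = ["ReferralEconomics", "SiteLedger", "cost_per_converted_case",
           "build_ledger", "round_gbp", "load_printed_table2",
           "load_printed_table3", "rebuild_from_printed",
           "economics_from_printed"]


def round_gbp(x: float) -> int:
    """Round to the nearest pound, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ReferralEconomics:
    """Conversion rate r in (0, 1] and cost per diagnostic test (GBP)."""

    conversion_rate: float
    cost_per_test: float

    def __post_init__(self):
        if not 0 < self.conversion_rate <= 1:
            raise ValueError("conversion_rate must be in (0, 1]")
        if self.cost_per_test < 0:
            raise ValueError("cost_per_test must be >= 0")


def cost_per_converted_case(econ: ReferralEconomics) -> float:
    """Cost of the negative tests incurred per positive diagnosis,
    c * (1 - r) / r."""
    r = econ.conversion_rate
    return econ.cost_per_test * (1.0 - r) / r


@dataclass
class SiteLedger:
    """The per-site cost ledger; derived totals follow the identities
    total_1yr = a + b + c1 + d1 and total_h = a + b + C5 + D5 exactly."""

    a: float            # non-conversion cost per converted case
    b: float            # pre-diagnosis cost variation
    c1: float           # survival cost variation, 1 year post
    d1: float           # intensity cost variation, 1 year post
    C5: float           # survival cost variation at horizon
    D5: float           # intensity cost variation at horizon
    delta_surv: float   # survival-probability difference at horizon
    yls: float          # years of life saved per rerouted patient
    horizon: int = 60

    @property
    def total_1yr(self) -> float:
        return self.a + self.b + self.c1 + self.d1

    @property
    def total_h(self) -> float:
        return self.a + self.b + self.C5 + self.D5

    @property
    def cost_per_survivor(self) -> float | None:
        """total_h per additional survivor; None when delta_surv == 0."""
        if self.delta_surv == 0:
            return None
        return self.total_h / self.delta_surv

    @property
    def cost_per_yls(self) -> float | None:
        """total_h per year of life saved; None when yls == 0."""
        if self.yls == 0:
            return None
        return self.total_h / self.yls

    def report(self) -> dict:
        """Rounded-to-the-pound reporting view (internal arithmetic unrounded)."""
        out = {"a": round_gbp(self.a), "b": round_gbp(self.b),
               "c": round_gbp(self.c1), "d": round_gbp(self.d1),
               "total_1yr": round_gbp(self.total_1yr),
               "C": round_gbp(self.C5), "D": round_gbp(self.D5),
               "total_h": round_gbp(self.total_h),
               "delta_surv": self.delta_surv, "yls": self.yls,
               "horizon": self.horizon}
        out["cost_per_survivor"] = (None if self.cost_per_survivor is None
                                    else round_gbp(self.cost_per_survivor))
        out["cost_per_yls"] = (None if self.cost_per_yls is None
                               else round_gbp(self.cost_per_yls))
        return out


def build_ledger(econ: ReferralEconomics, prediag_effect: float,
                 bm_curves: CostEffectCurves, surv: dict,
                 horizon: int = 60) -> SiteLedger:
    """Assemble a :class:`SiteLedger` from the pipeline stages.

    ``surv`` must carry ``delta_surv`` and ``yls``.  The decomposition
    curves must be defined at month 12 and at ``horizon``.
    """
    at12 = bm_curves.at(12)
    ath = bm_curves.at(horizon)
    return SiteLedger(a=cost_per_converted_case(econ), b=prediag_effect,
                      c1=at12["survival"], d1=at12["intensity"],
                      C5=ath["survival"], D5=ath["intensity"],
                      delta_surv=float(surv["delta_surv"]),
                      yls=float(surv["yls"]), horizon=horizon)


# ---------------------------------------------------------------------------
# printed-table fixtures and verification arithmetic

def _load(name: str) -> dict:
    with resources.files("reroutecost.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_printed_table2() -> dict:
    """Published per-site ledger components and derived rows."""
    return _load("table2_printed.json")


def load_printed_table3() -> dict:
    """Published policy scale-up rows (rerouted counts and aggregates)."""
    return _load("table3_printed.json")


def economics_from_printed(entry: dict) -> ReferralEconomics:
    """Referral economics with the conversion rate back-solved from the
    printed non-conversion cost, r = c_test / (a + c_test).

    Published conversion rates are rounded to three decimals; the unrounded
    rate implied by the printed (a) row (e.g. 0.0435 rather than 0.043 for
    colorectal) reproduces the component chain exactly.
    """
    c = entry["cost_per_test"]
    return ReferralEconomics(conversion_rate=c / (entry["a"] + c),
                             cost_per_test=c)


def rebuild_from_printed(entry: dict) -> dict:
    """Recompute every derived ledger row from printed components.

    Totals are rebuilt from the printed (a, b, c, d, C, D); the per-survivor
    and per-year-of-life ratios are rebuilt from the printed totals, since
    those are the intermediates the published ratios round from.
    """
    econ = economics_from_printed(entry)
    a = cost_per_converted_case(econ)
    led = SiteLedger(a=a, b=entry["b"], c1=entry["c"], d1=entry["d"],
                     C5=entry["C"], D5=entry["D"],
                     delta_surv=entry["delta_surv"], yls=entry["yls"],
                     horizon=entry["horizon"])
    return {
        "a": round_gbp(led.a),
        "total_1yr": round_gbp(led.total_1yr),
        "total_h": round_gbp(led.total_h),
        "cost_per_survivor": round_gbp(entry["total_5yr"] / entry["delta_surv"]),
        "cost_per_yls": round_gbp(entry["total_5yr"] / entry["yls"]),
    }
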