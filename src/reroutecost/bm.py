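"""Three-part censored-cost estimator and the survival/intensity decomposition.

The estimator partitions follow-up into intervals and, in each interval,
fits three risk-adjusted models among patients still at risk and observed
through the interval:

1. a probit model for the probability of dying within the interval,
2. a cost model for patients who die in the interval (decedents), and
3. a cost model for patients who survive the interval.

Expected cumulative cost to a horizon, for a covariate row x with the route
to diagnosis forced, is then

    mu(m; x) = sum_{j : end(j) <= m} S_{j-1}(x) [ h_j(x) muD_j(x)
                                                  + (1 - h_j(x)) muS_j(x) ],
    S_{j-1}(x) = prod_{k<j} (1 - h_k(x)),

averaged over a common population (recycled predictions).  Censoring is
assumed random given covariates: patients censored before an interval's end
are simply excluded from that interval's risk set, while decedents in the
interval are retained.

The route effect on cumulative cost, Delta(m) = mu_GPTWW(m) - mu_EP(m), is
decomposed with EP as baseline: the intensity effect re-weights GP/TWW cost
models by EP survival components, and the survival effect is the residual,
so the two channels add up to the total exactly.

Cost models are hurdle models: a binary part for any cost in the interval
times a gamma GLM (log link) for positive costs.  Saturated designs (at most
as many distinct covariate rows as parameters, e.g. intercept-only or
intercept + route) are fitted in closed form as group means, which makes the
estimator exact on such designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable

__all__ = [
    "IntervalGrid", "BMFit", "CostEffectCurves", "build_grid", "fit_bm",
    "expected_cumulative_cost", "decompose_effect", "bootstrap_curves",
    "prediag_cost_effect", "Design", "EstimationError", "GridError",
    "AlignmentError",
]


class GridError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class IntervalGrid:
    """Strictly increasing month boundaries from 0 to the horizon."""

    boundaries: tuple

    def __post_init__(self):
        b = self.boundaries
        if len(b) < 2 or b[0] != 0 or any(x >= y for x, y in zip(b, b[1:])):
            raise GridError(f"invalid boundaries {b}")

    @property
    def horizon(self) -> int:
        return self.boundaries[-1]

    @property
    def intervals(self):
        return list(zip(self.boundaries[:-1], self.boundaries[1:]))

    def __len__(self):
        return len(self.boundaries) - 1


def build_grid(horizon: int, scheme: str = "monthly12_then_quarterly") -> IntervalGrid:
    """Monthly intervals, or monthly for the first year then quarterly.

    The mixed scheme is the default because per-interval decedent cost
    models need events: 20 intervals for a 36-month horizon, 28 for 60.
    """
    if horizon not in (36, 60):
        raise GridError(f"unsupported horizon {horizon}; expected 36 or 60")
    if scheme == "monthly":
        bounds = tuple(range(horizon + 1))
    elif scheme == "monthly12_then_quarterly":
        bounds = tuple(range(13)) + tuple(range(15, horizon + 1, 3))
    else:
        raise GridError(f"unknown grid scheme {scheme!r}")
    return IntervalGrid(bounds)


# ---------------------------------------------------------------------------
# design matrices

class Design:
    """Covariate design: intercept, GP/TWW route indicator, then covariates.

    Categorical columns (dtype object) are dummy-coded against their first
    observed level; levels are frozen at fit time so predictions align.
    """

    def __init__(self, columns=()):
        self.columns = tuple(columns)
        self._levels: dict[str, list] = {}
        self._fitted = False

    def fit(self, patients: pd.DataFrame) -> "Design":
        self._levels = {}
        for col in self.columns:
            if patients[col].dtype == object:
                self._levels[col] = sorted(patients[col].unique())
        self._fitted = True
        return self

    @property
    def names(self):
        out = ["intercept", "route_gptww"]
        for col in self.columns:
            if col in self._levels:
                out += [f"{col}[{lv}]" for lv in self._levels[col][1:]]
            else:
                out.append(col)
        return out

    def matrix(self, patients: pd.DataFrame, route: str | None = None) -> np.ndarray:
        """Design matrix; ``route`` forces the route indicator for all rows."""
        if not self._fitted:
            raise EstimationError("Design.fit must be called before matrix()")
        n = len(patients)
        cols = [np.ones(n)]
        if route is None:
            cols.append((patients["route"] == "GPTWW").to_numpy(float))
        else:
            cols.append(np.full(n, 1.0 if route == "GPTWW" else 0.0))
        for col in self.columns:
            if col in self._levels:
                vals = patients[col]
                for lv in self._levels[col][1:]:
                    cols.append((vals == lv).to_numpy(float))
            else:
                cols.append(patients[col].to_numpy(float))
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# part models

def _group_index(X: np.ndarray):
    _, inverse = np.unique(X, axis=0, return_inverse=True)
    return inverse


class _BinaryPart:
    """P(y=1 | x): closed-form group proportions on saturated designs,
    otherwise a binomial GLM with probit (or logit) link."""

    def __init__(self, link: str = "probit"):
        self.link = link
        self._mode = None

    def fit(self, X: np.ndarray, y: np.ndarray, context: str = "") -> "_BinaryPart":
        y = np.asarray(y, float)
        uniq = np.unique(X, axis=0)
        if y.min() == y.max():
            self._mode, self._const = "const", float(y[0])
        elif len(uniq) <= X.shape[1]:
            self._mode = "groups"
            self._rows = uniq
            self._probs = np.array([y[(X == r).all(axis=1)].mean() for r in uniq])
            self._fallback = float(y.mean())
        else:
            link = sm.families.links.Probit() if self.link == "probit" \
                else sm.families.links.Logit()
            try:
                with warnings.catch_warnings():
                    # cells perfectly predicted in sparse intervals are benign
                    warnings.simplefilter("ignore")
                    res = sm.GLM(y, X, family=sm.families.Binomial(link=link)).fit(
                        maxiter=2000)
            except Exception as exc:  # non-convergence, separation
                raise EstimationError(f"binary part failed {context}: {exc}") from exc
            if not res.converged:
                raise EstimationError(f"binary part did not converge {context}")
            self._mode, self._res = "glm", res
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._mode == "const":
            return np.full(len(X), self._const)
        if self._mode == "groups":
            out = np.full(len(X), self._fallback)
            for r, p in zip(self._rows, self._probs):
                out[(X == r).all(axis=1)] = p
            return out
        return np.clip(self._res.predict(X), 0.0, 1.0)


class _CostPart:
    """E[cost | x] >= 0 via a hurdle: P(cost>0 | x) * E[cost | cost>0, x].

    The positive part is a gamma GLM with log link, or closed-form group
    means when the design is saturated (or has too few positive rows to
    support a regression).
    """

    def __init__(self, positivity_link: str = "probit"):
        self.positivity_link = positivity_link

    def fit(self, X: np.ndarray, y: np.ndarray, context: str = "") -> "_CostPart":
        y = np.asarray(y, float)
        if (y < 0).any():
            raise EstimationError(f"negative costs {context}")
        self._pos = _BinaryPart(self.positivity_link).fit(X, (y > 0).astype(float),
                                                          context + " [hurdle]")
        Xp, yp = X[y > 0], y[y > 0]
        if len(yp) == 0:
            self._mode = "zero"
            return self
        uniq = np.unique(Xp, axis=0)
        if yp.min() == yp.max():
            self._mode, self._const = "const", float(yp[0])
        elif len(uniq) <= Xp.shape[1] or len(yp) < 3 * Xp.shape[1]:
            self._mode = "groups"
            self._rows = uniq
            self._means = np.array([yp[(Xp == r).all(axis=1)].mean() for r in uniq])
            self._fallback = float(yp.mean())
        else:
            glm = sm.GLM(yp, Xp, family=sm.families.Gamma(
                link=sm.families.links.Log()))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = glm.fit(maxiter=2000)
                    if not res.converged:
                        # IRLS can oscillate on small heavy-tailed samples;
                        # a gradient optimiser is slower but more forgiving
                        res = glm.fit(method="lbfgs", maxiter=5000)
            except Exception as exc:
                raise EstimationError(f"cost part failed {context}: {exc}") from exc
            if not np.isfinite(np.asarray(res.params)).all():
                raise EstimationError(f"cost part did not converge {context}")
            self._mode, self._res = "glm", res
        return self

    def _positive_mean(self, X: np.ndarray) -> np.ndarray:
        if self._mode == "zero":
            return np.zeros(len(X))
        if self._mode == "const":
            return np.full(len(X), self._const)
        if self._mode == "groups":
            out = np.full(len(X), self._fallback)
            for r, m in zip(self._rows, self._means):
                out[(X == r).all(axis=1)] = m
            return out
        return np.asarray(self._res.predict(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._pos.predict(X) * self._positive_mean(X)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class _IntervalFit:
    lo: float
    hi: float
    n_at_risk: int
    n_decedents: int
    hazard: _BinaryPart | None      # None => no deaths, h == 0
    decedent_cost: _CostPart | None
    survivor_cost: _CostPart | None  # None => nobody survived the interval


@dataclass
class BMFit:
    """Fitted three-part models for every interval plus the design spec."""

    grid: IntervalGrid
    design: Design
    parts: list = field(default_factory=list)
    pooled_intervals: list = field(default_factory=list)

    def hazard(self, j: int, X: np.ndarray) -> np.ndarray:
        part = self.parts[j].hazard
        return np.zeros(len(X)) if part is None else part.predict(X)


def fit_bm(cohort: CohortTable, grid: IntervalGrid, covariates=(),
           hazard_link: str = "probit", min_decedents: int = 5) -> BMFit:
    """Fit the three-part estimator on ``cohort`` over ``grid``.

    ``covariates`` are patient-table column names entering every part in
    addition to the intercept and the route indicator.  Intervals with fewer
    than ``min_decedents`` decedents have their decedent cost model pooled
    with the neighbouring later interval (``min_decedents=1`` disables
    pooling); intervals with no decedents at all get hazard identically 0.
    """
    if grid.horizon > cohort.horizon_months:
        raise GridError("grid horizon exceeds cohort horizon")
    patients = cohort.patients.reset_index(drop=True)
    design = Design(covariates).fit(patients)
    X = design.matrix(patients)
    tte = patients["time_to_event"].to_numpy()
    event = patients["event"].to_numpy().astype(bool)

    intervals = grid.intervals
    cost_j = [cohort.interval_costs(lo, hi).to_numpy() for lo, hi in intervals]

    # masks per interval
    info = []
    for j, (lo, hi) in enumerate(intervals):
        at_risk = (tte > lo) & (event | (tte >= hi))
        dies = at_risk & event & (tte <= hi)
        survives = at_risk & ~dies
        if not at_risk.any():
            raise EstimationError(f"empty risk set in interval ({lo}, {hi}]")
        info.append((lo, hi, at_risk, dies, survives))

    # pool sparse decedent groups with the neighbouring later interval
    groups, current = [], []
    for j in range(len(intervals)):
        current.append(j)
        n_dec = sum(int(info[k][3].sum()) for k in current)
        if n_dec >= min_decedents:
            groups.append(current)
            current = []
    if current:  # sparse tail pools backwards
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)

    dec_models: dict[int, _CostPart | None] = {}
    pooled = []
    for grp in groups:
        rows = np.zeros(len(patients), dtype=bool)
        ys = np.zeros(len(patients))
        for j in grp:
            rows |= info[j][3]
            ys[info[j][3]] = cost_j[j][info[j][3]]
        if rows.any():
            model = _CostPart().fit(X[rows], ys[rows],
                                    f"[decedent costs, intervals {grp}]")
        else:
            model = None
        for j in grp:
            dec_models[j] = model
        if len(grp) > 1:
            pooled.append(tuple(grp))

    fit = BMFit(grid=grid, design=design, pooled_intervals=pooled)
    for j, (lo, hi, at_risk, dies, survives) in enumerate(info):
        ctx = f"[interval ({lo}, {hi}]]"
        if dies.any():
            hz = _BinaryPart(hazard_link).fit(X[at_risk],
                                              dies[at_risk].astype(float),
                                              ctx + " hazard")
            dec = dec_models[j]
        else:
            hz, dec = None, None
        if survives.any():
            sur = _CostPart().fit(X[survives], cost_j[j][survives],
                                  ctx + " survivor costs")
        else:
            # everyone at risk died: survivor weight (1 - h) is ~0 anyway
            sur = None
        fit.parts.append(_IntervalFit(lo, hi, int(at_risk.sum()),
                                      int(dies.sum()), hz, dec, sur))
    return fit


# ---------------------------------------------------------------------------
# prediction and decomposition

def _accumulate(fit: BMFit, X: np.ndarray, boundaries,
                hazard_X: np.ndarray | None = None) -> np.ndarray:
    """Mean cumulative cost at each boundary; ``hazard_X`` swaps the design
    used for the survival components (hazard and survival weights), which is
    how the intensity effect is constructed."""
    XH = X if hazard_X is None else hazard_X
    n = len(X)
    S = np.ones(n)
    total = np.zeros(n)
    out = {0: 0.0}
    for j, part in enumerate(fit.parts):
        h = fit.hazard(j, XH)
        muD = np.zeros(n) if part.decedent_cost is None \
            else part.decedent_cost.predict(X)
        muS = np.zeros(n) if part.survivor_cost is None \
            else part.survivor_cost.predict(X)
        total = total + S * (h * muD + (1.0 - h) * muS)
        S = S * (1.0 - h)
        out[part.hi] = float(total.mean())
    return np.array([out[b] for b in boundaries])


def expected_cumulative_cost(fit: BMFit, route: str, upto: float,
                             population: pd.DataFrame) -> float:
    """Population-averaged expected cumulative cost to month ``upto`` with
    the route forced for every covariate row (recycled predictions)."""
    if upto not in fit.grid.boundaries:
        raise AlignmentError(
            f"month {upto} is not a boundary of the interval grid")
    X = fit.design.matrix(population, route=route)
    return float(_accumulate(fit, X, [upto])[0])


@dataclass
class CostEffectCurves:
    """Cumulative route-effect curves on the grid's month boundaries.

    ``total = survival + intensity`` holds exactly at every month; negative
    values mean the GP/TWW route is cost saving relative to EP.
    """

    months: np.ndarray
    total: np.ndarray
    survival: np.ndarray
    intensity: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None

    def at(self, month: float) -> dict:
        i = np.nonzero(self.months == month)[0]
        if len(i) == 0:
            raise AlignmentError(f"month {month} not on the curve grid")
        i = int(i[0])
        return {"month": month, "total": float(self.total[i]),
                "survival": float(self.survival[i]),
                "intensity": float(self.intensity[i])}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"month": self.months, "total_effect": self.total,
                           "survival_effect": self.survival,
                           "intensity_effect": self.intensity})
        if self.lo is not None:
            df["lo"] = self.lo
            df["hi"] = self.hi
        return df


def decompose_effect(fit: BMFit, population: pd.DataFrame,
                     horizon: float | None = None) -> CostEffectCurves:
    """Total route effect on cumulative cost and its decomposition.

    With EP as baseline: the intensity effect combines EP survival
    components with GP/TWW cost components; the survival effect is the
    residual (total minus intensity), making the decomposition additive by
    construction.
    """
    horizon = fit.grid.horizon if horizon is None else horizon
    boundaries = [b for b in fit.grid.boundaries if b <= horizon]
    X_ep = fit.design.matrix(population, route="EP")
    X_gp = fit.design.matrix(population, route="GPTWW")
    mu_ep = _accumulate(fit, X_ep, boundaries)
    mu_gp = _accumulate(fit, X_gp, boundaries)
    mu_mix = _accumulate(fit, X_gp, boundaries, hazard_X=X_ep)
    total = mu_gp - mu_ep
    intensity = mu_mix - mu_ep
    return CostEffectCurves(months=np.array(boundaries), total=total,
                            survival=total - intensity, intensity=intensity)


def bootstrap_curves(cohort: CohortTable, grid: IntervalGrid, covariates=(),
                     n_reps: int = 200, seed: int = 0,
                     min_decedents: int = 5) -> CostEffectCurves:
    """Point estimate with percentile bootstrap bands (patient resampling).

    Resamples patients with replacement; a degenerate resample (an empty
    route arm, or an interval left with nobody at risk) is redrawn, and the
    count is recorded on the result as ``n_redrawn``.  Seed-deterministic.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    fit = fit_bm(cohort, grid, covariates, min_decedents=min_decedents)
    point = decompose_effect(fit, cohort.patients)
    rng = np.random.default_rng(seed)
    patients = cohort.patients.reset_index(drop=True)
    costs_by_pid = dict(tuple(cohort.costs.groupby("patient_id")))
    totals = []
    n_redrawn = 0
    for _ in range(n_reps):
        for _attempt in range(100):
            take = rng.integers(0, len(patients), len(patients))
            boot_p = patients.iloc[take].reset_index(drop=True)
            if boot_p["route"].nunique() < 2:
                n_redrawn += 1
                continue
            new_ids = [f"B{i:06d}" for i in range(len(boot_p))]
            frames = []
            for new_id, old_id in zip(new_ids, boot_p["patient_id"]):
                blk = costs_by_pid.get(old_id)
                if blk is not None:
                    blk = blk.copy()
                    blk["patient_id"] = new_id
                    frames.append(blk)
            boot_p = boot_p.copy()
            boot_p["patient_id"] = new_ids
            boot_costs = pd.concat(frames, ignore_index=True) if frames else \
                cohort.costs.iloc[:0].copy()
            boot = CohortTable(patients=boot_p, costs=boot_costs,
                               horizon_months=cohort.horizon_months,
                               validate_on_init=False)
            try:
                bfit = fit_bm(boot, grid, covariates,
                              min_decedents=min_decedents)
            except EstimationError:
                n_redrawn += 1
                continue
            break
        else:
            raise EstimationError("bootstrap: 100 degenerate resamples in a row")
        totals.append(decompose_effect(bfit, boot_p).total)
    arr = np.vstack(totals)
    point.lo = np.percentile(arr, 2.5, axis=0)
    point.hi = np.percentile(arr, 97.5, axis=0)
    point.n_redrawn = n_redrawn
    return point


def prediag_cost_effect(cohort: CohortTable, covariates=()) -> float:
    """Risk-adjusted GP/TWW-minus-EP difference in total cost over the year
    before diagnosis (months -12..-1), via one hurdle GLM on cumulative
    pre-diagnosis cost with recycled predictions.  Negative values mean
    GP/TWW patients cost less before diagnosis."""
    if not (cohort.costs["month_index"] < 0).any():
        raise EstimationError("cohort has no pre-diagnosis cost months")
    patients = cohort.patients.reset_index(drop=True)
    design = Design(covariates).fit(patients)
    y = cohort.interval_costs(-12, 0).to_numpy()
    model = _CostPart().fit(design.matrix(patients), y, "[pre-diagnosis costs]")
    mu_gp = model.predict(design.matrix(patients, route="GPTWW")).mean()
    mu_ep = model.predict(design.matrix(patients, route="EP")).mean()
    return float(mu_gp - mu_ep)
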