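"""Cohort data model, validation and CSV round-trip.

A cohort couples a patient table (one row per subject: route to diagnosis,
covariates, follow-up) with a long-format monthly hospital-cost table spanning
the 12 months before diagnosis and up to 60 months after (36 for lung cancer).
All downstream estimation modules consume the :class:`CohortTable` produced
here.

Month convention: month 0 is the month containing diagnosis, pre-diagnosis
months are -12..-1, and month bins are half-open.  The month containing a
death or censoring event is included in the patient's cost history, i.e.
cost rows must satisfy ``month_index < time_to_event``.  Months without any
hospital contact may simply be absent and are treated as zero-cost months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITES = ("colorectal", "breast", "prostate", "lung")
ROUTES = ("EP", "GPTWW")
SEXES = ("F", "M")

#: Charlson comorbidity indicator columns, in schema order.
CCI_COLUMNS = (
    "cci_ami", "cci_chf", "cci_pvd", "cci_cvd", "cci_dem", "cci_copd",
    "cci_rheum", "cci_ulcer", "cci_liver", "cci_diab", "cci_renal",
)

PATIENT_COLUMNS = (
    ("patient_id",) + ("site", "route", "age", "sex", "imd_income", "region")
    + CCI_COLUMNS + ("n_codiag", "surgery_12m", "time_to_event", "event")
)
COST_COLUMNS = ("patient_id", "month_index", "cost_gbp")

MIN_MONTH = -12


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class SchemaError(CohortError):
    """A required column is missing or of the wrong kind."""


class ValidationError(CohortError):
    """A value violates a cohort invariant."""


class ReferentialIntegrityError(CohortError):
    """A cost row references a patient that does not exist."""


def horizon_for_site(site: str) -> int:
    """Follow-up horizon in months: 36 for lung, 60 otherwise."""
    return 36 if site == "lung" else 60


@dataclass
class CohortTable:
    """A validated cohort: patients, monthly costs, and the follow-up horizon.

    Parameters
    ----------
    patients
        One row per patient with the columns in :data:`PATIENT_COLUMNS`.
    costs
        Long format, columns ``patient_id, month_index, cost_gbp``;
        ``month_index`` runs from -12 (a year before diagnosis) to
        ``horizon_months - 1``.
    horizon_months
        60, or 36 for lung cohorts.
    """

    patients: pd.DataFrame
    costs: pd.DataFrame
    horizon_months: int = 60
    validate_on_init: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.validate_on_init:
            self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check schema and every structural invariant; raise on violation."""
        p, c = self.patients, self.costs
        for col in PATIENT_COLUMNS:
            if col not in p.columns:
                raise SchemaError(f"patients table missing column {col!r}")
        for col in COST_COLUMNS:
            if col not in c.columns:
                raise SchemaError(f"costs table missing column {col!r}")
        if self.horizon_months not in (36, 60):
            raise ValidationError(
                f"horizon_months must be 36 or 60, got {self.horizon_months}")
        if len(p) == 0:
            if len(c) > 0:
                raise ReferentialIntegrityError("cost rows without patients")
            return

        if p["patient_id"].duplicated().any():
            raise ValidationError("duplicate patient_id in patients table")
        bad_site = ~p["site"].isin(SITES)
        if bad_site.any():
            raise ValidationError(
                f"unknown site values: {sorted(p.loc[bad_site, 'site'].unique())}")
        if (p["site"] == "lung").any() and self.horizon_months != 36:
            raise ValidationError("lung cohorts must use a 36-month horizon")
        if (p["site"] != "lung").all() and self.horizon_months == 36:
            raise ValidationError("36-month horizon is reserved for lung cohorts")
        if not p["route"].isin(ROUTES).all():
            raise ValidationError("route must be 'EP' or 'GPTWW'")
        if not p["sex"].isin(SEXES).all():
            raise ValidationError("sex must be 'F' or 'M'")
        if ((p["site"] == "breast") & (p["sex"] == "M")).any():
            raise ValidationError("breast cohort contains sex=M patients")
        if ((p["site"] == "prostate") & (p["sex"] == "F")).any():
            raise ValidationError("prostate cohort contains sex=F patients")
        if (p["age"] < 18).any():
            raise ValidationError("age_at_diagnosis below 18")
        if ((p["imd_income"] < 0) | (p["imd_income"] > 1)).any():
            raise ValidationError("imd_income outside [0, 1]")
        for col in CCI_COLUMNS:
            if not p[col].isin((0, 1)).all():
                raise ValidationError(f"{col} must be binary")
        if (p["n_codiag"] < 0).any():
            raise ValidationError("n_codiag must be non-negative")
        if not p["surgery_12m"].isin((0, 1)).all():
            raise ValidationError("surgery_12m must be binary")
        if (p["time_to_event"] <= 0).any():
            raise ValidationError("time_to_event must be positive")
        if (p["time_to_event"] > self.horizon_months).any():
            raise ValidationError(
                f"time_to_event exceeds the {self.horizon_months}-month horizon")
        if not p["event"].isin((0, 1)).all():
            raise ValidationError("event must be binary")

        if len(c) == 0:
            return
        orphans = ~c["patient_id"].isin(p["patient_id"])
        if orphans.any():
            raise ReferentialIntegrityError(
                f"{int(orphans.sum())} cost rows reference unknown patients "
                f"(e.g. {c.loc[orphans, 'patient_id'].iloc[0]!r})")
        if (c["cost_gbp"] < 0).any():
            raise ValidationError("negative cost_gbp")
        if (c["month_index"] < MIN_MONTH).any():
            raise ValidationError(f"month_index below {MIN_MONTH}")
        if (c["month_index"] >= self.horizon_months).any():
            raise ValidationError(
                f"month_index at or beyond the {self.horizon_months}-month horizon")
        if c.duplicated(subset=["patient_id", "month_index"]).any():
            raise ValidationError("duplicate (patient_id, month_index) cost rows")
        # post-diagnosis costs only while the patient is alive and uncensored
        tte = p.set_index("patient_id")["time_to_event"]
        post = c[c["month_index"] >= 0]
        limit = post["patient_id"].map(tte)
        if (post["month_index"].to_numpy() >= limit.to_numpy()).any():
            raise ValidationError(
                "cost recorded in a month after death or censoring")

    # -- convenience ------------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def interval_costs(self, lo: float, hi: float) -> pd.Series:
        """Total cost per patient over months ``[lo, hi)``, zero-filled.

        Indexed like ``patients`` (one entry per patient, in table order).
        """
        sel = self.costs[(self.costs["month_index"] >= lo)
                         & (self.costs["month_index"] < hi)]
        sums = sel.groupby("patient_id")["cost_gbp"].sum()
        out = self.patients["patient_id"].map(sums).fillna(0.0)
        out.name = f"cost_{lo}_{hi}"
        return out


def read_cohort(patient_path, cost_path) -> CohortTable:
    """Read and validate a cohort from the two CSV files.

    Raises :class:`SchemaError`, :class:`ValidationError` or
    :class:`ReferentialIntegrityError` with the offending column / rows named.
    """
    patients = pd.read_csv(patient_path, dtype={"patient_id": str})
    costs = pd.read_csv(cost_path, dtype={"patient_id": str})
    if len(patients) and "site" in patients.columns:
        horizon = horizon_for_site(patients["site"].iloc[0])
    else:
        horizon = 60
    return CohortTable(patients=patients, costs=costs, horizon_months=horizon)


def write_cohort(cohort: CohortTable, patient_path, cost_path) -> None:
    """Write a validated cohort to CSV; round-trips through :func:`read_cohort`.

    Reals are written with 12 significant digits; integers are preserved
    bit-for-bit.
    """
    cohort.validate()
    cohort.patients.to_csv(patient_path, index=False, float_format="%.12g",
                           columns=list(PATIENT_COLUMNS))
    cohort.costs.to_csv(cost_path, index=False, float_format="%.12g",
                        columns=list(COST_COLUMNS))


def add_cci_count(patients: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``cci_count`` column (sum of the 11 Charlson flags)."""
    out = patients.copy()
    out["cci_count"] = patients[list(CCI_COLUMNS)].sum(axis=1)
    return out


def empty_cohort(site: str = "colorectal") -> CohortTable:
    """An empty, schema-complete cohort (useful for header-only CSV output)."""
    patients = pd.DataFrame({col: pd.Series(dtype=object if col in
                             ("patient_id", "site", "route", "sex", "region")
                             else float) for col in PATIENT_COLUMNS})
    costs = pd.DataFrame({"patient_id": pd.Series(dtype=object),
                          "month_index": pd.Series(dtype=int),
                          "cost_gbp": pd.Series(dtype=float)})
    return CohortTable(patients=patients, costs=costs,
                       horizon_months=horizon_for_site(site))
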