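import numpy as np
import pandas as pd
import pytest

from reroutecost.cohort import (CohortTable, ReferentialIntegrityError,
                                SchemaError, ValidationError, empty_cohort,
                                read_cohort, write_cohort)
from reroutecost.simulate import SimulationConfig, simulate_cohort

from conftest import make_cohort, make_patients


def two_patient_fixture():
    patients = make_patients([10.5, 60.0], [1, 0], ["EP", "GPTWW"])
    costs = pd.DataFrame({
        "patient_id": ["T0000"] * 12 + ["T0001"] * 12,
        "month_index": list(range(-12, 0)) * 2,
        "cost_gbp": [100.0] * 12 + [55.25] * 12,
    })
    return make_cohort(patients, costs)


def test_two_patient_round_trip(tmp_path):
    cohort = two_patient_fixture()
    write_cohort(cohort, tmp_path / "p.csv", tmp_path / "c.csv")
    back = read_cohort(tmp_path / "p.csv", tmp_path / "c.csv")
    assert back.n_patients == 2
    assert len(back.costs) == 24
    pd.testing.assert_frame_equal(
        back.patients, cohort.patients[back.patients.columns], check_dtype=False)
    pd.testing.assert_frame_equal(
        back.costs, cohort.costs[back.costs.columns], check_dtype=False)


def test_synthetic_cohort_round_trip_identity(tmp_path):
    cohort = simulate_cohort(SimulationConfig(n_patients=100, seed=5))
    write_cohort(cohort, tmp_path / "p.csv", tmp_path / "c.csv")
    back = read_cohort(tmp_path / "p.csv", tmp_path / "c.csv")
    for col in ("time_to_event", "age", "imd_income"):
        # writer contract: reals survive to 12 significant digits
        np.testing.assert_allclose(back.patients[col], cohort.patients[col],
                                   rtol=5e-12)
    np.testing.assert_array_equal(back.patients["event"], cohort.patients["event"])
    np.testing.assert_allclose(back.costs["cost_gbp"], cohort.costs["cost_gbp"],
                               rtol=1e-11)


def test_empty_cohort_writes_headers_only(tmp_path):
    write_cohort(empty_cohort(), tmp_path / "p.csv", tmp_path / "c.csv")
    assert (tmp_path / "p.csv").read_text().count("\n") == 1
    back = read_cohort(tmp_path / "p.csv", tmp_path / "c.csv")
    assert back.n_patients == 0


def test_missing_column_names_the_column(tmp_path):
    cohort = two_patient_fixture()
    write_cohort(cohort, tmp_path / "p.csv", tmp_path / "c.csv")
    df = pd.read_csv(tmp_path / "p.csv").drop(columns=["imd_income"])
    df.to_csv(tmp_path / "p.csv", index=False)
    with pytest.raises(SchemaError, match="imd_income"):
        read_cohort(tmp_path / "p.csv", tmp_path / "c.csv")


def _mutate_month_out_of_range(p, c):
    c.loc[0, "month_index"] = -13


def _mutate_negative_cost(p, c):
    c.loc[0, "cost_gbp"] = -1.0


def _mutate_orphan_cost(p, c):
    c.loc[0, "patient_id"] = "GHOST"


def _mutate_duplicate_cost_row(p, c):
    c.loc[1, ["patient_id", "month_index"]] = c.loc[0, ["patient_id",
                                                        "month_index"]].values


def _mutate_underage(p, c):
    p.loc[0, "age"] = 17


def _mutate_male_breast(p, c):
    p.loc[:, "site"] = "breast"
    p.loc[0, "sex"] = "M"


def _mutate_female_prostate(p, c):
    p.loc[:, "site"] = "prostate"
    p.loc[0, "sex"] = "F"


def _mutate_nonpositive_followup(p, c):
    p.loc[0, "time_to_event"] = 0.0


def _mutate_followup_beyond_horizon(p, c):
    p.loc[0, "time_to_event"] = 61.0


def _mutate_bad_route(p, c):
    p.loc[0, "route"] = "SCREENING"


def _mutate_cost_after_death(p, c):
    c.loc[0, "month_index"] = 12  # patient T0000 dies at month 10.5


@pytest.mark.parametrize("mutate", [
    _mutate_month_out_of_range, _mutate_negative_cost, _mutate_orphan_cost,
    _mutate_duplicate_cost_row, _mutate_underage, _mutate_male_breast,
    _mutate_female_prostate, _mutate_nonpositive_followup,
    _mutate_followup_beyond_horizon, _mutate_bad_route,
    _mutate_cost_after_death,
], ids=lambda f: f.__name__.removeprefix("_mutate_"))
def test_validation_rejects_each_broken_invariant(mutate):
    base = two_patient_fixture()
    patients = base.patients.copy()
    costs = base.costs.copy()
    mutate(patients, costs)
    with pytest.raises((ValidationError, ReferentialIntegrityError)):
        CohortTable(patients=patients, costs=costs, horizon_months=60)


def test_lung_cohort_rejects_months_beyond_three_years():
    patients = make_patients([30.0], [1], ["EP"], site="lung")
    costs = pd.DataFrame({"patient_id": ["T0000"], "month_index": [40],
                          "cost_gbp": [10.0]})
    with pytest.raises(ValidationError):
        CohortTable(patients=patients, costs=costs, horizon_months=36)


def test_interval_costs_fills_zero_for_quiet_months():
    cohort = two_patient_fixture()
    # no post-diagnosis rows at all: alive months count as zero-cost months
    assert (cohort.interval_costs(0, 12) == 0).all()
    assert cohort.interval_costs(-12, 0).tolist() == [1200.0, 12 * 55.25]
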