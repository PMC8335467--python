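import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptrt.grid import DoseGrid, GridSpec, StructureSet
from adaptrt.criteria_penalty import (
    PENALTY_CRITERIA,
    ConfigurationError,
    CriterionResult,
    DoseCriterion,
    EvaluationError,
    PlanEvaluation,
    Tier,
    cohort_penalty_table,
    evaluate_criterion,
    load_criteria,
    load_printed_table,
    penalty_score,
    percent_reduction,
    plan_penalty,
    printed_per_criterion,
    printed_per_patient,
)


# ----------------------------------------------------------------------
# penalty_score
# ----------------------------------------------------------------------


def test_boundary_not_exceeded():
    assert penalty_score(2.0, 2.0, "upper") == 0.0
    assert penalty_score(95.0, 95.0, "lower") == 0.0


def test_upper_bound_formula():
    assert penalty_score(2.5, 2.0, "upper") == pytest.approx(25.0)


def test_lower_bound_formula():
    assert penalty_score(34.0, 34.4, "lower") == pytest.approx(1.1628, abs=1e-4)


def test_coverage_minor_variation_penalty():
    assert penalty_score(92.0, 95.0, "lower") == pytest.approx(3.158, abs=1e-3)


def test_non_positive_bound_rejected():
    with pytest.raises(ConfigurationError):
        penalty_score(1.0, 0.0, "upper")


@settings(max_examples=100, deadline=None)
@given(
    st.floats(min_value=0.01, max_value=1e4),
    st.floats(min_value=0.01, max_value=1e4),
    st.floats(min_value=1e-3, max_value=1e3),
    st.sampled_from(["upper", "lower"]),
)
def test_scale_invariance(m, c, k, direction):
    assert penalty_score(k * m, k * c, direction) == pytest.approx(
        penalty_score(m, c, direction), rel=1e-9
    )


@settings(max_examples=100, deadline=None)
@given(
    st.floats(min_value=0.0, max_value=100.0),
    st.floats(min_value=0.0, max_value=100.0),
)
def test_monotonicity_in_measured_value(m1, m2):
    lo, hi = sorted((m1, m2))
    c = 50.0
    assert penalty_score(hi, c, "upper") >= penalty_score(lo, c, "upper")
    assert penalty_score(hi, c, "lower") <= penalty_score(lo, c, "lower")


# ----------------------------------------------------------------------
# evaluate_criterion / tiers
# ----------------------------------------------------------------------


def _structures_with_doses(doses_gy):
    """One 100-voxel structure named 'ptv' with the given per-voxel doses."""
    grid = GridSpec(shape=(10, 10, 10), spacing=(2.0, 2.0, 2.0))
    mask = np.zeros(grid.shape, bool)
    mask[:4, :5, :5] = True  # 100 voxels
    values = np.zeros(grid.shape)
    values[mask] = np.asarray(doses_gy, float)
    return DoseGrid(grid, values), StructureSet(grid=grid, masks={"ptv": mask})


COVERAGE = DoseCriterion(
    name="ptv_v36.25",
    structure="ptv",
    metric="V",
    threshold_gy=36.25,
    unit="pct",
    bound=95.0,
    direction="lower",
    minor_band=(90.0, 94.9),
    in_penalty=True,
)


def test_satisfied_criterion_optimal():
    doses = [40.0] * 96 + [10.0] * 4  # V36.25 = 96 %
    dose, ss = _structures_with_doses(doses)
    res = evaluate_criterion(dose, ss, COVERAGE)
    assert res.tier is Tier.OPTIMAL
    assert res.penalty_contribution == 0.0


def test_minor_variation_tier_and_penalty():
    doses = [40.0] * 92 + [10.0] * 8  # V36.25 = 92 %
    dose, ss = _structures_with_doses(doses)
    res = evaluate_criterion(dose, ss, COVERAGE)
    assert res.tier is Tier.MINOR
    assert res.penalty_contribution == pytest.approx(3.158, abs=1e-3)


def test_violation_tier():
    doses = [40.0] * 80 + [10.0] * 20  # V36.25 = 80 %
    dose, ss = _structures_with_doses(doses)
    res = evaluate_criterion(dose, ss, COVERAGE)
    assert res.tier is Tier.VIOLATION
    assert res.penalty_contribution > 0


def test_upper_bound_boundary_is_optimal():
    crit = DoseCriterion(
        name="rectum_v36",
        structure="ptv",
        metric="V",
        threshold_gy=36.0,
        unit="cc",
        bound=2.0,
        direction="upper",
        in_penalty=True,
    )
    doses = [40.0] * 250  # exactly 2.0 cc at 36+ Gy... need 250 voxels
    grid = GridSpec(shape=(10, 10, 10), spacing=(2.0, 2.0, 2.0))
    mask = np.zeros(grid.shape, bool)
    mask[:5, :5, :10] = True  # 250 voxels = 2.0 cc
    values = np.zeros(grid.shape)
    values[mask] = 40.0
    dose = DoseGrid(grid, values)
    ss = StructureSet(grid=grid, masks={"ptv": mask})
    res = evaluate_criterion(dose, ss, crit)
    assert res.measured_value == pytest.approx(2.0)
    assert res.tier is Tier.OPTIMAL
    assert res.penalty_contribution == 0.0


def test_missing_structure_raises():
    dose, ss = _structures_with_doses([40.0] * 100)
    crit = DoseCriterion(
        name="x", structure="bladder", metric="V", threshold_gy=37.0,
        unit="cc", bound=10.0, direction="upper",
    )
    with pytest.raises(EvaluationError):
        evaluate_criterion(dose, ss, crit)


# ----------------------------------------------------------------------
# plan_penalty
# ----------------------------------------------------------------------


def _result(name, contribution, in_penalty=True):
    crit = DoseCriterion(
        name=name, structure="s", metric="V", threshold_gy=1.0,
        unit="cc", bound=1.0, direction="upper", in_penalty=in_penalty,
    )
    tier = Tier.VIOLATION if contribution > 0 else Tier.OPTIMAL
    return CriterionResult(crit, 0.0, tier, contribution)


def test_plan_penalty_sums_scoring_criteria():
    results = [
        _result("ptv_v36.25", 3.158),
        _result("ptv_d98", 0.0),
        _result("bladder_v37", 25.0),
        _result("rectum_v36", 0.0),
    ]
    assert plan_penalty(results) == pytest.approx(28.158)


def test_all_satisfied_gives_zero():
    results = [_result(n, 0.0) for n in PENALTY_CRITERIA]
    assert plan_penalty(results) == 0.0


def test_extra_satisfied_criterion_ignored():
    results = [_result(n, 1.0) for n in PENALTY_CRITERIA]
    s = plan_penalty(results)
    results.append(_result("ctv_v40", 99.0, in_penalty=False))
    assert plan_penalty(results) == pytest.approx(s)


def test_missing_scoring_criterion_raises():
    results = [_result(n, 0.0) for n in PENALTY_CRITERIA[:-1]]
    with pytest.raises(EvaluationError):
        plan_penalty(results)


# ----------------------------------------------------------------------
# criterion config
# ----------------------------------------------------------------------


def test_shipped_criteria_cover_protocol():
    criteria = load_criteria()
    names = {c.name for c in criteria}
    assert set(PENALTY_CRITERIA) <= names
    assert sum(c.in_penalty for c in criteria) == 4
    ctv = next(c for c in criteria if c.name == "ctv_v40")
    assert not ctv.in_penalty and ctv.minor_band == (90.0, 94.9)


# ----------------------------------------------------------------------
# cohort_penalty_table
# ----------------------------------------------------------------------


def _evaluation(patient, fraction, approach, contributions):
    results = tuple(
        _result(name, value) for name, value in zip(PENALTY_CRITERIA, contributions)
    )
    return PlanEvaluation(
        patient=patient, fraction=fraction, approach=approach, results=results,
        overlap_volumes_cc={"bladder": 5.0, "rectum": 2.0},
    )


def test_singleton_table():
    table = cohort_penalty_table([_evaluation("P1", 1, "IGRT", [25.0, 0, 0, 0])])
    assert table.per_criterion.loc["ptv_v36.25", "IGRT"] == 25.0
    assert table.per_patient_mean.loc["P1", "IGRT"] == 25.0
    assert table.per_patient_sd.loc["P1", "IGRT"] == 0.0  # n = 1 convention


def test_column_total_consistency_random_cohorts():
    rng = np.random.default_rng(6)
    evaluations = []
    for p in range(4):
        for f in range(1, 4):
            for a in ("IGRT", "ART1"):
                evaluations.append(
                    _evaluation(f"P{p + 1}", f, a, rng.uniform(0, 30, 4))
                )
    table = cohort_penalty_table(evaluations)
    for a in ("IGRT", "ART1"):
        parts = table.per_criterion.loc[list(PENALTY_CRITERIA), a]
        assert table.per_criterion.loc["total", a] == pytest.approx(parts.sum())
        # cohort mean equals the mean of per-patient means
        means = table.per_patient_mean.drop(index="mean")[a]
        assert table.per_patient_mean.loc["mean", a] == pytest.approx(means.mean())


def test_ragged_grid_rejected():
    evaluations = [
        _evaluation("P1", 1, "IGRT", [1, 1, 1, 1]),
        _evaluation("P1", 2, "IGRT", [1, 1, 1, 1]),
        _evaluation("P2", 1, "IGRT", [1, 1, 1, 1]),
    ]
    with pytest.raises(ValueError):
        cohort_penalty_table(evaluations)


# ----------------------------------------------------------------------
# percent_reduction + printed fixture
# ----------------------------------------------------------------------


def test_reduction_identity():
    assert percent_reduction(100.0, 100.0) == 0.0


def test_reduction_zero_reference_rejected():
    with pytest.raises(EvaluationError):
        percent_reduction(10.0, 0.0)


def test_printed_fixture_totals():
    fixture = load_printed_table()
    table = printed_per_criterion(fixture)
    assert table["IGRT"].sum() == 9139
    assert list(table["IGRT"]) == [544, 852, 1800, 5943]
    assert percent_reduction(624.0, 9139.0) == 93.2
    assert percent_reduction(92.0, 1800.0) == 94.9


def test_printed_fixture_patients():
    fixture = load_printed_table()
    table = printed_per_patient(fixture)
    assert table.shape[0] == 32
    assert round(table["IGRT"].mean(), 1) == 57.1
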