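import math

import numpy as np
import pytest

from adaptrt.grid import DoseGrid
from adaptrt.dose_model import (
    ApproachKind,
    DoseModelParams,
    conformal_dose,
    make_plan,
    oar_spare,
    reference_plan,
    rescale_to_coverage,
    transform_dose,
)
from adaptrt.dvh_metrics import EvaluationError, d_volume, v_dose
from adaptrt.synthetic_cohort import (
    PLANNING,
    FractionScenario,
    RigidRegistration,
    realize_structures,
    rigid_register,
)
from test_synthetic_cohort import big_grid, simple_template


def noiseless_params(**overrides) -> DoseModelParams:
    return DoseModelParams(noise_amplitude=0.0, **overrides)


@pytest.fixture
def box_ptv(grid2mm):
    mask = np.zeros(grid2mm.shape, dtype=bool)
    mask[12:28, 12:28, 12:28] = True
    return mask


# ----------------------------------------------------------------------
# conformal_dose
# ----------------------------------------------------------------------


def test_interior_plateau_exact(grid2mm, box_ptv):
    params = noiseless_params()
    dose = conformal_dose(box_ptv, grid2mm, params, ApproachKind.REFERENCE, 0)
    assert dose.values[20, 20, 20] == pytest.approx(params.plateau_gy())


def test_falloff_at_one_sigma(grid2mm, box_ptv):
    # sigma = 6 mm = 3 voxels: voxel 3 steps outside the PTV face sits at
    # exactly one sigma from the nearest PTV voxel centre
    params = noiseless_params(
        penumbra_sigma_mm={a.value: 6.0 for a in ApproachKind},
        conformity_degradation={a.value: 0.0 for a in ApproachKind},
    )
    dose = conformal_dose(box_ptv, grid2mm, params, ApproachKind.REFERENCE, 0)
    expected = params.plateau_gy() * math.exp(-0.5)
    assert dose.values[30, 20, 20] == pytest.approx(expected, rel=1e-9)


def test_monotone_falloff_along_ray(grid2mm, box_ptv):
    dose = conformal_dose(box_ptv, grid2mm, noiseless_params(), ApproachKind.REFERENCE, 0)
    ray = dose.values[27:, 20, 20]
    assert np.all(np.diff(ray) <= 1e-12)


def test_empty_ptv_raises(grid2mm):
    with pytest.raises(EvaluationError):
        conformal_dose(np.zeros(grid2mm.shape, bool), grid2mm, noiseless_params(), ApproachKind.ART1, 0)


def test_noise_field_mean_one(grid2mm, box_ptv):
    params = DoseModelParams(noise_amplitude=0.02)
    a = conformal_dose(box_ptv, grid2mm, params, ApproachKind.REFERENCE, 1)
    b = conformal_dose(box_ptv, grid2mm, params, ApproachKind.REFERENCE, 1)
    np.testing.assert_array_equal(a.values, b.values)  # seeded determinism
    plateau = params.plateau_gy()
    interior = a.values[16:24, 16:24, 16:24]
    assert abs(interior.mean() / plateau - 1.0) < 0.02


# ----------------------------------------------------------------------
# oar_spare
# ----------------------------------------------------------------------


@pytest.fixture
def oar_mask(grid2mm):
    mask = np.zeros(grid2mm.shape, dtype=bool)
    mask[30:39, 10:30, 10:30] = True  # slab beside the box PTV
    return mask


def test_sparing_depth_zero_identity(grid2mm, box_ptv, oar_mask):
    params = noiseless_params(oar_sparing_depth=0.0)
    dose = conformal_dose(box_ptv, grid2mm, params, ApproachKind.ART3, 0)
    spared = oar_spare(dose, {"oar": oar_mask}, box_ptv, params)
    np.testing.assert_array_equal(spared.values, dose.values)


def test_sparing_saturates_far_from_ptv(grid2mm, box_ptv, oar_mask):
    params = noiseless_params(oar_sparing_depth=0.3, oar_interface_margin_mm=3.0)
    dose = conformal_dose(box_ptv, grid2mm, params, ApproachKind.ART3, 0)
    spared = oar_spare(dose, {"oar": oar_mask}, box_ptv, params)
    # voxel (36, 20, 20) is 9 * 2 = 18 mm beyond the PTV face > 2 * margin
    assert spared.values[36, 20, 20] == pytest.approx(0.7 * dose.values[36, 20, 20])


def test_sparing_leaves_non_oar_untouched(grid2mm, box_ptv, oar_mask):
    params = noiseless_params(oar_sparing_depth=0.3)
    dose = conformal_dose(box_ptv, grid2mm, params, ApproachKind.ART3, 0)
    spared = oar_spare(dose, {"oar": oar_mask}, box_ptv, params)
    outside = ~oar_mask
    np.testing.assert_array_equal(spared.values[outside], dose.values[outside])


# ----------------------------------------------------------------------
# transform_dose
# ----------------------------------------------------------------------


def test_identity_transform(grid2mm, box_ptv):
    dose = conformal_dose(box_ptv, grid2mm, noiseless_params(), ApproachKind.REFERENCE, 0)
    out = transform_dose(dose, RigidRegistration())
    np.testing.assert_allclose(out.values, dose.values, atol=1e-9)


def test_one_voxel_lattice_shift(grid2mm, box_ptv):
    dose = conformal_dose(box_ptv, grid2mm, noiseless_params(), ApproachKind.REFERENCE, 0)
    out = transform_dose(dose, RigidRegistration(translation=(2.0, 0.0, 0.0)))
    np.testing.assert_allclose(
        out.values[5:-5, 5:-5, 5:-5], dose.values[4:-6, 5:-5, 5:-5], atol=1e-9
    )


def test_integral_dose_preserved_for_interior_field(grid2mm, box_ptv):
    dose = conformal_dose(box_ptv, grid2mm, noiseless_params(), ApproachKind.REFERENCE, 0)
    out = transform_dose(dose, RigidRegistration(translation=(3.0, -4.0, 1.0)))
    assert out.values.sum() == pytest.approx(dose.values.sum(), rel=0.01)


# ----------------------------------------------------------------------
# rescale_to_coverage
# ----------------------------------------------------------------------


def test_rescale_noop_when_already_on_target(grid2mm, box_ptv):
    values = np.zeros(grid2mm.shape)
    values[box_ptv] = 40.0
    dose = DoseGrid(grid2mm, values)
    out = rescale_to_coverage(dose, box_ptv, 40.0, 95.0)
    np.testing.assert_allclose(out.values, dose.values)


def test_rescale_uniform_field(grid2mm, box_ptv):
    dose = DoseGrid(grid2mm, np.full(grid2mm.shape, 20.0))
    out = rescale_to_coverage(dose, box_ptv, 40.0, 95.0)
    np.testing.assert_allclose(out.values, 40.0)


def test_rescale_postcondition(grid2mm, box_ptv):
    rng = np.random.default_rng(9)
    dose = DoseGrid(grid2mm, rng.uniform(5.0, 45.0, grid2mm.shape))
    out = rescale_to_coverage(dose, box_ptv, 40.0, 95.0)
    assert abs(d_volume(out, box_ptv, 95.0) - 40.0) < 1e-6


def test_rescale_zero_dose_raises(grid2mm, box_ptv):
    dose = DoseGrid(grid2mm, np.zeros(grid2mm.shape))
    with pytest.raises(EvaluationError):
        rescale_to_coverage(dose, box_ptv, 40.0, 95.0)


# ----------------------------------------------------------------------
# make_plan
# ----------------------------------------------------------------------


@pytest.fixture(scope="module")
def anatomy():
    template = simple_template()
    grid = big_grid()
    planning = realize_structures(template, PLANNING, grid)
    scenario = FractionScenario(
        fraction_index=1,
        prostate_shift=(1.0, 3.0, -1.0),
        bladder_fill_scale=1.3,
        rectum_fill_scale=1.2,
        target_axis_scales=(1.05, 1.1, 0.95),
    )
    daily = realize_structures(template, scenario, grid)
    registration = rigid_register(planning["ctv"], daily["ctv"], grid)
    return planning, daily, registration


def test_unknown_approach_rejected(anatomy):
    planning, daily, reg = anatomy
    with pytest.raises(ValueError):
        make_plan("IGRT", planning, daily, reg, noiseless_params(), 0)


def test_igrt_equals_reference_without_deformation(anatomy):
    planning, _, _ = anatomy
    params = noiseless_params()
    dose = make_plan(
        ApproachKind.IGRT,
        planning,
        planning,
        RigidRegistration(),
        params,
        0,
    )
    ref = make_plan(
        ApproachKind.REFERENCE, planning, planning, RigidRegistration(), params, 0
    )
    np.testing.assert_allclose(dose.values, ref.values, atol=1e-9)


@pytest.mark.parametrize("approach", [ApproachKind.ART1, ApproachKind.ART2, ApproachKind.ART3])
def test_adapted_plans_hit_coverage(anatomy, approach):
    planning, daily, reg = anatomy
    dose = make_plan(approach, planning, daily, reg, noiseless_params(), 3)
    assert abs(d_volume(dose, daily["ctv"], 95.0) - 40.0) < 1e-6
    # V_40Gy(CTV) >= 95 % up to the one-voxel discreteness of the quantile
    slack = 100.0 / daily["ctv"].sum()
    assert v_dose(dose, daily["ctv"], 40.0, mode="pct") >= 95.0 - slack


def test_art3_spares_bladder_vs_art1(anatomy):
    planning, daily, reg = anatomy
    params = noiseless_params()
    art1 = make_plan(ApproachKind.ART1, planning, daily, reg, params, 3)
    art3 = make_plan(ApproachKind.ART3, planning, daily, reg, params, 3)
    # compare mean dose in the bladder away from the PTV interface
    from adaptrt.dose_model import ptv_distance

    dist = ptv_distance(daily["ptv"], daily.grid)
    region = daily["bladder"] & (dist > 2 * params.oar_interface_margin_mm)
    assert art3.values[region].mean() < art1.values[region].mean()


def test_reference_plan_never_rescaled(anatomy):
    planning, _, _ = anatomy
    params = noiseless_params()
    ref = reference_plan(planning, params, 0)
    # the plateau is the un-rescaled prescription plateau
    interior = planning["ctv"] & ~planning["bladder"] & ~planning["rectum"]
    assert np.max(ref.values[interior]) == pytest.approx(params.plateau_gy())


def test_equal_ctv_dvh_across_non_art3_archetypes(anatomy):
    """With zero deformation and noise, CTV doses agree for all but ART3."""
    planning, _, _ = anatomy
    params = noiseless_params()
    reg = RigidRegistration()
    ctv = planning["ctv"]
    doses = {}
    for approach in (ApproachKind.REFERENCE, ApproachKind.IGRT):
        doses[approach] = make_plan(approach, planning, planning, reg, params, 0)
    np.testing.assert_allclose(
        doses[ApproachKind.REFERENCE].values[ctv],
        doses[ApproachKind.IGRT].values[ctv],
        atol=1e-9,
    )
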