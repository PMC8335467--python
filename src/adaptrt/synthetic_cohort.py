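"""Synthetic pelvic cohort: reproducible patient anatomies and daily variations.

Each patient is a parametric phantom (ellipsoidal prostate, two seminal-vesicle
lobes, spherical bladder, capsule-shaped rectum) voxelised on a regular
lattice by the voxel-centre-inside rule. Daily anatomies apply a rigid target
shift, anisotropic target axis scaling, and organ-filling changes; a
centroid-based rigid registration per fraction mimics couch correction.

The clinical target volume (CTV) is the prostate plus the proximal 1 cm of the
seminal vesicles, and the planning target volume (PTV) adds an isotropic 4 mm
margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grid import GridSpec, StructureSet, Triple

DEFAULT_MARGIN_MM = 4.0
CTV_SV_PROXIMAL_MM = 10.0


class ConfigurationError(ValueError):
    """Invalid distribution or geometry settings."""


class GridTooSmallError(ValueError):
    """An organ extends beyond the voxel lattice."""


# --------------------------------------------------------------------------
# cohort-level distribution settings
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Distribution settings for patient templates and daily variations.

    Volume draws are lognormal, positions Gaussian. Defaults are calibrated so
    the cohort prostate volume matches 65.3 +/- 26.3 cc and so that daily
    anatomies occasionally violate the shipped dose criteria.
    """

    prostate_volume_mean_cc: float = 65.3
    prostate_volume_sd_cc: float = 26.3
    prostate_axis_ratios: Triple = (1.0, 0.90, 0.85)
    prostate_center_sigma_mm: float = 1.5

    sv_lateral_offset_mm: float = 13.0
    sv_posterior_offset_mm: float = 10.0
    sv_semiaxes_mm: Triple = (7.0, 7.0, 13.0)
    sv_size_jitter: float = 0.10

    bladder_anterior_offset_mm: float = 13.0
    bladder_superior_offset_mm: float = 38.0
    bladder_base_radius_mm: float = 32.0
    bladder_radius_jitter: float = 0.08
    bladder_offset_sigma_mm: float = 3.0

    rectum_posterior_gap_mm: float = -3.5
    rectum_base_radius_mm: float = 14.0
    rectum_radius_jitter: float = 0.08
    rectum_inferior_mm: float = -60.0
    rectum_superior_mm: float = 35.0

    # daily variation
    shift_sigma_mm: Triple = (1.0, 1.5, 1.0)
    shift_cap_mm: float = 10.0
    rectum_push_mm: float = 5.0  # anterior target push per unit of rectal filling
    fill_sigma: float = 0.35
    fill_bounds: Tuple[float, float] = (0.6, 1.6)
    target_axis_scale_sigma: float = 0.11
    target_axis_scale_bounds: Tuple[float, float] = (0.82, 1.25)

    def __post_init__(self) -> None:
        if self.prostate_volume_mean_cc <= 0 or self.prostate_volume_sd_cc <= 0:
            raise ConfigurationError("prostate volume mean/sd must be positive")
        if any(r <= 0 for r in self.prostate_axis_ratios):
            raise ConfigurationError("axis ratios must be positive")
        if self.bladder_base_radius_mm <= 0 or self.rectum_base_radius_mm <= 0:
            raise ConfigurationError("organ radii must be positive")
        if not 0 < self.fill_bounds[0] <= self.fill_bounds[1]:
            raise ConfigurationError("fill bounds must be positive and ordered")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientTemplate:
    """Planning anatomy parameters for one synthetic patient (mm)."""

    patient_id: str
    prostate_center: Triple
    prostate_semiaxes: Triple
    sv_params: Tuple[Triple, Triple, Triple]  # left centre, right centre, semiaxes
    bladder_center: Triple
    bladder_base_radius: float
    rectum_axis: Tuple[Triple, Triple]  # inferior and superior end points
    rectum_base_radius: float
    seed: int

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.prostate_semiaxes):
            raise ConfigurationError("prostate semiaxes must be positive")
        if self.bladder_base_radius <= 0 or self.rectum_base_radius <= 0:
            raise ConfigurationError("organ radii must be positive")
        if any(r <= 0 for r in self.sv_params[2]):
            raise ConfigurationError("SV semiaxes must be positive")
        # bladder sits anterior-superior of the prostate, rectum posterior
        if not (
            self.bladder_center[1] >= self.prostate_center[1]
            and self.bladder_center[2] > self.prostate_center[2]
        ):
            raise ConfigurationError("bladder must be anterior-superior of prostate")
        if not all(p[1] < self.prostate_center[1] for p in self.rectum_axis):
            raise ConfigurationError("rectum axis must be posterior of prostate")


@dataclass(frozen=True)
class FractionScenario:
    """Daily anatomy parameters for one treatment fraction."""

    fraction_index: int
    prostate_shift: Triple = (0.0, 0.0, 0.0)
    bladder_fill_scale: float = 1.0
    rectum_fill_scale: float = 1.0
    deformation_seed: int = 0
    target_axis_scales: Triple = (1.0, 1.0, 1.0)
    fill_bounds: Tuple[float, float] = (0.6, 1.6)
    shift_cap_mm: float = 10.0

    def __post_init__(self) -> None:
        lo, hi = self.fill_bounds
        for name, scale in (
            ("bladder", self.bladder_fill_scale),
            ("rectum", self.rectum_fill_scale),
        ):
            if not lo <= scale <= hi:
                raise ConfigurationError(
                    f"{name} fill scale {scale} outside bounds [{lo}, {hi}]"
                )
        if float(np.linalg.norm(self.prostate_shift)) > self.shift_cap_mm + 1e-9:
            raise ConfigurationError(
                f"prostate shift {self.prostate_shift} exceeds cap {self.shift_cap_mm} mm"
            )


@dataclass(frozen=True)
class RigidRegistration:
    """Per-fraction rigid correction: translation (mm) and rotation (degrees)."""

    translation: Triple = (0.0, 0.0, 0.0)
    rotation_deg: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.translation)) or not np.all(
            np.isfinite(self.rotation_deg)
        ):
            raise ValueError("registration parameters must be finite")
        if any(abs(r) > 10.0 for r in self.rotation_deg):
            raise ValueError("rotation magnitudes above 10 degrees are rejected")


PLANNING: Optional[FractionScenario] = None  # sentinel: planning anatomy


# --------------------------------------------------------------------------
# seeding
# --------------------------------------------------------------------------


def derive_seed(master_seed: int, *indices: int) -> int:
    """Stable per-patient / per-fraction seed from a master seed."""
    ss = np.random.SeedSequence([int(master_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0])


# --------------------------------------------------------------------------
# template and scenario sampling
# --------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def generate_patient(
    seed: int,
    cohort_params: CohortParams | None = None,
    patient_id: str | None = None,
) -> PatientTemplate:
    """Draw one patient template; deterministic for a given seed."""
    p = cohort_params or CohortParams()
    rng = np.random.default_rng(seed)

    volume_cc = _lognormal(rng, p.prostate_volume_mean_cc, p.prostate_volume_sd_cc)
    ra, rb, rc = p.prostate_axis_ratios
    # 4/3 pi a b c = V  with (a, b, c) = s * ratios
    s = (volume_cc * 1000.0 * 3.0 / (4.0 * math.pi * ra * rb * rc)) ** (1.0 / 3.0)
    semiaxes = (s * ra, s * rb, s * rc)

    center = tuple(rng.normal(0.0, p.prostate_center_sigma_mm, size=3))
    sv_scale = float(np.clip(rng.normal(1.0, p.sv_size_jitter), 0.7, 1.3))
    sv_semiaxes = tuple(a * sv_scale for a in p.sv_semiaxes_mm)
    sv_base_z = center[2] + 0.65 * semiaxes[2]
    sv_left = (
        center[0] - p.sv_lateral_offset_mm,
        center[1] - p.sv_posterior_offset_mm,
        sv_base_z + sv_semiaxes[2] * 0.6,
    )
    sv_right = (
        center[0] + p.sv_lateral_offset_mm,
        center[1] - p.sv_posterior_offset_mm,
        sv_base_z + sv_semiaxes[2] * 0.6,
    )

    bladder_radius = p.bladder_base_radius_mm * float(
        np.clip(rng.normal(1.0, p.bladder_radius_jitter), 0.75, 1.25)
    )
    bladder_center = (
        center[0] + rng.normal(0.0, p.bladder_offset_sigma_mm),
        center[1]
        + p.bladder_anterior_offset_mm
        + abs(rng.normal(0.0, p.bladder_offset_sigma_mm)),
        center[2]
        + p.bladder_superior_offset_mm
        + rng.normal(0.0, p.bladder_offset_sigma_mm),
    )

    rectum_radius = p.rectum_base_radius_mm * float(
        np.clip(rng.normal(1.0, p.rectum_radius_jitter), 0.75, 1.25)
    )
    rectum_y = center[1] - semiaxes[1] - rectum_radius - p.rectum_posterior_gap_mm
    rectum_axis = (
        (center[0], rectum_y, center[2] + p.rectum_inferior_mm),
        (center[0], rectum_y, center[2] + p.rectum_superior_mm),
    )

    return PatientTemplate(
        patient_id=patient_id or f"SP{seed % 10_000:04d}",
        prostate_center=tuple(float(c) for c in center),
        prostate_semiaxes=tuple(float(a) for a in semiaxes),
        sv_params=(
            tuple(float(c) for c in sv_left),
            tuple(float(c) for c in sv_right),
            tuple(float(a) for a in sv_semiaxes),
        ),
        bladder_center=tuple(float(c) for c in bladder_center),
        bladder_base_radius=float(bladder_radius),
        rectum_axis=rectum_axis,
        rectum_base_radius=float(rectum_radius),
        seed=int(seed),
    )


def sample_scenario(
    seed: int,
    fraction_index: int,
    cohort_params: CohortParams | None = None,
) -> FractionScenario:
    """Draw one daily-variation scenario; deterministic for a given seed."""
    p = cohort_params or CohortParams()
    rng = np.random.default_rng(seed)

    shift = rng.normal(0.0, p.shift_sigma_mm, size=3)

    lo, hi = p.fill_bounds
    bladder_fill = float(np.clip(rng.lognormal(0.0, p.fill_sigma), lo, hi))
    rectum_fill = float(np.clip(rng.lognormal(0.0, p.fill_sigma), lo, hi))

    # rectal filling pushes the target anteriorly
    shift[1] += p.rectum_push_mm * (rectum_fill - 1.0)
    norm = float(np.linalg.norm(shift))
    if norm > p.shift_cap_mm:
        shift *= p.shift_cap_mm / norm

    slo, shi = p.target_axis_scale_bounds
    axis_scales = tuple(
        float(np.clip(v, slo, shi))
        for v in rng.lognormal(0.0, p.target_axis_scale_sigma, size=3)
    )

    return FractionScenario(
        fraction_index=int(fraction_index),
        prostate_shift=tuple(float(s) for s in shift),
        bladder_fill_scale=bladder_fill,
        rectum_fill_scale=rectum_fill,
        deformation_seed=int(seed),
        target_axis_scales=axis_scales,
        fill_bounds=p.fill_bounds,
        shift_cap_mm=p.shift_cap_mm,
    )


# --------------------------------------------------------------------------
# voxelisation
# --------------------------------------------------------------------------


def _ellipsoid_mask(grid: GridSpec, center: Sequence[float], semiaxes: Sequence[float]) -> np.ndarray:
    gx, gy, gz = grid.coordinate_grids()
    return (
        ((gx - center[0]) / semiaxes[0]) ** 2
        + ((gy - center[1]) / semiaxes[1]) ** 2
        + ((gz - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _sphere_mask(grid: GridSpec, center: Sequence[float], radius: float) -> np.ndarray:
    return _ellipsoid_mask(grid, center, (radius, radius, radius))


def _capsule_mask(
    grid: GridSpec, p0: Sequence[float], p1: Sequence[float], radius: float
) -> np.ndarray:
    """Cylinder with hemispherical caps: distance-to-segment <= radius."""
    gx, gy, gz = grid.coordinate_grids()
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    length2 = float(d @ d)
    vx, vy, vz = gx - p0[0], gy - p0[1], gz - p0[2]
    if length2 == 0.0:
        dist2 = vx**2 + vy**2 + vz**2
    else:
        t = np.clip((vx * d[0] + vy * d[1] + vz * d[2]) / length2, 0.0, 1.0)
        dist2 = (vx - t * d[0]) ** 2 + (vy - t * d[1]) ** 2 + (vz - t * d[2]) ** 2
    return dist2 <= radius * radius


def expand_margin(mask: np.ndarray, margin_mm: float, spacing: Triple) -> np.ndarray:
    """Isotropic expansion: all voxels within ``margin_mm`` (Euclidean, mm) of the set.

    Distances are taken to voxel centres, which sit on average a quarter
    voxel inside the continuous surface the mask approximates; the threshold
    is widened by that bias so expanded volumes track the analytic geometry
    (a zero margin remains an exact identity).
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be non-negative, got {margin_mm}")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm + 0.25 * float(np.mean(spacing))


def default_grid_for(template: PatientTemplate, spacing: float = 2.0, padding_mm: float = 24.0) -> GridSpec:
    """Axis-aligned lattice covering every organ with the requested padding."""
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)

    def _grow(center, extent):
        nonlocal lo, hi
        center = np.asarray(center, dtype=float)
        extent = np.asarray(extent, dtype=float)
        lo = np.minimum(lo, center - extent)
        hi = np.maximum(hi, center + extent)

    # allow for fill growth (1.6x volume), 10 mm shifts, margin, axis scaling
    grow = 1.6 ** (1.0 / 3.0)
    slack = 10.0 + DEFAULT_MARGIN_MM
    _grow(template.prostate_center, 1.3 * np.asarray(template.prostate_semiaxes) + slack)
    for c in template.sv_params[:2]:
        _grow(c, np.asarray(template.sv_params[2]) + slack)
    _grow(template.bladder_center, grow * template.bladder_base_radius)
    r = grow * template.rectum_base_radius
    p0, p1 = (np.asarray(p) for p in template.rectum_axis)
    _grow((p0 + p1) / 2, np.abs(p1 - p0) / 2 * grow + r)

    lo -= padding_mm
    hi += padding_mm
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    return GridSpec(shape=shape, spacing=(spacing,) * 3, origin=tuple(lo))


def _check_inside(grid: GridSpec, mask: np.ndarray, name: str) -> None:
    if (
        mask[0, :, :].any()
        or mask[-1, :, :].any()
        or mask[:, 0, :].any()
        or mask[:, -1, :].any()
        or mask[:, :, 0].any()
        or mask[:, :, -1].any()
    ):
        raise GridTooSmallError(f"structure {name!r} reaches the grid boundary")


def realize_structures(
    template: PatientTemplate,
    scenario: Optional[FractionScenario] = PLANNING,
    grid: Optional[GridSpec] = None,
    margin_mm: float = DEFAULT_MARGIN_MM,
    rectal_wall_deformation: bool = False,
) -> StructureSet:
    """Voxelise the (planning or daily) anatomy on the lattice.

    Daily anatomies shift and anisotropically rescale the target, and rescale
    bladder/rectum by the cube root of the fill scale so organ volume scales
    linearly with filling.
    """
    if grid is None:
        grid = default_grid_for(template)

    shift = np.zeros(3)
    axis_scales = np.ones(3)
    bladder_fill = rectum_fill = 1.0
    if scenario is not PLANNING and scenario is not None:
        shift = np.asarray(scenario.prostate_shift, dtype=float)
        axis_scales = np.asarray(scenario.target_axis_scales, dtype=float)
        bladder_fill = scenario.bladder_fill_scale
        rectum_fill = scenario.rectum_fill_scale

    p_center = np.asarray(template.prostate_center) + shift
    p_semiaxes = np.asarray(template.prostate_semiaxes) * axis_scales
    prostate = _ellipsoid_mask(grid, p_center, p_semiaxes)

    sv_left, sv_right, sv_semiaxes = template.sv_params
    sv = np.zeros(grid.shape, dtype=bool)
    for c in (sv_left, sv_right):
        sv |= _ellipsoid_mask(grid, np.asarray(c) + shift, sv_semiaxes)
    sv &= ~prostate

    # CTV: prostate plus the proximal 1 cm of the SV (measured from the SV base)
    sv_base_z = min(sv_left[2], sv_right[2]) - sv_semiaxes[2] + shift[2]
    _, _, gz = grid.coordinate_grids()
    proximal = np.broadcast_to(gz <= sv_base_z + CTV_SV_PROXIMAL_MM, grid.shape)
    ctv = prostate | (sv & proximal)
    ptv = expand_margin(ctv, margin_mm, grid.spacing)

    bladder_radius = template.bladder_base_radius * bladder_fill ** (1.0 / 3.0)
    bladder = _sphere_mask(grid, template.bladder_center, bladder_radius) & ~ctv

    # capsule: radius and cap-to-cap length both scale with the cube root of
    # the fill so the enclosed volume scales linearly
    rscale = rectum_fill ** (1.0 / 3.0)
    rectum_radius = template.rectum_base_radius * rscale
    p0, p1 = (np.asarray(p, dtype=float) for p in template.rectum_axis)
    mid = (p0 + p1) / 2.0
    p0 = mid + (p0 - mid) * rscale
    p1 = mid + (p1 - mid) * rscale
    rectum = _capsule_mask(grid, p0, p1, rectum_radius)

    if rectal_wall_deformation and scenario is not None:
        rng = np.random.default_rng(scenario.deformation_seed + 991)
        pocket_z = float(rng.uniform(p_center[2] - 15.0, p_center[2] + 15.0))
        pocket_r = float(rng.uniform(4.0, 9.0))
        pocket_c = (p0[0], p0[1] + rectum_radius * 0.8, pocket_z)
        rectum |= _sphere_mask(grid, pocket_c, pocket_r)
    rectum &= ~ctv  # delineated organs are mutually exclusive with the target

    masks = {
        "prostate": prostate,
        "sv": sv,
        "ctv": ctv,
        "ptv": ptv,
        "bladder": bladder,
        "rectum": rectum,
    }
    for name in ("ctv", "ptv", "bladder", "rectum"):
        if not masks[name].any():
            raise GridTooSmallError(f"structure {name!r} voxelised to empty")
        _check_inside(grid, masks[name], name)

    provenance = (
        "planning"
        if scenario is PLANNING or scenario is None
        else f"fraction {scenario.fraction_index}"
    )
    return StructureSet(grid=grid, masks=masks, provenance=provenance)


# --------------------------------------------------------------------------
# registration
# --------------------------------------------------------------------------


def _mask_centroid_mm(mask: np.ndarray, grid: GridSpec) -> np.ndarray:
    if not mask.any():
        raise ValueError("cannot register an empty mask")
    idx = np.argwhere(mask).mean(axis=0)
    return grid.index_to_physical(idx)


def rigid_register(
    planning_ctv: np.ndarray,
    daily_ctv: np.ndarray,
    grid: GridSpec,
    principal_axes: bool = False,
) -> RigidRegistration:
    """Centroid-matching rigid registration (translation = daily - planning).

    Rotations default to zero; the optional principal-axes mode estimates a
    rotation from second moments but is fragile on near-spherical targets.
    """
    t = _mask_centroid_mm(daily_ctv, grid) - _mask_centroid_mm(planning_ctv, grid)
    rotation = (0.0, 0.0, 0.0)
    if principal_axes:
        rotation = _principal_axes_rotation_deg(planning_ctv, daily_ctv, grid)
    return RigidRegistration(
        translation=tuple(float(v) for v in t), rotation_deg=rotation
    )


def _principal_axes_rotation_deg(
    planning: np.ndarray, daily: np.ndarray, grid: GridSpec
) -> Triple:
    from scipy.spatial.transform import Rotation

    def _axes(mask: np.ndarray) -> np.ndarray:
        pts = np.argwhere(mask) * np.asarray(grid.spacing)
        pts = pts - pts.mean(axis=0)
        _, vecs = np.linalg.eigh(np.cov(pts.T))
        # fix signs for comparability
        for i in range(3):
            if vecs[np.argmax(np.abs(vecs[:, i])), i] < 0:
                vecs[:, i] *= -1
        return vecs

    rot = _axes(daily) @ _axes(planning).T
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    angles = Rotation.from_matrix(rot).as_euler("xyz", degrees=True)
    angles = np.clip(angles, -10.0, 10.0)
    return tuple(float(a) for a in angles)


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientFraction:
    """One daily anatomy with its registration to the planning anatomy."""

    scenario: FractionScenario
    structures: StructureSet
    registration: RigidRegistration


@dataclass(frozen=True)
class SyntheticPatient:
    template: PatientTemplate
    planning: StructureSet
    fractions: Tuple[PatientFraction, ...]


def generate_cohort(
    master_seed: int,
    n_patients: int = 32,
    n_fractions: int = 5,
    cohort_params: CohortParams | None = None,
    spacing_mm: float = 2.0,
    shift_scale: float = 1.0,
) -> list[SyntheticPatient]:
    """Generate the full cohort; a pure function of (master_seed, settings).

    ``shift_scale`` multiplies the daily target-shift magnitude (used by the
    sensitivity analyses); fills and axis scales are unaffected.
    """
    params = cohort_params or CohortParams()
    patients = []
    for i in range(n_patients):
        template = generate_patient(
            derive_seed(master_seed, i), params, patient_id=f"P{i + 1}"
        )
        grid = default_grid_for(template, spacing=spacing_mm)
        planning = realize_structures(template, PLANNING, grid)
        fractions = []
        for k in range(1, n_fractions + 1):
            scenario = sample_scenario(derive_seed(master_seed, i, k), k, params)
            if shift_scale != 1.0:
                shifted = np.asarray(scenario.prostate_shift) * shift_scale
                norm = float(np.linalg.norm(shifted))
                if norm > params.shift_cap_mm:
                    shifted *= params.shift_cap_mm / norm
                scenario = replace(
                    scenario, prostate_shift=tuple(float(s) for s in shifted)
                )
            daily = realize_structures(template, scenario, grid)
            registration = rigid_register(planning["ctv"], daily["ctv"], grid)
            fractions.append(
                PatientFraction(
                    scenario=scenario, structures=daily, registration=registration
                )
            )
        patients.append(
            SyntheticPatient(
                template=template, planning=planning, fractions=tuple(fractions)
            )
        )
    return patients
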