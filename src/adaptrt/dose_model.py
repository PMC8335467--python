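"""Parametric dose engine for the reference plan and four adaptation archetypes.

The engine replaces a treatment planning system with an explicit model:
a dose plateau inside the PTV with a Gaussian lateral falloff outside it,
optional organ-at-risk sparing (full re-optimisation archetype), a smooth
multiplicative noise field, rigid dose transport for the non-adaptive
archetype, and the coverage rescaling rule that normalises adapted plans to
D_95%(CTV) = 40 Gy.

Archetypes
----------
REFERENCE  plan on the planning anatomy, never rescaled.
IGRT       reference dose copied rigidly onto the daily anatomy, never rescaled.
ART1       re-shaped to the daily PTV (weight-level adaptation), rescaled.
ART2       re-shaped with a slightly tighter penumbra (shape optimisation), rescaled.
ART3       full re-optimisation: tightest penumbra plus OAR sparing, rescaled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .dvh_metrics import EvaluationError, d_volume
from .grid import DoseGrid, GridSpec, LatticeMismatchError, StructureSet
from .synthetic_cohort import RigidRegistration


class ApproachKind(str, enum.Enum):
    REFERENCE = "REFERENCE"
    IGRT = "IGRT"
    ART1 = "ART1"
    ART2 = "ART2"
    ART3 = "ART3"

    @classmethod
    def adaptation_approaches(cls) -> tuple["ApproachKind", ...]:
        return (cls.IGRT, cls.ART1, cls.ART2, cls.ART3)


@dataclass(frozen=True)
class DoseModelParams:
    """Archetype parameters of the virtual dose engine.

    ``penumbra_sigma_mm`` controls the Gaussian falloff outside the PTV per
    approach; ``conformity_degradation`` widens it multiplicatively. The
    defaults order the archetypes so that the non-adaptive and weight-only
    plans have the broadest penumbra and the full re-optimisation the
    tightest, with additional explicit OAR sparing for the latter.
    """

    prescription_ctv_gy: float = 40.0
    prescription_ptv_gy: float = 36.25
    interior_boost: float = 41.0 / 36.25 - 1.0  # plateau 41 Gy inside the PTV
    penumbra_sigma_mm: Mapping[str, float] = field(
        default_factory=lambda: {
            "REFERENCE": 5.0,
            "IGRT": 5.0,
            "ART1": 5.0,
            "ART2": 4.6,
            "ART3": 4.0,
        }
    )
    conformity_degradation: Mapping[str, float] = field(
        default_factory=lambda: {
            "REFERENCE": 0.0,
            "IGRT": 0.0,
            "ART1": 0.05,
            "ART2": 0.02,
            "ART3": 0.0,
        }
    )
    oar_sparing_depth: float = 0.35  # ART3 only
    oar_interface_margin_mm: float = 3.0
    # interior carving applied by every optimised plan to ITS anatomy's OARs:
    # dose is reduced with depth into the organ, sparing all but a surface
    # shell whose thickness reflects how tight the organ's constraint is
    oar_protect_depth: float = 0.30
    oar_protect_wall_mm: Mapping[str, float] = field(
        default_factory=lambda: {"bladder": 4.5, "rectum": 2.0, "default": 3.0}
    )
    oar_protect_ramp_mm: float = 4.0
    noise_amplitude: float = 0.01
    noise_correlation_mm: float = 8.0
    coverage_volume_pct: float = 95.0
    apply_rotation: bool = False

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.penumbra_sigma_mm.values()):
            raise ValueError("penumbra sigmas must be positive")
        if not 0.0 <= self.oar_sparing_depth <= 1.0:
            raise ValueError("sparing depth must lie in [0, 1]")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")

    def plateau_gy(self) -> float:
        return self.prescription_ptv_gy * (1.0 + self.interior_boost)

    def sigma_for(self, approach: "ApproachKind") -> float:
        s = self.penumbra_sigma_mm[approach.value]
        return s * (1.0 + self.conformity_degradation.get(approach.value, 0.0))


def _noise_field(
    grid: GridSpec, amplitude: float, correlation_mm: float, seed: int
) -> np.ndarray:
    """Smooth positive multiplicative field, mean 1, relative spread ~amplitude."""
    if amplitude == 0:
        return np.ones(grid.shape)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(grid.shape)
    sigma_vox = [correlation_mm / s for s in grid.spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    sd = smooth.std()
    if sd == 0:
        return np.ones(grid.shape)
    fieldv = np.exp(amplitude * smooth / sd)
    return fieldv / fieldv.mean()


def ptv_distance(ptv: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Exact Euclidean distance (mm) to the PTV set, zero inside it."""
    ptv = np.asarray(ptv, dtype=bool)
    if not ptv.any():
        raise EvaluationError("PTV mask is empty")
    return ndimage.distance_transform_edt(~ptv, sampling=grid.spacing)


def conformal_dose(
    ptv: np.ndarray,
    grid: GridSpec,
    params: DoseModelParams,
    approach: ApproachKind,
    noise_seed: int,
    dist: np.ndarray | None = None,
) -> DoseGrid:
    """Plateau-plus-Gaussian-falloff dose shaped to the PTV.

    D(x) = plateau * exp(-d(x)^2 / (2 sigma^2)) with d the Euclidean distance
    to the PTV set (zero inside), times a smooth multiplicative noise field.
    A precomputed distance map may be passed to share work across approaches.
    """
    if dist is None:
        dist = ptv_distance(ptv, grid)
    sigma = params.sigma_for(approach)
    dose = params.plateau_gy() * np.exp(-(dist**2) / (2.0 * sigma**2))
    dose *= _noise_field(
        grid, params.noise_amplitude, params.noise_correlation_mm, noise_seed
    )
    return DoseGrid(grid, dose)


def oar_carve_factor(
    oars: Mapping[str, np.ndarray], grid: GridSpec, params: DoseModelParams
) -> np.ndarray:
    """Multiplicative carving field an optimiser imposes inside its OARs.

    Every optimised plan (reference and all re-optimised archetypes) trades
    dose deep inside an organ at risk for coverage at the interface: the
    factor is 1 within a surface shell of ``oar_protect_wall_mm`` and ramps
    down to ``1 - oar_protect_depth`` over ``oar_protect_ramp_mm`` of depth.
    The copied, non-adaptive plan transports a carving frozen to the planning
    anatomy, which is what makes it degrade under daily organ changes.
    """
    factor = np.ones(grid.shape)
    if params.oar_protect_depth == 0:
        return factor
    walls = params.oar_protect_wall_mm
    for name, mask in oars.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise LatticeMismatchError("OAR mask does not share the lattice")
        if not mask.any():
            continue
        wall = walls.get(name, walls.get("default", 3.0))
        depth = ndimage.distance_transform_edt(mask, sampling=grid.spacing)
        w = np.clip((depth - wall) / params.oar_protect_ramp_mm, 0.0, 1.0)
        factor = np.minimum(factor, 1.0 - params.oar_protect_depth * w)
    return factor


def oar_spare(
    dose: DoseGrid,
    oars: Mapping[str, np.ndarray],
    ptv: np.ndarray,
    params: DoseModelParams,
    dist: np.ndarray | None = None,
) -> DoseGrid:
    """Reduce dose inside OARs away from the PTV interface (full re-optimisation).

    Within each OAR the dose is multiplied by ``1 - depth * w(d)`` where d is
    the distance to the PTV surface, w = 0 up to the interface margin m,
    ramps linearly to 1 at 2 m, and saturates beyond.
    """
    if params.oar_sparing_depth == 0:
        return DoseGrid(dose.grid, dose.values.copy())
    if dist is None:
        dist = ptv_distance(ptv, dose.grid)
    m = params.oar_interface_margin_mm
    w = np.clip((dist - m) / m, 0.0, 1.0)
    factor = np.ones(dose.grid.shape)
    for mask in oars.values():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != dose.grid.shape:
            raise LatticeMismatchError("OAR mask does not share the dose lattice")
        factor[mask] = np.minimum(
            factor[mask], 1.0 - params.oar_sparing_depth * w[mask]
        )
    return DoseGrid(dose.grid, dose.values * factor)


def transform_dose(
    reference_dose: DoseGrid,
    registration: RigidRegistration,
    rotation_center_mm: np.ndarray | None = None,
    apply_rotation: bool = False,
) -> DoseGrid:
    """Rigidly transport a dose grid: output(x) = input(T^-1 x), trilinear.

    The translation moves the dose along with the registered target; voxels
    sampling outside the source grid receive 0 Gy. Rotation (about the
    planning target centroid) is applied only when requested.
    """
    grid = reference_dose.grid
    shift_vox = np.asarray(registration.translation) / np.asarray(grid.spacing)
    rot = np.asarray(registration.rotation_deg, dtype=float)
    if not apply_rotation or np.allclose(rot, 0.0):
        values = ndimage.shift(
            reference_dose.values, shift_vox, order=1, mode="constant", cval=0.0
        )
    else:
        from scipy.spatial.transform import Rotation

        rmat = Rotation.from_euler("xyz", rot, degrees=True).as_matrix()
        center = (
            np.asarray(rotation_center_mm)
            if rotation_center_mm is not None
            else np.asarray(grid.origin)
            + np.asarray(grid.spacing) * (np.asarray(grid.shape) - 1) / 2.0
        )
        spacing = np.asarray(grid.spacing)
        origin = np.asarray(grid.origin)
        # index -> physical, inverse-rotate/translate, physical -> index
        rinv = rmat.T
        matrix = np.diag(1.0 / spacing) @ rinv @ np.diag(spacing)
        t_phys = np.asarray(registration.translation)
        offset_phys = rinv @ (origin - center - t_phys) + center - origin
        offset = offset_phys / spacing
        values = ndimage.affine_transform(
            reference_dose.values, matrix, offset=offset, order=1, cval=0.0
        )
    return DoseGrid(grid, np.maximum(values, 0.0))


def rescale_to_coverage(
    dose: DoseGrid,
    ctv: np.ndarray,
    target_dose_gy: float = 40.0,
    target_volume_pct: float = 95.0,
) -> DoseGrid:
    """Scale so the CTV coverage dose D_p% equals the prescription exactly."""
    current = d_volume(dose, ctv, target_volume_pct)
    if current <= 0:
        raise EvaluationError("CTV receives no dose; cannot rescale")
    return dose.scaled(target_dose_gy / current)


def reference_plan(
    planning: StructureSet,
    params: DoseModelParams,
    seed: int,
    oar_names: tuple[str, ...] = ("bladder", "rectum"),
) -> DoseGrid:
    """Optimised plan on the planning anatomy: conformal dose with OAR carving."""
    dose = conformal_dose(
        planning["ptv"], planning.grid, params, ApproachKind.REFERENCE, seed
    )
    oars = {n: planning[n] for n in oar_names if n in planning}
    factor = oar_carve_factor(oars, planning.grid, params)
    return DoseGrid(planning.grid, dose.values * factor)


def make_plan(
    approach: ApproachKind,
    planning: StructureSet,
    daily: StructureSet,
    registration: RigidRegistration,
    params: DoseModelParams,
    seed: int,
    reference_dose: DoseGrid | None = None,
    daily_ptv_distance: np.ndarray | None = None,
    daily_carve_factor: np.ndarray | None = None,
    info: dict | None = None,
) -> DoseGrid:
    """Build the dose distribution of one archetype on the daily anatomy.

    The reference dose (conformal plan on the planning PTV) can be passed in
    to avoid recomputation; it is built on demand otherwise. The noise seed
    of the reference plan is tied to the planning anatomy, not the fraction,
    because a single physical plan is reused across fractions.
    """
    if not planning.grid.same_lattice(daily.grid):
        raise LatticeMismatchError("planning and daily anatomies must share a lattice")
    if not isinstance(approach, ApproachKind):
        raise ValueError(f"unknown approach {approach!r}")

    if approach in (ApproachKind.REFERENCE, ApproachKind.IGRT):
        if info is not None:
            info["rescale_factor"] = 1.0  # copied unaltered, never rescaled
        if reference_dose is None:
            reference_dose = reference_plan(planning, params, seed)
        if approach is ApproachKind.REFERENCE:
            return reference_dose
        return transform_dose(
            reference_dose,
            registration,
            rotation_center_mm=planning.centroid_mm("ctv"),
            apply_rotation=params.apply_rotation,
        )

    dist = daily_ptv_distance
    if dist is None:
        dist = ptv_distance(daily["ptv"], daily.grid)
    dose = conformal_dose(daily["ptv"], daily.grid, params, approach, seed, dist=dist)
    if daily_carve_factor is None:
        daily_oars = {
            n: daily[n] for n in ("bladder", "rectum") if n in daily
        }
        daily_carve_factor = oar_carve_factor(daily_oars, daily.grid, params)
    dose = DoseGrid(daily.grid, dose.values * daily_carve_factor)
    if approach is ApproachKind.ART3:
        oars = {name: daily[name] for name in ("bladder", "rectum") if name in daily}
        dose = oar_spare(dose, oars, daily["ptv"], params, dist=dist)
    if info is not None:
        current = d_volume(dose, daily["ctv"], params.coverage_volume_pct)
        info["rescale_factor"] = params.prescription_ctv_gy / current
    return rescale_to_coverage(
        dose,
        daily["ctv"],
        target_dose_gy=params.prescription_ctv_gy,
        target_volume_pct=params.coverage_volume_pct,
    )
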