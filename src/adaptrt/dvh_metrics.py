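"""Cumulative DVH curves and voxel-exact dose-volume / geometric metrics.

Point metrics (V_xGy, D_x%) are computed directly from the voxel dose values,
never from a binned curve, so the penalty scoring is independent of the DVH
bin width. Binned curves exist for plotting and point-wise cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence, Tuple

import numpy as np

from .grid import DoseGrid, GridSpec, LatticeMismatchError

DEFAULT_BIN_WIDTH_GY = 0.05


class EvaluationError(ValueError):
    """A metric could not be evaluated (e.g. empty structure)."""


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume curve: volume receiving at least each dose edge."""

    dose_edges: np.ndarray  # Gy, uniform
    volume_cc: np.ndarray
    structure_volume_cc: float

    @property
    def volume_pct(self) -> np.ndarray:
        return 100.0 * self.volume_cc / self.structure_volume_cc

    def __post_init__(self) -> None:
        if self.dose_edges.shape != self.volume_cc.shape:
            raise ValueError("edge and volume arrays must align")
        if np.any(np.diff(self.volume_cc) > 1e-12):
            raise ValueError("cumulative volume must be non-increasing")


def _masked_doses(dose: DoseGrid, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.grid.shape:
        raise LatticeMismatchError("mask does not share the dose lattice")
    if not mask.any():
        raise EvaluationError("structure mask is empty")
    return dose.values[mask]


def cumulative_dvh(
    dose: DoseGrid,
    mask: np.ndarray,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
    max_dose_gy: float | None = None,
) -> DVHCurve:
    """Cumulative DVH: bin b holds the volume with dose >= edge b."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    vals = _masked_doses(dose, mask)
    top = float(max_dose_gy) if max_dose_gy is not None else float(vals.max())
    n_bins = int(np.ceil(top / bin_width_gy)) + 2
    edges = np.arange(n_bins) * bin_width_gy
    vals_sorted = np.sort(vals)
    # voxels with dose >= edge, via position of the first such voxel
    n_ge = vals.size - np.searchsorted(vals_sorted, edges, side="left")
    voxel_cc = dose.grid.voxel_volume_cc
    return DVHCurve(
        dose_edges=edges,
        volume_cc=n_ge * voxel_cc,
        structure_volume_cc=vals.size * voxel_cc,
    )


def v_dose(
    dose: DoseGrid,
    mask: np.ndarray,
    threshold_gy: float,
    mode: Literal["cc", "pct"] = "cc",
) -> float:
    """Volume receiving at least ``threshold_gy``, voxel-exact."""
    if threshold_gy < 0:
        raise ValueError("threshold must be non-negative")
    vals = _masked_doses(dose, mask)
    n = int(np.count_nonzero(vals >= threshold_gy))
    if mode == "cc":
        return n * dose.grid.voxel_volume_cc
    if mode == "pct":
        return 100.0 * n / vals.size
    raise ValueError(f"unknown mode {mode!r}")


def d_volume(dose: DoseGrid, mask: np.ndarray, volume_pct: float) -> float:
    """Minimum dose to the hottest ``volume_pct`` of the structure.

    Implemented as the (100 - p) percent quantile of the voxel doses with
    linear interpolation between order statistics.
    """
    if not 0 < volume_pct <= 100:
        raise ValueError("volume percentage must be in (0, 100]")
    vals = _masked_doses(dose, mask)
    return float(np.quantile(vals, 1.0 - volume_pct / 100.0, method="linear"))


def overlap_volume(a: np.ndarray, b: np.ndarray, grid: GridSpec) -> float:
    """Volume (cc) of the intersection of two masks on one lattice."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != grid.shape or b.shape != grid.shape:
        raise LatticeMismatchError("masks do not share the lattice")
    return float(np.count_nonzero(a & b)) * grid.voxel_volume_cc


def pointwise_dvh_stats(
    curves: Sequence[DVHCurve],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin mean and sample SD (ddof=1) of relative-volume curves.

    Returns (dose_edges, mean_pct, sd_pct). All curves must share a dose axis.
    """
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    edges = curves[0].dose_edges
    for c in curves[1:]:
        if c.dose_edges.shape != edges.shape or not np.allclose(
            c.dose_edges, edges
        ):
            raise ValueError("curves must share the dose axis")
    stack = np.stack([c.volume_pct for c in curves])
    return edges, stack.mean(axis=0), stack.std(axis=0, ddof=1)


def align_curves(curves: Iterable[DVHCurve], bin_width_gy: float, max_dose_gy: float) -> list[DVHCurve]:
    """Pad curves with zeros onto one common dose axis."""
    n_bins = int(np.ceil(max_dose_gy / bin_width_gy)) + 2
    edges = np.arange(n_bins) * bin_width_gy
    out = []
    for c in curves:
        vol = np.zeros(n_bins)
        k = min(n_bins, c.volume_cc.size)
        vol[:k] = c.volume_cc[:k]
        out.append(
            DVHCurve(
                dose_edges=edges,
                volume_cc=vol,
                structure_volume_cc=c.structure_volume_cc,
            )
        )
    return out
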