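"""Dose-criterion evaluation, tiering and the penalty score S.

A criterion compares one dose-volume metric M against a protocol bound C.
The penalty contribution of an exceeded criterion is ``|(M - C) / C| * 100``;
criteria that are met (including exactly at the bound) contribute zero. The
plan score S sums the four scoring criteria: V_36.25Gy(PTV), D_98%(PTV),
V_37Gy(bladder) and V_36Gy(rectum). Target coverage V_40Gy(CTV) is tiered
but never scored, because adapted plans are normalised to D_95%(CTV).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import dvh_metrics
from .grid import DoseGrid, StructureSet

PENALTY_CRITERIA = ("ptv_v36.25", "ptv_d98", "bladder_v37", "rectum_v36")


class ConfigurationError(ValueError):
    pass


class EvaluationError(ValueError):
    pass


class Tier(str, enum.Enum):
    OPTIMAL = "optimal"
    MINOR = "minor"
    VIOLATION = "violation"


@dataclass(frozen=True)
class DoseCriterion:
    """One protocol constraint on a dose-volume metric."""

    name: str
    structure: str
    metric: Literal["V", "D"]
    bound: float
    direction: Literal["upper", "lower"]
    threshold_gy: Optional[float] = None  # V metrics
    unit: Literal["cc", "pct"] = "cc"  # V metrics
    volume_pct: Optional[float] = None  # D metrics
    minor_band: Optional[Tuple[float, float]] = None
    in_penalty: bool = False
    optional: bool = False

    def __post_init__(self) -> None:
        if self.bound <= 0:
            raise ConfigurationError(
                f"{self.name}: bound must be positive for relative penalties"
            )
        if self.metric == "V" and self.threshold_gy is None:
            raise ConfigurationError(f"{self.name}: V metric needs threshold_gy")
        if self.metric == "D" and self.volume_pct is None:
            raise ConfigurationError(f"{self.name}: D metric needs volume_pct")
        if self.minor_band is not None:
            lo, hi = self.minor_band
            if self.direction == "lower" and not hi <= self.bound:
                raise ConfigurationError(
                    f"{self.name}: minor band must lie below a lower bound"
                )
            if self.direction == "upper" and not lo >= self.bound:
                raise ConfigurationError(
                    f"{self.name}: minor band must lie above an upper bound"
                )

    def measure(self, dose: DoseGrid, structures: StructureSet) -> float:
        if self.structure not in structures:
            raise EvaluationError(f"structure {self.structure!r} missing")
        mask = structures[self.structure]
        if self.metric == "V":
            return dvh_metrics.v_dose(dose, mask, self.threshold_gy, mode=self.unit)
        return dvh_metrics.d_volume(dose, mask, self.volume_pct)


@dataclass(frozen=True)
class CriterionResult:
    criterion: DoseCriterion
    measured_value: float
    tier: Tier
    penalty_contribution: float


@dataclass(frozen=True)
class PlanEvaluation:
    """All criterion results for one (patient, fraction, approach) plan."""

    patient: str
    fraction: int
    approach: str
    results: Tuple[CriterionResult, ...]
    overlap_volumes_cc: Dict[str, float] = field(default_factory=dict)

    @property
    def total_penalty(self) -> float:
        return plan_penalty(self.results)

    def result(self, name: str) -> CriterionResult:
        for r in self.results:
            if r.criterion.name == name:
                return r
        raise KeyError(name)


def penalty_score(
    measured: float, bound: float, direction: Literal["upper", "lower"]
) -> float:
    """Relative percentage deviation, counted only when the bound is exceeded.

    A measured value exactly at the bound is treated as not exceeded.
    """
    if bound <= 0:
        raise ConfigurationError("bound must be positive")
    exceeded = measured > bound if direction == "upper" else measured < bound
    if not exceeded:
        return 0.0
    return abs((measured - bound) / bound) * 100.0


def _tier(criterion: DoseCriterion, measured: float) -> Tier:
    met = (
        measured >= criterion.bound
        if criterion.direction == "lower"
        else measured <= criterion.bound
    )
    if met:
        return Tier.OPTIMAL
    if criterion.minor_band is not None:
        lo, hi = criterion.minor_band
        if lo <= measured <= hi:
            return Tier.MINOR
    return Tier.VIOLATION


def evaluate_criterion(
    dose: DoseGrid, structures: StructureSet, criterion: DoseCriterion
) -> CriterionResult:
    measured = criterion.measure(dose, structures)
    return CriterionResult(
        criterion=criterion,
        measured_value=measured,
        tier=_tier(criterion, measured),
        penalty_contribution=penalty_score(
            measured, criterion.bound, criterion.direction
        ),
    )


def evaluate_plan(
    dose: DoseGrid,
    structures: StructureSet,
    criteria: Sequence[DoseCriterion],
    patient: str = "",
    fraction: int = 0,
    approach: str = "",
    overlap_volumes_cc: Optional[Dict[str, float]] = None,
) -> PlanEvaluation:
    """Evaluate all criteria whose structures exist (optional ones may be absent)."""
    results = []
    for criterion in criteria:
        if criterion.structure not in structures:
            if criterion.optional:
                continue
            raise EvaluationError(f"structure {criterion.structure!r} missing")
        results.append(evaluate_criterion(dose, structures, criterion))
    return PlanEvaluation(
        patient=patient,
        fraction=fraction,
        approach=approach,
        results=tuple(results),
        overlap_volumes_cc=dict(overlap_volumes_cc or {}),
    )


def plan_penalty(results: Sequence[CriterionResult]) -> float:
    """Sum of the four scoring-criterion contributions; all must be present."""
    by_name = {r.criterion.name: r for r in results if r.criterion.in_penalty}
    missing = [n for n in PENALTY_CRITERIA if n not in by_name]
    if missing:
        raise EvaluationError(f"missing scoring criteria: {missing}")
    return float(sum(by_name[n].penalty_contribution for n in PENALTY_CRITERIA))


# --------------------------------------------------------------------------
# criterion configuration
# --------------------------------------------------------------------------


def load_criteria(path: Optional[str] = None) -> List[DoseCriterion]:
    """Load the criterion table from YAML (the shipped protocol by default)."""
    if path is None:
        text = (
            resources.files("adaptrt.data")
            .joinpath("pace_c_criteria.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    criteria = []
    for entry in raw["criteria"]:
        entry = dict(entry)
        if "minor_band" in entry and entry["minor_band"] is not None:
            entry["minor_band"] = tuple(entry["minor_band"])
        criteria.append(DoseCriterion(**entry))
    names = [c.name for c in criteria]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate criterion names")
    return criteria


# --------------------------------------------------------------------------
# cohort aggregation (printed-table twin)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PenaltyTable:
    """Two aggregations of S over a cohort.

    ``per_criterion``: criterion rows x approach columns, summed over all
    plans, plus a ``total`` row. ``per_patient``: patient rows x approach
    columns holding the mean over fractions, with a matching SD frame and a
    cohort-mean row appended.
    """

    per_criterion: pd.DataFrame
    per_patient_mean: pd.DataFrame
    per_patient_sd: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        return self.per_criterion.loc["total"]

    @property
    def cohort_means(self) -> pd.Series:
        return self.per_patient_mean.loc["mean"]


def cohort_penalty_table(evaluations: Sequence[PlanEvaluation]) -> PenaltyTable:
    """Aggregate plan evaluations into the per-criterion / per-patient table.

    Requires a full patients x fractions grid per approach (the reference
    approach may have a single planning 'fraction').
    """
    if not evaluations:
        raise ValueError("no evaluations given")
    rows = []
    for ev in evaluations:
        for r in ev.results:
            if r.criterion.in_penalty:
                rows.append(
                    {
                        "patient": ev.patient,
                        "fraction": ev.fraction,
                        "approach": ev.approach,
                        "criterion": r.criterion.name,
                        "penalty": r.penalty_contribution,
                    }
                )
    df = pd.DataFrame(rows)

    counts = df.pivot_table(
        index="patient", columns="approach", values="fraction", aggfunc="nunique"
    )
    for approach in counts.columns:
        if counts[approach].nunique() != 1:
            raise ValueError(
                f"ragged cohort: unequal fraction counts for approach {approach}"
            )

    per_criterion = df.pivot_table(
        index="criterion", columns="approach", values="penalty", aggfunc="sum"
    ).reindex(list(PENALTY_CRITERIA))
    per_criterion.loc["total"] = per_criterion.sum(axis=0)

    per_plan = (
        df.groupby(["patient", "approach", "fraction"])["penalty"].sum().reset_index()
    )
    mean = per_plan.pivot_table(
        index="patient", columns="approach", values="penalty", aggfunc="mean"
    )
    sd = per_plan.pivot_table(
        index="patient",
        columns="approach",
        values="penalty",
        aggfunc=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
    )
    order = sorted(mean.index, key=lambda p: (len(p), p))
    mean = mean.loc[order]
    sd = sd.loc[order]
    mean.loc["mean"] = mean.mean(axis=0)
    sd.loc["mean"] = mean.drop(index="mean").std(axis=0, ddof=1)
    return PenaltyTable(
        per_criterion=per_criterion, per_patient_mean=mean, per_patient_sd=sd
    )


def percent_reduction(s_adapt: float, s_igrt: float) -> float:
    """Relative penalty reduction vs the non-adaptive approach, one decimal."""
    if s_igrt <= 0:
        raise EvaluationError("reference penalty must be positive")
    return round(100.0 * (1.0 - s_adapt / s_igrt), 1)


# --------------------------------------------------------------------------
# printed-table fixture
# --------------------------------------------------------------------------


def load_printed_table(path: Optional[str] = None) -> pd.DataFrame:
    """Tidy fixture of the published per-criterion and per-patient scores."""
    if path is None:
        with resources.files("adaptrt.data").joinpath("table3_printed.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def printed_per_criterion(fixture: pd.DataFrame) -> pd.DataFrame:
    """Criterion rows x approach columns of the printed per-criterion sums."""
    sub = fixture[fixture["panel"] == "criterion"]
    return sub.pivot(index="row", columns="approach", values="value").reindex(
        list(PENALTY_CRITERIA)
    )


def printed_per_patient(fixture: pd.DataFrame) -> pd.DataFrame:
    """Patient rows x approach columns of the printed per-patient mean scores."""
    sub = fixture[fixture["panel"] == "patient"]
    table = sub.pivot(index="row", columns="approach", values="value")
    return table.loc[sorted(table.index, key=lambda p: int(p[1:]))]
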