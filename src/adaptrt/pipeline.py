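"""End-to-end study orchestration: cohort -> plans -> evaluations -> reports.

The default study generates 32 patients x 5 fractions, builds one reference
plan per patient and four adaptation plans per fraction (640 adaptation plans
in total), evaluates all shipped dose criteria, and aggregates penalty
scores, paired statistics, overlap-volume triggers and mean DVH curves.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (
    TriggerReport,
    overlap_penalty_correlation,
    paired_t_test,
    trigger_analysis,
)
from .criteria_penalty import (
    PENALTY_CRITERIA,
    DoseCriterion,
    PenaltyTable,
    PlanEvaluation,
    cohort_penalty_table,
    evaluate_plan,
    load_criteria,
    load_printed_table,
    percent_reduction,
    printed_per_criterion,
    printed_per_patient,
)
from .dose_model import (
    ApproachKind,
    DoseModelParams,
    make_plan,
    oar_carve_factor,
    ptv_distance,
    reference_plan,
)
from .dvh_metrics import DVHCurve, align_curves, cumulative_dvh, overlap_volume, pointwise_dvh_stats
from .synthetic_cohort import (
    CohortParams,
    SyntheticPatient,
    derive_seed,
    generate_cohort,
)

DVH_STRUCTURES = ("ctv", "ptv", "bladder", "rectum")


@dataclass(frozen=True)
class StudyConfig:
    master_seed: int = 20210804
    n_patients: int = 32
    n_fractions: int = 5
    spacing_mm: float = 2.0
    shift_scale: float = 1.0
    cohort: CohortParams = field(default_factory=CohortParams)
    dose: DoseModelParams = field(default_factory=DoseModelParams)
    criteria_path: Optional[str] = None
    dvh_bin_width_gy: float = 0.05

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortParams(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in kwargs["cohort"].items()
            })
        if "dose" in kwargs:
            kwargs["dose"] = DoseModelParams(**kwargs["dose"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class StudyResult:
    config: StudyConfig
    evaluations: List[PlanEvaluation]  # adaptation plans, per fraction
    reference_evaluations: List[PlanEvaluation]  # one per patient, planning anatomy
    penalty_table: PenaltyTable
    statistics: pd.DataFrame
    triggers: Dict[str, Dict[str, TriggerReport]]  # approach -> organ -> report
    correlations: pd.DataFrame
    dvh_stats: pd.DataFrame

    def evaluations_for(self, approach: ApproachKind | str) -> List[PlanEvaluation]:
        name = approach.value if isinstance(approach, ApproachKind) else approach
        return [ev for ev in self.evaluations if ev.approach == name]

    def total_penalty(self, approach: ApproachKind | str) -> float:
        name = approach.value if isinstance(approach, ApproachKind) else approach
        return float(self.penalty_table.totals[name])


# --------------------------------------------------------------------------
# study execution
# --------------------------------------------------------------------------


def simulate_cohort(config: StudyConfig) -> List[SyntheticPatient]:
    return generate_cohort(
        master_seed=config.master_seed,
        n_patients=config.n_patients,
        n_fractions=config.n_fractions,
        cohort_params=config.cohort,
        spacing_mm=config.spacing_mm,
        shift_scale=config.shift_scale,
    )


def evaluate_patient(
    patient: SyntheticPatient,
    patient_index: int,
    config: StudyConfig,
    criteria: Sequence[DoseCriterion],
    collect_dvh: bool = False,
) -> Tuple[PlanEvaluation, List[PlanEvaluation], Dict[str, List[Tuple[str, DVHCurve]]]]:
    """Reference evaluation, per-fraction adaptation evaluations, DVH curves."""
    params = config.dose
    ref_seed = derive_seed(config.master_seed, patient_index, 10_000)
    reference_dose = reference_plan(patient.planning, params, ref_seed)
    planning_overlaps = {
        organ: overlap_volume(
            patient.planning["ptv"], patient.planning[organ], patient.planning.grid
        )
        for organ in ("bladder", "rectum")
    }
    reference_eval = evaluate_plan(
        reference_dose,
        patient.planning,
        criteria,
        patient=patient.template.patient_id,
        fraction=0,
        approach=ApproachKind.REFERENCE.value,
        overlap_volumes_cc=planning_overlaps,
    )

    evaluations: List[PlanEvaluation] = []
    curves: Dict[str, List[Tuple[str, DVHCurve]]] = {
        a.value: [] for a in ApproachKind.adaptation_approaches()
    }
    max_dose = params.prescription_ctv_gy * 1.25
    for frac in patient.fractions:
        daily = frac.structures
        overlaps = {
            organ: overlap_volume(daily["ptv"], daily[organ], daily.grid)
            for organ in ("bladder", "rectum")
        }
        dist = ptv_distance(daily["ptv"], daily.grid)
        carve = oar_carve_factor(
            {n: daily[n] for n in ("bladder", "rectum")}, daily.grid, params
        )
        for j, approach in enumerate(ApproachKind.adaptation_approaches()):
            seed = derive_seed(
                config.master_seed, patient_index, frac.scenario.fraction_index, j
            )
            dose = make_plan(
                approach,
                patient.planning,
                daily,
                frac.registration,
                params,
                seed,
                reference_dose=reference_dose,
                daily_ptv_distance=dist,
                daily_carve_factor=carve,
            )
            evaluations.append(
                evaluate_plan(
                    dose,
                    daily,
                    criteria,
                    patient=patient.template.patient_id,
                    fraction=frac.scenario.fraction_index,
                    approach=approach.value,
                    overlap_volumes_cc=overlaps,
                )
            )
            if collect_dvh:
                for structure in DVH_STRUCTURES:
                    curve = cumulative_dvh(
                        dose,
                        daily[structure],
                        bin_width_gy=config.dvh_bin_width_gy,
                        max_dose_gy=max_dose,
                    )
                    curves[approach.value].append((structure, curve))
    return reference_eval, evaluations, curves


def run_study(config: StudyConfig, collect_dvh: bool = True) -> StudyResult:
    """Execute the full synthetic study in memory."""
    criteria = load_criteria(config.criteria_path)
    patients = simulate_cohort(config)
    reference_evals: List[PlanEvaluation] = []
    evaluations: List[PlanEvaluation] = []
    all_curves: Dict[str, List[Tuple[str, DVHCurve]]] = {
        a.value: [] for a in ApproachKind.adaptation_approaches()
    }
    for i, patient in enumerate(patients):
        ref_eval, evs, curves = evaluate_patient(
            patient, i, config, criteria, collect_dvh=collect_dvh
        )
        reference_evals.append(ref_eval)
        evaluations.extend(evs)
        for name, lst in curves.items():
            all_curves[name].extend(lst)

    penalty_table = cohort_penalty_table(evaluations + reference_evals)
    statistics = _paired_statistics(evaluations)
    triggers, correlations = _trigger_and_correlation(evaluations)
    dvh_stats = (
        _dvh_statistics(all_curves, config) if collect_dvh else pd.DataFrame()
    )
    return StudyResult(
        config=config,
        evaluations=evaluations,
        reference_evaluations=reference_evals,
        penalty_table=penalty_table,
        statistics=statistics,
        triggers=triggers,
        correlations=correlations,
        dvh_stats=dvh_stats,
    )


def _metric_matrix(evaluations: Sequence[PlanEvaluation]) -> pd.DataFrame:
    rows = []
    for ev in evaluations:
        row = {
            "patient": ev.patient,
            "fraction": ev.fraction,
            "approach": ev.approach,
            "S": ev.total_penalty,
            "overlap_bladder_cc": ev.overlap_volumes_cc.get("bladder"),
            "overlap_rectum_cc": ev.overlap_volumes_cc.get("rectum"),
        }
        for r in ev.results:
            row[r.criterion.name] = r.measured_value
            row[f"tier_{r.criterion.name}"] = r.tier.value
        rows.append(row)
    return pd.DataFrame(rows)


def _paired_statistics(evaluations: Sequence[PlanEvaluation]) -> pd.DataFrame:
    """Paired t-tests between approaches for each scoring-criterion metric."""
    df = _metric_matrix(evaluations)
    approaches = [a.value for a in ApproachKind.adaptation_approaches()]
    rows = []
    for metric in PENALTY_CRITERIA:
        wide = df.pivot_table(
            index=["patient", "fraction"], columns="approach", values=metric
        )
        for i, a in enumerate(approaches):
            for b in approaches[i + 1 :]:
                t, p = paired_t_test(wide[a].to_numpy(), wide[b].to_numpy())
                rows.append(
                    {
                        "metric": metric,
                        "comparison": f"{a}-vs-{b}",
                        "t": t,
                        "p": p,
                        "n": int(wide.shape[0]),
                    }
                )
    return pd.DataFrame(rows)


def _trigger_and_correlation(
    evaluations: Sequence[PlanEvaluation],
) -> Tuple[Dict[str, Dict[str, TriggerReport]], pd.DataFrame]:
    # pooled baseline: overlaps are anatomy properties, identical across
    # approaches for a given fraction; use one approach's copy
    one = [ev for ev in evaluations if ev.approach == ApproachKind.IGRT.value]
    mean_overlaps = {
        organ: float(np.mean([ev.overlap_volumes_cc[organ] for ev in one]))
        for organ in ("bladder", "rectum")
    }
    triggers: Dict[str, Dict[str, TriggerReport]] = {}
    corr_rows = []
    for approach in ApproachKind.adaptation_approaches():
        evs = [ev for ev in evaluations if ev.approach == approach.value]
        triggers[approach.value] = trigger_analysis(evs, mean_overlaps)
        for organ in ("bladder", "rectum"):
            try:
                r = overlap_penalty_correlation(evs, organ)
            except ValueError:
                r = float("nan")
            corr_rows.append(
                {"approach": approach.value, "organ": organ, "pearson_r": r}
            )
    return triggers, pd.DataFrame(corr_rows)


def _dvh_statistics(
    all_curves: Dict[str, List[Tuple[str, DVHCurve]]], config: StudyConfig
) -> pd.DataFrame:
    max_dose = config.dose.prescription_ctv_gy * 1.25
    rows = []
    for approach, tagged in all_curves.items():
        for structure in DVH_STRUCTURES:
            curves = [c for s, c in tagged if s == structure]
            if len(curves) < 2:
                continue
            aligned = align_curves(curves, config.dvh_bin_width_gy, max_dose)
            edges, mean_pct, sd_pct = pointwise_dvh_stats(aligned)
            rows.append(
                pd.DataFrame(
                    {
                        "approach": approach,
                        "structure": structure,
                        "dose_gy": edges,
                        "mean_volume_pct": mean_pct,
                        "sd_volume_pct": sd_pct,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


# --------------------------------------------------------------------------
# reporting / output
# --------------------------------------------------------------------------


def reductions_from_per_criterion(
    per_criterion: pd.DataFrame,
) -> Dict[str, Optional[float]]:
    """Penalty reductions of the adapted approaches vs the non-adaptive one.

    Works on any criterion-by-approach table with a ``total`` row, including
    the shipped fixture of the published table.
    """
    igrt = per_criterion["IGRT"]

    def _reduction(s_adapt: float, s_igrt: float) -> Optional[float]:
        if s_igrt <= 0:
            return None  # not applicable: nothing to reduce
        return percent_reduction(s_adapt, s_igrt)

    def _avg(a: Optional[float], b: Optional[float]) -> Optional[float]:
        if a is None or b is None:
            return None
        return round((a + b) / 2.0, 1)

    out: Dict[str, Optional[float]] = {}
    for approach in ("ART1", "ART2", "ART3"):
        col = per_criterion[approach]
        out[f"total_{approach}"] = _reduction(col["total"], igrt["total"])
        for criterion in PENALTY_CRITERIA:
            out[f"{criterion}_{approach}"] = _reduction(col[criterion], igrt[criterion])
        out[f"ptv_avg_{approach}"] = _avg(
            out[f"ptv_v36.25_{approach}"], out[f"ptv_d98_{approach}"]
        )
        out[f"oar_avg_{approach}"] = _avg(
            out[f"bladder_v37_{approach}"], out[f"rectum_v36_{approach}"]
        )
    return out


def verify_printed_table(fixture: Optional[pd.DataFrame] = None) -> Dict:
    """Recompute totals, cohort means and reductions from the printed fixture.

    Returns the recomputed values together with a list of mismatches against
    the fixture's own printed totals/means (empty for the shipped table).
    """
    if fixture is None:
        fixture = load_printed_table()
    per_criterion = printed_per_criterion(fixture)
    per_patient = printed_per_patient(fixture)

    recomputed_totals = per_criterion.sum(axis=0)
    cohort_means = per_patient.mean(axis=0).round(1)
    table = per_criterion.copy()
    table.loc["total"] = recomputed_totals
    reductions = reductions_from_per_criterion(table)

    mismatches = []
    printed_totals = fixture[fixture["panel"] == "total"].set_index("approach")["value"]
    for approach, printed in printed_totals.items():
        if abs(recomputed_totals[approach] - printed) > 1e-9:
            mismatches.append(
                {
                    "field": f"total[{approach}]",
                    "printed": float(printed),
                    "recomputed": float(recomputed_totals[approach]),
                }
            )
    printed_means = fixture[fixture["panel"] == "mean"].set_index("approach")["value"]
    for approach, printed in printed_means.items():
        if abs(cohort_means[approach] - printed) > 1e-9:
            mismatches.append(
                {
                    "field": f"mean[{approach}]",
                    "printed": float(printed),
                    "recomputed": float(cohort_means[approach]),
                }
            )
    return {
        "per_criterion_totals": {k: float(v) for k, v in recomputed_totals.items()},
        "cohort_means": {k: float(v) for k, v in cohort_means.items()},
        "reductions_pct": reductions,
        "mismatches": mismatches,
    }


def write_outputs(result: StudyResult, out_dir: str) -> Dict[str, str]:
    """Write canonical CSV/JSON outputs plus the run manifest; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def _csv(name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = os.path.join(out_dir, name)
        df.to_csv(path, index=index, float_format="%.10g")
        paths[name] = path

    metrics = _metric_matrix(result.evaluations + result.reference_evaluations)
    _csv("metrics.csv", metrics, index=False)
    _csv("penalty_per_criterion.csv", result.penalty_table.per_criterion)
    _csv("penalty_per_patient_mean.csv", result.penalty_table.per_patient_mean)
    _csv("penalty_per_patient_sd.csv", result.penalty_table.per_patient_sd)
    _csv("statistics.csv", result.statistics, index=False)
    _csv("correlations.csv", result.correlations, index=False)
    if not result.dvh_stats.empty:
        _csv("dvh_mean_sd.csv", result.dvh_stats, index=False)

    reductions = reductions_from_per_criterion(result.penalty_table.per_criterion)
    with open(os.path.join(out_dir, "reductions.json"), "w") as fh:
        json.dump(reductions, fh, indent=2, sort_keys=True)
    paths["reductions.json"] = os.path.join(out_dir, "reductions.json")

    triggers = {
        approach: {
            organ: {
                "rule": rep.rule,
                "mean_overlap_cc": rep.mean_overlap_cc,
                "n_overdose": rep.n_overdose,
                "n_joint": rep.n_overdose_and_over_average_overlap,
                "ratio": rep.ratio,
            }
            for organ, rep in organ_reports.items()
        }
        for approach, organ_reports in result.triggers.items()
    }
    with open(os.path.join(out_dir, "triggers.json"), "w") as fh:
        json.dump(triggers, fh, indent=2, sort_keys=True)
    paths["triggers.json"] = os.path.join(out_dir, "triggers.json")

    manifest = {
        "tool": "adaptrt",
        "version": __version__,
        "master_seed": result.config.master_seed,
        "n_patients": result.config.n_patients,
        "n_fractions": result.config.n_fractions,
        "approaches": [a.value for a in ApproachKind.adaptation_approaches()],
        "n_adaptation_evaluations": len(result.evaluations),
        "config_hash": result.config.config_hash(),
        "valid": True,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest.json"] = os.path.join(out_dir, "manifest.json")
    return paths
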