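"""Cohort-level statistics: paired t-tests, correlation, overlap triggers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .criteria_penalty import PlanEvaluation


class EvaluationError(ValueError):
    pass


# rule: a plan counts as an OAR overdose when the metric exceeds the cutoff
TRIGGER_RULES: Dict[str, Tuple[str, float]] = {
    "bladder": ("bladder_v37", 9.0),  # V_37Gy(bladder) > 9 cc
    "rectum": ("rectum_v36", 1.5),  # V_36Gy(rectum) > 1.5 cc
}


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Classic paired Student's t on the differences; two-sided p, df = n - 1.

    Degenerate all-zero differences are reported as (0.0, 1.0) with the
    convention that identical samples are maximally non-significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EvaluationError("paired samples must be equal-length 1D arrays")
    if x.size < 3:
        raise EvaluationError("need at least three pairs")
    d = x - y
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    if d.std(ddof=1) == 0:
        # constant non-zero difference: infinitely significant in the model
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise EvaluationError("need two equal-length 1D arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EvaluationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class TriggerReport:
    """Overlap-volume adaptation-trigger summary for one organ and approach."""

    organ: str
    approach: str
    rule: str
    mean_overlap_cc: float
    n_overdose: int
    n_overdose_and_over_average_overlap: int

    @property
    def ratio(self) -> Optional[float]:
        if self.n_overdose == 0:
            return None  # not applicable
        return self.n_overdose_and_over_average_overlap / self.n_overdose


def trigger_analysis(
    evaluations: Sequence[PlanEvaluation],
    mean_overlaps_cc: Optional[Dict[str, float]] = None,
) -> Dict[str, TriggerReport]:
    """Fraction of overdosing plans whose organ overlap exceeds the cohort mean.

    ``evaluations`` holds the plans of one approach. The over-average baseline
    is the pooled mean overlap across all given plans (overlaps are anatomy
    properties, identical across approaches for a fraction); pass
    ``mean_overlaps_cc`` to pin the baseline to a larger pool.
    """
    if not evaluations:
        raise EvaluationError("no evaluations given")
    approaches = {ev.approach for ev in evaluations}
    if len(approaches) != 1:
        raise EvaluationError("trigger analysis expects a single approach")
    approach = approaches.pop()

    reports = {}
    for organ, (criterion_name, cutoff) in TRIGGER_RULES.items():
        overlaps = []
        for ev in evaluations:
            if organ not in ev.overlap_volumes_cc:
                raise EvaluationError(f"overlap volume for {organ!r} missing")
            overlaps.append(ev.overlap_volumes_cc[organ])
        mean_overlap = (
            mean_overlaps_cc[organ]
            if mean_overlaps_cc is not None
            else float(np.mean(overlaps))
        )
        n_over = 0
        n_joint = 0
        for ev, overlap in zip(evaluations, overlaps):
            measured = ev.result(criterion_name).measured_value
            if measured > cutoff:
                n_over += 1
                if overlap > mean_overlap:
                    n_joint += 1
        reports[organ] = TriggerReport(
            organ=organ,
            approach=approach,
            rule=f"{criterion_name} > {cutoff} cc",
            mean_overlap_cc=mean_overlap,
            n_overdose=n_over,
            n_overdose_and_over_average_overlap=n_joint,
        )
    return reports


def overlap_penalty_correlation(
    evaluations: Sequence[PlanEvaluation],
    organ: str,
    organ_criterion_only: bool = False,
) -> float:
    """Pearson r between per-plan organ overlap volume and penalty score S.

    By default S is the full four-criterion plan score; with
    ``organ_criterion_only`` only the organ's own criterion contributes.
    """
    overlaps = []
    scores = []
    criterion_name = TRIGGER_RULES[organ][0]
    for ev in evaluations:
        overlaps.append(ev.overlap_volumes_cc[organ])
        if organ_criterion_only:
            scores.append(ev.result(criterion_name).penalty_contribution)
        else:
            scores.append(ev.total_penalty)
    return pearson_r(overlaps, scores)
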