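"""ROC and predictive-value evaluation of the score as a triage test.

The score takes small integer values with heavy ties, so everything here is
tie-aware: the AUC is the rank (Mann-Whitney) statistic — the probability that
a random mutation carrier outscores a random non-carrier, ties counted half —
which equals trapezoidal integration of the empirical ROC curve.  The AUC
confidence interval uses DeLong's nonparametric variance estimator.
Test-positivity at a cutoff means score >= cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import CohortValidationError
from .phenotype_model import Cohort, MutationStatus


@dataclass
class CutoffPerformance:
    """Operating characteristics at one cutoff; None marks a 0/0 metric."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


@dataclass
class RocResult:
    cutoffs: np.ndarray  # ascending; includes max(score)+1 sentinel
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """(FPR, TPR) pairs of the empirical ROC curve, in plotting order."""
        fpr = self.fp / self.n_neg
        tpr = self.tp / self.n_pos
        order = np.lexsort((tpr, fpr))  # ties in FPR ascend in TPR
        return fpr[order], tpr[order]


def _split(scores: Sequence[float], is_case: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if scores.shape != is_case.shape:
        raise CohortValidationError("scores and labels differ in length")
    cases, controls = scores[is_case], scores[~is_case]
    if cases.size == 0 or controls.size == 0:
        raise CohortValidationError("ROC analysis needs both classes present")
    return cases, controls


def rank_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """Tie-corrected rank AUC: P(case > control) + 0.5 P(case = control)."""
    combined = np.concatenate([cases, controls])
    ranks = stats.rankdata(combined)
    m = cases.size
    return (ranks[:m].sum() - m * (m + 1) / 2) / (m * controls.size)


def delong_ci(cases: np.ndarray, controls: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """DeLong nonparametric CI for the AUC, clipped to [0, 1]."""
    m, n = cases.size, controls.size
    combined = np.concatenate([cases, controls])
    ranks = stats.rankdata(combined)
    auc = (ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    # placement values: V10_i = P(control < case_i) + 0.5 P(= case_i), and dually
    v10 = (ranks[:m] - stats.rankdata(cases)) / n
    v01 = 1.0 - (ranks[m:] - stats.rankdata(controls)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf((1 + level) / 2)
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


def roc_curve(scores: Sequence[float], is_case: Sequence[bool], level: float = 0.95) -> RocResult:
    """Empirical ROC over every observed score value plus a sentinel cutoff.

    Cutoffs are the sorted unique scores together with max(score)+1 (nobody
    test-positive); at each cutoff the full confusion matrix is recorded.
    """
    cases, controls = _split(scores, is_case)
    cutoffs = np.unique(np.concatenate([cases, controls]))
    cutoffs = np.append(cutoffs, cutoffs[-1] + 1)
    tp = np.array([(cases >= c).sum() for c in cutoffs])
    fp = np.array([(controls >= c).sum() for c in cutoffs])
    return RocResult(
        cutoffs=cutoffs,
        tp=tp,
        fp=fp,
        tn=controls.size - fp,
        fn=cases.size - tp,
        auc=rank_auc(cases, controls),
        auc_ci=delong_ci(cases, controls, level),
        n_pos=cases.size,
        n_neg=controls.size,
    )


def trapezoidal_auc(roc: RocResult) -> float:
    """Area under the empirical ROC by the trapezoid rule (cross-check path)."""
    fpr, tpr = roc.points()
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    return float(np.trapezoid(tpr, fpr))


def performance_at_cutoff(
    scores: Sequence[float], is_case: Sequence[bool], cutoff: float
) -> CutoffPerformance:
    """Sensitivity/specificity/PPV/NPV with positivity at score >= cutoff.

    Metrics with a zero denominator are None (undefined), never 0, so that
    "no negatives called" stays distinguishable from "NPV = 0".
    """
    cases, controls = _split(scores, is_case)
    tp = int((cases >= cutoff).sum())
    fn = cases.size - tp
    fp = int((controls >= cutoff).sum())
    tn = controls.size - fp

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    return CutoffPerformance(
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )


def threshold_sweep(scores: Sequence[float], is_case: Sequence[bool]) -> list[CutoffPerformance]:
    """Performance at every integer cutoff from 0 to max(score) + 1."""
    cases, controls = _split(scores, is_case)
    top = int(math.floor(max(cases.max(), controls.max()))) + 1
    return [performance_at_cutoff(scores, is_case, c) for c in range(0, top + 1)]


def cohort_scores(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """(score, is-carrier) arrays from a scored cohort, skipping unknown status.

    Records must carry a cached ``raw_score`` (see ``score_cohort``).
    """
    from .score_engine import compute_score

    scores, labels = [], []
    for rec in cohort:
        if rec.mutation_status is MutationStatus.UNKNOWN:
            continue
        total = rec.raw_score if rec.raw_score is not None else compute_score(rec).total
        scores.append(total)
        labels.append(rec.mutation_status is MutationStatus.MUTATION)
    return np.asarray(scores, dtype=float), np.asarray(labels, dtype=bool)
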