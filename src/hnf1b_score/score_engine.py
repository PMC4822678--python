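"""The 17-item HNF1B clinical score.

The score is an additive triage instrument for selecting patients for *HNF1B*
genetic testing.  Item weights: family history +2; antenatal renal abnormality
+2; per kidney — hyperechogenicity +4, renal cysts +4, hypoplasia +2,
multicystic/dysplastic kidney +2, urinary tract malformation +1; solitary
kidney +1 (awarded once: two absent kidneys are biologically impossible, so it
is modelled record-level); hypomagnesaemia +2; hypokalaemia +1; early-onset
gout (<30 years at diagnosis) +2; glomerular cysts or oligomeganephronia on
biopsy +1; pancreas item (young-onset diabetes/MODY, pancreatic hypoplasia, or
exocrine insufficiency) +4 capped at 4; genital tract malformation +4; liver
test abnormality of unknown origin +2.

A referral is test-positive at a cutoff (default 8) when score >= cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import CohortValidationError
from .phenotype_model import KIDNEY_FIELDS, Cohort, PatientRecord

#: Arithmetic maximum of the published score table (solitary kidney is listed
#: under each kidney there; with record-level solitary an all-true record
#: reaches 47, still within this bound).
SCORE_MAX = 48

#: Default decision threshold for recommending genetic testing.
DEFAULT_CUTOFF = 8

KIDNEY_ITEM_POINTS = {
    "hyperechogenicity": 4,
    "cysts": 4,
    "hypoplasia": 2,
    "multicystic_dysplastic": 2,
    "urinary_tract_malformation": 1,
}

PATIENT_ITEM_POINTS = {
    "family_history": 2,
    "antenatal_abnormality": 2,
    "solitary_kidney": 1,
    "hypomagnesaemia": 2,
    "hypokalaemia": 1,
    "early_onset_gout": 2,
    "biopsy_glomerular_cysts_or_oligomeganephronia": 1,
    "genital_tract_malformation": 4,
    "liver_test_abnormality": 2,
}

PANCREAS_POINTS = 4


@dataclass
class ScoreBreakdown:
    """Per-item contributions and the total score for one patient."""

    items: dict[str, int]
    total: int
    pancreas_capped: bool


@dataclass
class CutoffClassification:
    score: int
    cutoff: int
    positive: bool


def compute_score(record: PatientRecord, strict_mody: bool = False) -> ScoreBreakdown:
    """Compute the HNF1B score for one patient record.

    ``strict_mody=False`` (default) lets young-onset diabetes (diagnosis <=35
    years) satisfy the MODY clause of the pancreas item, matching scoring from
    routine referral information; ``strict_mody=True`` awards the pancreas item
    only for pancreatic hypoplasia / exocrine failure.
    """
    items: dict[str, int] = {}
    for fld, pts in PATIENT_ITEM_POINTS.items():
        items[fld] = pts if getattr(record, fld) else 0
    for side, kid in (("left", record.kidney_left), ("right", record.kidney_right)):
        for fld in KIDNEY_FIELDS:
            items[f"{side}_{fld}"] = KIDNEY_ITEM_POINTS[fld] if getattr(kid, fld) else 0

    clauses = int(record.pancreatic_hypoplasia_or_exocrine_failure)
    if not strict_mody:
        clauses += int(record.diabetes_young_onset)
    items["pancreas"] = PANCREAS_POINTS if clauses else 0

    total = sum(items.values())
    return ScoreBreakdown(items=items, total=total, pancreas_capped=clauses > 1)


def classify(score: int, cutoff: int = DEFAULT_CUTOFF) -> CutoffClassification:
    """Classify a score as test-positive (score >= cutoff) or negative."""
    if score < 0:
        raise CohortValidationError(f"score must be non-negative, got {score}")
    if cutoff < 0:
        raise CohortValidationError(f"cutoff must be non-negative, got {cutoff}")
    return CutoffClassification(score=score, cutoff=cutoff, positive=score >= cutoff)


def score_cohort(
    cohort: Cohort, cutoff: int = DEFAULT_CUTOFF, strict_mody: bool = False
) -> list[tuple[str, ScoreBreakdown, CutoffClassification]]:
    """Score every record (order preserved), caching totals in ``raw_score``."""
    out = []
    for rec in cohort:
        breakdown = compute_score(rec, strict_mody=strict_mody)
        rec.raw_score = breakdown.total
        out.append((rec.patient_id, breakdown, classify(breakdown.total, cutoff)))
    return out


def scores_frame(cohort: Cohort, cutoff: int = DEFAULT_CUTOFF, strict_mody: bool = False) -> pd.DataFrame:
    """Tabular view of a scored cohort: one row per patient, one column per item."""
    rows = []
    for (pid, breakdown, cls), rec in zip(score_cohort(cohort, cutoff, strict_mody), cohort):
        row: dict[str, object] = {
            "patient_id": pid,
            "age_group": rec.age_group.value,
            "mutation_status": rec.mutation_status.value,
        }
        row.update(breakdown.items)
        row["total"] = breakdown.total
        row["positive"] = int(cls.positive)
        rows.append(row)
    return pd.DataFrame(rows)
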