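"""Patient records, cohorts, and their delimited-text / JSON representations.

A referral for *HNF1B* genetic testing is represented by :class:`PatientRecord`:
demographics (age group, child = age <=16 years), the genetic test outcome, and
the scoreable phenotype items.  Renal ultrasound findings are held per kidney in
:class:`KidneyFindings`; everything else is a patient-level flag.  Missing
phenotype data means "not assessed" and is coded ``False`` — scores and 2x2
tables treat unassessed items as absent, mirroring retrospective scoring from
referral forms — with a per-record ``completeness`` fraction kept for reporting.

The on-disk format is a CSV/TSV with one row per referral.  Kidney findings are
encoded with ``left_``/``right_`` column prefixes; alternatively, patient-level
renal columns (e.g. ``renal_cysts``) are accepted and expanded with a
"bilateral" convention (both kidneys flagged), which is the documented default
for features the study reports without laterality.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterator, Optional

import pandas as pd

from .errors import CohortValidationError, SchemaError

logger = logging.getLogger(__name__)

#: Age (years) at or below which a referral counts as paediatric.
CHILD_AGE_MAX = 16

#: Age (years) at or below which diabetes counts as young-onset.
YOUNG_ONSET_DIABETES_AGE_MAX = 35.0


class AgeGroup(str, Enum):
    CHILD = "child"
    ADULT = "adult"


class MutationStatus(str, Enum):
    MUTATION = "mutation"
    NORMAL = "normal"
    UNKNOWN = "unknown"


#: Per-kidney ultrasound/imaging findings, in score-table order.
KIDNEY_FIELDS = (
    "hyperechogenicity",
    "cysts",
    "hypoplasia",
    "multicystic_dysplastic",
    "urinary_tract_malformation",
)

#: Patient-level boolean phenotype fields of :class:`PatientRecord`.
PATIENT_BOOL_FIELDS = (
    "family_history",
    "antenatal_abnormality",
    "solitary_kidney",
    "hypomagnesaemia",
    "hypokalaemia",
    "early_onset_gout",
    "biopsy_glomerular_cysts_or_oligomeganephronia",
    "diabetes_young_onset",
    "pancreatic_hypoplasia_or_exocrine_failure",
    "genital_tract_malformation",
    "liver_test_abnormality",
)

# Accepted aliases for patient-level boolean columns (reader only).
_COLUMN_ALIASES = {
    "antenatal_renal_abnormalities": "antenatal_abnormality",
    "glomerular_cysts_or_oligomeganephronia": "biopsy_glomerular_cysts_or_oligomeganephronia",
    "genital_tract_malformations": "genital_tract_malformation",
    "liver_test_abnormalities": "liver_test_abnormality",
    "single_kidney": "solitary_kidney",
}

# Patient-level renal columns expanded to both kidneys (bilateral convention).
_BILATERAL_ALIASES = {
    "hyperechogenicity": "hyperechogenicity",
    "renal_cysts": "cysts",
    "hypoplasia": "hypoplasia",
    "multicystic_dysplastic_kidney": "multicystic_dysplastic",
    "urinary_tract_malformations": "urinary_tract_malformation",
    "urinary_tract_malformation": "urinary_tract_malformation",
}

_MANDATORY_COLUMNS = ("patient_id", "age_group", "mutation_status")


@dataclass
class KidneyFindings:
    """Structural findings for a single kidney; any combination is permitted."""

    hyperechogenicity: bool = False
    cysts: bool = False
    hypoplasia: bool = False
    multicystic_dysplastic: bool = False
    urinary_tract_malformation: bool = False

    def any_finding(self) -> bool:
        return any(getattr(self, f) for f in KIDNEY_FIELDS)


@dataclass
class PatientRecord:
    """One referral for genetic testing with its scoreable phenotype.

    All phenotype booleans default ``False`` (missing = not assessed).
    ``completeness`` is the fraction of phenotype items actually assessed in
    the source file; it is bookkeeping metadata and excluded from equality.
    """

    patient_id: str
    age_group: AgeGroup = AgeGroup.ADULT
    mutation_status: MutationStatus = MutationStatus.UNKNOWN
    family_history: bool = False
    antenatal_abnormality: bool = False
    kidney_left: KidneyFindings = field(default_factory=KidneyFindings)
    kidney_right: KidneyFindings = field(default_factory=KidneyFindings)
    solitary_kidney: bool = False
    hypomagnesaemia: bool = False
    hypokalaemia: bool = False
    early_onset_gout: bool = False
    biopsy_glomerular_cysts_or_oligomeganephronia: bool = False
    diabetes_young_onset: bool = False
    age_at_diabetes_diagnosis: Optional[float] = None
    pancreatic_hypoplasia_or_exocrine_failure: bool = False
    genital_tract_malformation: bool = False
    liver_test_abnormality: bool = False
    raw_score: Optional[int] = None
    completeness: float = field(default=1.0, compare=False)

    def validate(self) -> None:
        """Raise :class:`CohortValidationError` on any invariant violation."""
        if self.solitary_kidney and self.kidney_left.any_finding() and self.kidney_right.any_finding():
            raise CohortValidationError(
                f"{self.patient_id}: solitary_kidney is set but both kidneys carry findings"
            )
        if self.age_at_diabetes_diagnosis is not None:
            young = self.age_at_diabetes_diagnosis <= YOUNG_ONSET_DIABETES_AGE_MAX
            if self.diabetes_young_onset != young:
                raise CohortValidationError(
                    f"{self.patient_id}: diabetes_young_onset={self.diabetes_young_onset} "
                    f"inconsistent with age at diagnosis {self.age_at_diabetes_diagnosis}"
                )
        if not 0.0 <= self.completeness <= 1.0:
            raise CohortValidationError(f"{self.patient_id}: completeness outside [0, 1]")


@dataclass
class Cohort:
    """Ordered collection of :class:`PatientRecord` with unique patient ids."""

    records: list[PatientRecord] = field(default_factory=list)
    label: str = ""
    config: Optional[Any] = None  # generating CohortConfig, if synthetic

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id in seen:
                raise CohortValidationError(f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)
            rec.validate()


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f", "0.0"}


def _parse_bool(value: Any) -> Optional[bool]:
    """Parse a CSV cell into a bool, or None when blank/missing."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(value)
    text = str(value).strip().lower()
    if text == "" or text == "nan":
        return None
    if text in _TRUE_TOKENS:
        return True
    if text in _FALSE_TOKENS:
        return False
    try:
        return bool(float(text))
    except ValueError as exc:
        raise SchemaError(f"cannot interpret {value!r} as a boolean flag") from exc


def _sep_for(path: Path, dialect: Optional[str]) -> str:
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if dialect not in {"csv", "tsv"}:
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def _known_columns() -> set[str]:
    known = set(_MANDATORY_COLUMNS) | set(PATIENT_BOOL_FIELDS)
    known |= set(_COLUMN_ALIASES) | set(_BILATERAL_ALIASES)
    known |= {f"{side}_{f}" for side in ("left", "right") for f in KIDNEY_FIELDS}
    known |= {"age_at_diabetes_diagnosis", "raw_score"}
    return known


def read_cohort(path: str | Path, dialect: Optional[str] = None, label: str = "") -> Cohort:
    """Read a cohort from a delimited-text file.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.  Mandatory columns: ``patient_id``,
        ``age_group`` (child/adult), ``mutation_status`` (mutation/normal/
        unknown).  All phenotype columns are optional; blank cells mean "not
        assessed" and parse as ``False``.
    dialect
        ``"csv"`` or ``"tsv"``; inferred from the file suffix when omitted.

    Raises
    ------
    SchemaError
        on missing mandatory columns or unparseable cells.
    CohortValidationError
        on duplicate patient ids or records violating an invariant; a bad
        record is rejected, never silently repaired.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[""])

    missing = [c for c in _MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")
    unknown = [c for c in frame.columns if c not in _known_columns()]
    if unknown:
        logger.warning("ignoring unknown columns: %s", ", ".join(unknown))

    records = [_record_from_row(row) for _, row in frame.iterrows()]
    cohort = Cohort(records=records, label=label or path.stem)
    cohort.validate()
    return cohort


def _record_from_row(row: pd.Series) -> PatientRecord:
    def cell(name: str) -> Any:
        return row[name] if name in row.index else None

    pid = cell("patient_id")
    if pid is None or (isinstance(pid, float) and math.isnan(pid)):
        raise SchemaError("blank patient_id")
    try:
        age_group = AgeGroup(str(cell("age_group")).strip().lower())
        mutation_status = MutationStatus(str(cell("mutation_status")).strip().lower())
    except ValueError as exc:
        raise SchemaError(f"{pid}: {exc}") from exc

    assessed = 0
    total_items = len(PATIENT_BOOL_FIELDS) + 2 * len(KIDNEY_FIELDS)
    flags: dict[str, bool] = {}
    for fld in PATIENT_BOOL_FIELDS:
        raw = cell(fld)
        for alias, target in _COLUMN_ALIASES.items():
            if target == fld and raw is None:
                raw = cell(alias)
        parsed = _parse_bool(raw)
        flags[fld] = bool(parsed)
        if parsed is not None:
            assessed += 1

    kidneys = {"left": KidneyFindings(), "right": KidneyFindings()}
    for side, kid in kidneys.items():
        for fld in KIDNEY_FIELDS:
            parsed = _parse_bool(cell(f"{side}_{fld}"))
            if parsed is not None:
                setattr(kid, fld, parsed)
                assessed += 1
    # patient-level renal columns: bilateral convention (both kidneys flagged)
    for col, fld in _BILATERAL_ALIASES.items():
        parsed = _parse_bool(cell(col))
        if parsed is not None:
            for kid in kidneys.values():
                if not getattr(kid, fld):
                    setattr(kid, fld, parsed)
            assessed += 2

    age_dm: Optional[float] = None
    raw_age = cell("age_at_diabetes_diagnosis")
    if raw_age is not None and str(raw_age).strip() not in {"", "nan"}:
        age_dm = float(raw_age)
        if _parse_bool(cell("diabetes_young_onset")) is None:
            # infer young-onset status from the recorded age at diagnosis
            flags["diabetes_young_onset"] = age_dm <= YOUNG_ONSET_DIABETES_AGE_MAX
            assessed += 1

    raw_score: Optional[int] = None
    rs = cell("raw_score")
    if rs is not None and str(rs).strip() not in {"", "nan"}:
        raw_score = int(float(rs))

    return PatientRecord(
        patient_id=str(pid),
        age_group=age_group,
        mutation_status=mutation_status,
        kidney_left=kidneys["left"],
        kidney_right=kidneys["right"],
        age_at_diabetes_diagnosis=age_dm,
        raw_score=raw_score,
        completeness=min(assessed, total_items) / total_items,
        **flags,
    )


def write_cohort(cohort: Cohort, path: str | Path, dialect: Optional[str] = None) -> None:
    """Write a cohort with the full column schema; read_cohort round-trips it."""
    cohort.validate()
    path = Path(path)
    sep = _sep_for(path, dialect)
    pd.DataFrame([_record_to_row(rec) for rec in cohort.records], columns=_schema_columns()).to_csv(
        path, sep=sep, index=False
    )


def _schema_columns() -> list[str]:
    cols = list(_MANDATORY_COLUMNS) + list(PATIENT_BOOL_FIELDS)
    cols += [f"{side}_{f}" for side in ("left", "right") for f in KIDNEY_FIELDS]
    cols += ["age_at_diabetes_diagnosis", "raw_score"]
    return cols


def _record_to_row(rec: PatientRecord) -> dict[str, Any]:
    row: dict[str, Any] = {
        "patient_id": rec.patient_id,
        "age_group": rec.age_group.value,
        "mutation_status": rec.mutation_status.value,
    }
    for fld in PATIENT_BOOL_FIELDS:
        row[fld] = int(getattr(rec, fld))
    for side, kid in (("left", rec.kidney_left), ("right", rec.kidney_right)):
        for fld in KIDNEY_FIELDS:
            row[f"{side}_{fld}"] = int(getattr(kid, fld))
    row["age_at_diabetes_diagnosis"] = (
        "" if rec.age_at_diabetes_diagnosis is None else rec.age_at_diabetes_diagnosis
    )
    row["raw_score"] = "" if rec.raw_score is None else rec.raw_score
    return row


# ---------------------------------------------------------------------------
# JSON serialisation
# ---------------------------------------------------------------------------


def cohort_to_dict(cohort: Cohort) -> dict[str, Any]:
    def rec_dict(rec: PatientRecord) -> dict[str, Any]:
        d = dataclasses.asdict(rec)
        d["age_group"] = rec.age_group.value
        d["mutation_status"] = rec.mutation_status.value
        return d

    return {"label": cohort.label, "records": [rec_dict(r) for r in cohort.records]}


def cohort_from_dict(data: dict[str, Any]) -> Cohort:
    records = []
    for d in data["records"]:
        d = dict(d)
        d["age_group"] = AgeGroup(d["age_group"])
        d["mutation_status"] = MutationStatus(d["mutation_status"])
        d["kidney_left"] = KidneyFindings(**d["kidney_left"])
        d["kidney_right"] = KidneyFindings(**d["kidney_right"])
        records.append(PatientRecord(**d))
    cohort = Cohort(records=records, label=data.get("label", ""))
    cohort.validate()
    return cohort


def save_cohort_json(cohort: Cohort, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cohort_to_dict(cohort), indent=1))


def load_cohort_json(path: str | Path) -> Cohort:
    return cohort_from_dict(json.loads(Path(path).read_text()))
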