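"""Synthetic referral cohorts and the embedded UK characteristics fixture.

The generator emulates the sampling frame of the UK referral study: 686
referrals, 25.8% mutation-positive, 60.6% children (age <=16), with each
clinical feature drawn Bernoulli with a frequency conditional on mutation
status and age group (defaults are the study's published feature frequencies).
Features are drawn independently given (status, age group): the source data
report only marginal frequencies, so no co-occurrence structure is assumed —
a documented simplification.

``uk_fixture`` embeds the published per-feature counts (carriers 177 /
non-carriers 509 overall; 116/300 children; 61/209 adults) together with the
printed OR/CI/p strings for regression tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .association_stats import FEATURES, TwoByTwoTable, feature_table, odds_ratio
from .errors import CohortValidationError
from .phenotype_model import AgeGroup, Cohort, MutationStatus, PatientRecord

logger = logging.getLogger(__name__)

SUBGROUPS = ("total", "child", "adult")

#: (carriers, non-carriers) group sizes per subgroup in the UK referral study.
GROUP_SIZES: dict[str, tuple[int, int]] = {
    "total": (177, 509),
    "child": (116, 300),
    "adult": (61, 209),
}

# Feature-present counts (carriers, non-carriers) by subgroup, and the
# published "OR (95% CI)" / p strings, one row per tabulated feature.
# Child and adult counts sum to the totals for every row.
_UK_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "antenatal_renal_abnormalities": {"total": (54, 83), "child": (53, 80), "adult": (1, 3)},
    "hyperechogenicity": {"total": (23, 22), "child": (21, 20), "adult": (2, 2)},
    "renal_cysts": {"total": (136, 314), "child": (93, 190), "adult": (43, 124)},
    "hypoplasia": {"total": (21, 24), "child": (6, 16), "adult": (15, 8)},
    "multicystic_dysplastic_kidney": {"total": (6, 26), "child": (6, 25), "adult": (0, 1)},
    "urinary_tract_malformations": {"total": (19, 52), "child": (13, 29), "adult": (6, 23)},
    "solitary_kidney": {"total": (14, 54), "child": (6, 21), "adult": (8, 33)},
    "glomerular_cysts_or_oligomeganephronia": {"total": (4, 10), "child": (2, 8), "adult": (2, 2)},
    "diabetes_young_onset": {"total": (60, 59), "child": (26, 25), "adult": (34, 34)},
    "pancreatic_hypoplasia_or_exocrine_failure": {"total": (7, 1), "child": (1, 0), "adult": (6, 1)},
    "family_history": {"total": (64, 184), "child": (36, 76), "adult": (28, 108)},
    "genital_tract_malformations": {"total": (9, 16), "child": (1, 8), "adult": (8, 8)},
    "liver_test_abnormalities": {"total": (15, 5), "child": (0, 2), "adult": (15, 3)},
    "hypomagnesaemia": {"total": (11, 7), "child": (3, 6), "adult": (8, 1)},
    "early_onset_gout": {"total": (3, 13), "child": (1, 6), "adult": (2, 7)},
}

_UK_PRINTED: dict[str, dict[str, str]] = {
    "antenatal_renal_abnormalities": {
        "total": "<=0.0001 | 2.3 (1.5-3.4)", "child": "0.0003 | 2.3 (1.5-3.6)", "adult": "1 | 1.1 (0.1-11.2)"},
    "hyperechogenicity": {
        "total": "0.0002 | 3.3 (1.8-6.1)", "child": "0.0008 | 3.1 (1.6-6.0)", "adult": "0.2 | 3.5 (0.5-25.4)"},
    "renal_cysts": {
        "total": "0.0002 | 2.1 (1.4-3.0)", "child": "0.001 | 2.3 (1.4-3.9)", "adult": "0.1 | 1.6 (0.9-3.0)"},
    "hypoplasia": {
        "total": "0.002 | 2.7 (1.5-5.0)", "child": "1 | 1.0 (0.4-2.5)", "adult": "<=0.0001 | 8.2 (3.3-20.5)"},
    "multicystic_dysplastic_kidney": {
        "total": "0.4 | 0.7 (0.3-1.6)", "child": "0.3 | 0.6 (0.2-1.5)", "adult": "1 | 0 (0-65.1)"},
    "urinary_tract_malformations": {
        "total": "0.9 | 1.1 (0.6-1.8)", "child": "0.7 | 1.2 (0.6-2.4)", "adult": "1 | 0.9 (0.3-2.3)"},
    "solitary_kidney": {
        "total": "0.4 | 0.7 (0.4-1.3)", "child": "0.7 | 0.7 (0.3-1.8)", "adult": "1 | 0.8 (0.4-1.8)"},
    "glomerular_cysts_or_oligomeganephronia": {
        "total": "0.8 | 1.2 (0.4-3.7)", "child": "0.7 | 0.6 (0.1-3.1)", "adult": "0.2 | 3.5 (0.5-25.4)"},
    "diabetes_young_onset": {
        "total": "<=0.0001 | 3.9 (2.6-5.9)", "child": "0.0002 | 3.2 (1.7-5.8)", "adult": "<=0.0001 | 6.5 (3.5-12.1)"},
    "pancreatic_hypoplasia_or_exocrine_failure": {
        "total": "0.0004 | 20.7 (2.5-169)", "child": "0.3 | -", "adult": "0.0006 | 22.7 (2.7-192)"},
    "family_history": {
        "total": "1 | 1.0 (0.7-1.4)", "child": "0.3 | 1.3 (0.8-2.1)", "adult": "0.5 | 0.8 (0.4-1.4)"},
    "genital_tract_malformations": {
        "total": "0.2 | 1.7 (0.7-3.8)", "child": "0.5 | 0.3 (0.04-2.6)", "adult": "0.01 | 3.8 (1.4-10.6)"},
    "liver_test_abnormalities": {
        "total": "<=0.0001 | 9.3 (3.3-26.1)", "child": "1 | 0 (0-9.0)", "adult": "<=0.0001 | 22.4 (6.2-80.5)"},
    "hypomagnesaemia": {
        "total": "0.001 | 4.8 (1.8-12.5)", "child": "0.7 | 1.3 (0.3-5.3)", "adult": "<=0.0001 | 31.4 (3.8-257)"},
    "early_onset_gout": {
        "total": "0.8 | 0.7 (0.2-2.3)", "child": "0.7 | 0.4 (0.05-3.6)", "adult": "1 | 1.0 (0.2-4.8)"},
}

#: Kidney-level features that receive laterality when generated.
_RENAL_FEATURES = {
    "hyperechogenicity": "hyperechogenicity",
    "renal_cysts": "cysts",
    "hypoplasia": "hypoplasia",
    "multicystic_dysplastic_kidney": "multicystic_dysplastic",
    "urinary_tract_malformations": "urinary_tract_malformation",
}

_PATIENT_FEATURES = {
    "antenatal_renal_abnormalities": "antenatal_abnormality",
    "solitary_kidney": "solitary_kidney",
    "glomerular_cysts_or_oligomeganephronia": "biopsy_glomerular_cysts_or_oligomeganephronia",
    "diabetes_young_onset": "diabetes_young_onset",
    "pancreatic_hypoplasia_or_exocrine_failure": "pancreatic_hypoplasia_or_exocrine_failure",
    "family_history": "family_history",
    "genital_tract_malformations": "genital_tract_malformation",
    "liver_test_abnormalities": "liver_test_abnormality",
    "hypomagnesaemia": "hypomagnesaemia",
    "early_onset_gout": "early_onset_gout",
}

# Age at diabetes diagnosis (years), conditional on carrier status, as
# (median, IQR low, IQR high) of the referral data; sampled log-normally
# truncated at the young-onset limit of 35.
_DIABETES_AGE = {
    MutationStatus.MUTATION: (16.5, 12.0, 26.8),
    MutationStatus.NORMAL: (32.5, 15.3, 49.8),
}


@dataclass
class FixtureRow:
    feature: str
    tables: dict[str, TwoByTwoTable]  # keyed by subgroup
    printed: dict[str, str]  # "p | OR (CI)" strings as published


@dataclass
class FixtureTable:
    """The published per-feature counts as ready-made 2x2 tables."""

    rows: dict[str, FixtureRow]
    group_sizes: dict[str, tuple[int, int]]

    def table(self, feature: str, subgroup: str = "total") -> TwoByTwoTable:
        return self.rows[feature].tables[subgroup]

    def validate(self) -> None:
        """Every row's reconstructed group sizes must equal the published ones."""
        for row in self.rows.values():
            for sub, t in row.tables.items():
                n_case, n_ctrl = self.group_sizes[sub]
                if t.a + t.b != n_case or t.c + t.d != n_ctrl:
                    raise CohortValidationError(f"{row.feature}/{sub}: margins do not reconstruct")


def uk_fixture() -> FixtureTable:
    """The embedded UK characteristics table (carriers 177, non-carriers 509)."""
    rows = {}
    for feature, by_sub in _UK_COUNTS.items():
        tables = {}
        for sub, (a, c) in by_sub.items():
            n_case, n_ctrl = GROUP_SIZES[sub]
            tables[sub] = TwoByTwoTable(a, n_case - a, c, n_ctrl - c, feature_label=feature)
        rows[feature] = FixtureRow(feature=feature, tables=tables, printed=_UK_PRINTED[feature])
    fixture = FixtureTable(rows=rows, group_sizes=dict(GROUP_SIZES))
    fixture.validate()
    return fixture


def fixture_frame() -> pd.DataFrame:
    """The fixture flattened to one row per (feature, subgroup) for export."""
    recs = []
    for row in uk_fixture().rows.values():
        for sub, t in row.tables.items():
            recs.append(
                {"feature": row.feature, "subgroup": sub, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                 "printed": row.printed[sub]}
            )
    return pd.DataFrame(recs)


def default_feature_freqs() -> dict[tuple[str, str, str], float]:
    """Feature frequencies conditional on (mutation status, age group).

    Keys are (feature, "mutation"/"normal", "child"/"adult"); values are the
    published count fractions, e.g. antenatal abnormality in carrier children
    = 53/116.
    """
    freqs: dict[tuple[str, str, str], float] = {}
    for feature, by_sub in _UK_COUNTS.items():
        for sub in ("child", "adult"):
            a, c = by_sub[sub]
            n_case, n_ctrl = GROUP_SIZES[sub]
            freqs[(feature, "mutation", sub)] = a / n_case
            freqs[(feature, "normal", sub)] = c / n_ctrl
    return freqs


@dataclass
class CohortConfig:
    """Generative parameters for a synthetic referral cohort.

    Defaults reproduce the UK study conditions: n = 686 referrals, mutation
    prevalence 25.8%, 60.6% children, per-feature frequencies from the
    published characteristics table, and renal findings bilateral with
    probability 0.8 when present (bilateral hyperechogenic kidneys are the
    typical antenatal presentation).
    """

    n: int = 686
    prevalence: float = 0.258
    child_fraction: float = 0.606
    feature_freqs: dict[tuple[str, str, str], float] = field(default_factory=default_feature_freqs)
    bilateral_prob: float = 0.8
    # hypokalaemia is a scored item but not tabulated against mutation status
    # in the source data; realistic referral-cohort rates, documented choice
    hypokalaemia_freq: dict[str, float] = field(
        default_factory=lambda: {"mutation": 0.05, "normal": 0.02}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise CohortValidationError("n must be >= 1")
        probs = [self.prevalence, self.child_fraction, self.bilateral_prob]
        probs += list(self.feature_freqs.values()) + list(self.hypokalaemia_freq.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise CohortValidationError("all probabilities must lie in [0, 1]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["feature_freqs"] = {"|".join(k): v for k, v in self.feature_freqs.items()}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        if "feature_freqs" in d:
            d["feature_freqs"] = {tuple(k.split("|")): v for k, v in d["feature_freqs"].items()}
        return cls(**d)


def _truncated_lognormal_age(rng: np.random.Generator, median: float, q1: float, q3: float,
                             upper: float) -> float:
    """Draw age at diagnosis from a log-normal matched to (median, IQR), <= upper."""
    mu = math.log(median)
    sigma = (math.log(q3) - math.log(q1)) / (2 * stats.norm.ppf(0.75))
    cap = stats.norm.cdf((math.log(upper) - mu) / sigma)
    u = rng.uniform(0, cap)
    return float(math.exp(mu + sigma * stats.norm.ppf(u)))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a synthetic referral cohort; same seed gives an identical cohort.

    Each record draws mutation status ~ Bernoulli(prevalence) and age group ~
    Bernoulli(child_fraction); each feature ~ Bernoulli(freq | status, age).
    Renal features are bilateral with probability ``bilateral_prob`` (otherwise
    one side at random), except when a solitary kidney was drawn, in which case
    all findings sit on the single kidney.  Young-onset diabetics also receive
    an age at diagnosis <= 35 drawn from a truncated log-normal matched to the
    study's medians/IQRs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    for i in range(config.n):
        status = MutationStatus.MUTATION if rng.random() < config.prevalence else MutationStatus.NORMAL
        age_group = AgeGroup.CHILD if rng.random() < config.child_fraction else AgeGroup.ADULT
        skey, akey = status.value, age_group.value

        present = {
            feat: rng.random() < config.feature_freqs.get((feat, skey, akey), 0.0)
            for feat in FEATURES
        }
        rec = PatientRecord(patient_id=f"S{i:05d}", age_group=age_group, mutation_status=status)
        for feat, fld in _PATIENT_FEATURES.items():
            setattr(rec, fld, present[feat])
        for feat, fld in _RENAL_FEATURES.items():
            if not present[feat]:
                continue
            if rec.solitary_kidney:
                sides = (rec.kidney_left,)  # all findings on the single kidney
            elif rng.random() < config.bilateral_prob:
                sides = (rec.kidney_left, rec.kidney_right)
            else:
                sides = (rec.kidney_left,) if rng.random() < 0.5 else (rec.kidney_right,)
            for kid in sides:
                setattr(kid, fld, True)
        if rec.diabetes_young_onset:
            med, q1, q3 = _DIABETES_AGE[status]
            rec.age_at_diabetes_diagnosis = round(
                _truncated_lognormal_age(rng, med, q1, q3, upper=35.0), 1
            )
        rec.hypokalaemia = rng.random() < config.hypokalaemia_freq[skey]
        records.append(rec)

    cohort = Cohort(records=records, label=f"synthetic-seed{config.seed}", config=config)
    cohort.validate()
    return cohort


def implied_marginal_or(config: CohortConfig, feature: str) -> float:
    """Whole-cohort odds ratio implied by the generating conditional frequencies."""
    cf = config.child_fraction
    p = {}
    for skey in ("mutation", "normal"):
        p[skey] = cf * config.feature_freqs.get((feature, skey, "child"), 0.0) + (1 - cf) * (
            config.feature_freqs.get((feature, skey, "adult"), 0.0)
        )
    pm, pn = p["mutation"], p["normal"]
    if pm in (0.0, 1.0) or pn in (0.0, 1.0):
        return math.inf if pn == 0.0 and pm > 0 else math.nan
    return (pm / (1 - pm)) / (pn / (1 - pn))


@dataclass
class RecoveryReport:
    """Parameter-recovery summary: generating vs estimated whole-cohort ORs."""

    table: pd.DataFrame  # one row per feature
    n_reps: int

    @property
    def flagged(self) -> list[str]:
        return list(self.table.loc[self.table["flag"], "feature"])


def recovery_check(config: CohortConfig, n_reps: int = 200, seed: int = 0) -> RecoveryReport:
    """Simulate cohorts and check the estimated ORs recover the generating ORs.

    For each feature the whole-cohort OR is estimated in every replicate
    (Haldane-Anscombe 0.5 correction when a zero cell occurs) and the
    generating marginal OR is compared with the central 95% of the estimates;
    features whose generating value falls outside that band are flagged.
    """
    if n_reps < 1:
        raise CohortValidationError("n_reps must be >= 1")
    child_seeds = np.random.SeedSequence(seed).spawn(n_reps)
    estimates: dict[str, list[float]] = {feat: [] for feat in FEATURES}
    for ss in child_seeds:
        rep_config = dataclasses.replace(config, seed=int(ss.generate_state(1)[0] % 2**31))
        cohort = generate_cohort(rep_config)
        for feat in FEATURES:
            t = feature_table(cohort, feat, "all")
            if t.has_zero_cell():
                est = ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))
            else:
                est = odds_ratio(t)
            estimates[feat].append(est)

    rows = []
    for feat in FEATURES:
        est = np.asarray(estimates[feat])
        gen = implied_marginal_or(config, feat)
        lo, hi = np.percentile(est, [2.5, 97.5])
        covered = bool(lo <= gen <= hi) if math.isfinite(gen) else True
        rows.append(
            {"feature": feat, "generating_or": gen, "est_median": float(np.median(est)),
             "band_low": float(lo), "band_high": float(hi), "flag": not covered}
        )
    return RecoveryReport(table=pd.DataFrame(rows), n_reps=n_reps)
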