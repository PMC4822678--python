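"""2x2 feature-vs-mutation statistics: odds ratios, CIs, exact tests.

Conventions follow the study's reporting: the cross-product odds ratio
(a.d)/(b.c) with a Woolf (logit) 95% CI when all cells are positive, and
conditional-exact limits (inversion of the noncentral hypergeometric) when any
cell is zero; two-sided Fisher's exact p-values use the point-probability
summation convention; Mann-Whitney U compares continuous variables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .errors import CohortValidationError, DegenerateTableError
from .phenotype_model import AgeGroup, Cohort, MutationStatus, PatientRecord

logger = logging.getLogger(__name__)


@dataclass
class TwoByTwoTable:
    """Counts for one clinical feature against mutation status.

    ``a``/``b`` are feature-present/absent among cases (mutation carriers);
    ``c``/``d`` are feature-present/absent among controls (mutation-negative).
    """

    a: int
    b: int
    c: int
    d: int
    feature_label: str = ""
    outcome_label: str = "HNF1B mutation"

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise DegenerateTableError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise DegenerateTableError("empty 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def degenerate_margin(self) -> bool:
        return 0 in (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass
class OrResult:
    or_point: float  # may be 0, +inf, or nan (undefined)
    ci_low: float
    ci_high: float
    ci_method: str  # "woolf" or "exact"
    p_value: float


@dataclass
class RankTestResult:
    u_statistic: float
    p_value: float
    median_x: float
    median_y: float
    iqr_x: tuple[float, float]
    iqr_y: tuple[float, float]


def odds_ratio(t: TwoByTwoTable) -> float:
    """Cross-product odds ratio (a.d)/(b.c).

    Returns 0 when a.d = 0 and b.c > 0, ``inf`` when b.c = 0 and a.d > 0, and
    ``nan`` (undefined) when both products vanish.
    """
    if t.a == t.b == t.c == t.d == 0:  # unreachable given __post_init__, kept for clarity
        raise DegenerateTableError("all-zero table")
    ad, bc = t.a * t.d, t.b * t.c
    if ad == 0 and bc == 0:
        return math.nan
    if bc == 0:
        return math.inf
    return ad / bc


def woolf_ci(t: TwoByTwoTable, level: float = 0.95) -> tuple[float, float]:
    """Woolf (logit) confidence interval; requires all four cells positive."""
    if t.has_zero_cell():
        raise DegenerateTableError("woolf_ci requires all cells > 0; use exact_or_ci")
    z = stats.norm.ppf((1 + level) / 2)
    log_or = math.log(odds_ratio(t))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def _midp_tail(t: TwoByTwoTable, psi: float, upper: bool) -> float:
    """Mid-p tail probability of the conditional (noncentral hypergeometric) law."""
    M, n, N = t.n, t.a + t.b, t.a + t.c
    dist = stats.nchypergeom_fisher(M, n, N, psi)
    if upper:
        return dist.cdf(t.a - 1) + 0.5 * dist.pmf(t.a)
    return dist.sf(t.a) + 0.5 * dist.pmf(t.a)


def exact_or_ci(t: TwoByTwoTable, level: float = 0.95, midp: bool = False) -> tuple[float, float]:
    """Conditional-exact OR limits by inversion of the noncentral hypergeometric.

    The default inverts the exact tail probabilities at alpha/2 (Cornfield-style
    limits, as computed by ``scipy.stats.contingency.odds_ratio``).  ``midp=True``
    counts only half the observed table's probability in each tail, giving the
    narrower mid-p limits some clinical packages report for zero-cell tables.

    The lower limit is exactly 0 when ``a`` is at its conditional minimum, and
    the upper limit is ``inf`` when ``a`` is at its conditional maximum.
    """
    if t.degenerate_margin():
        raise DegenerateTableError("exact_or_ci requires both margins positive")
    if not midp:
        ci = _scipy_odds_ratio(t.as_array(), kind="conditional").confidence_interval(level)
        return float(ci.low), float(ci.high)

    alpha = (1 - level) / 2
    x_min = max(0, (t.a + t.c) - (t.c + t.d))
    x_max = min(t.a + t.b, t.a + t.c)

    def invert(upper: bool) -> float:
        f = lambda log_psi: _midp_tail(t, math.exp(log_psi), upper) - alpha
        return math.exp(brentq(f, -50.0, 50.0))

    if t.a == x_min:
        low = 0.0
    else:
        low = invert(upper=False)
    if t.a == x_max:
        high = math.inf
    else:
        high = invert(upper=True)
    return low, high


def fisher_exact(t: TwoByTwoTable) -> float:
    """Two-sided Fisher's exact p (point-probability summation convention)."""
    if t.degenerate_margin():
        logger.warning("degenerate margins for %s; Fisher p set to 1", t.feature_label or "table")
        return 1.0
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def or_result(t: TwoByTwoTable, level: float = 0.95, midp: bool = False) -> OrResult:
    """Point OR, CI (Woolf when all cells positive, exact otherwise), Fisher p."""
    point = odds_ratio(t)
    if t.has_zero_cell():
        low, high = exact_or_ci(t, level, midp=midp)
        method = "exact"
    else:
        low, high = woolf_ci(t, level)
        method = "woolf"
    return OrResult(or_point=point, ci_low=low, ci_high=high, ci_method=method, p_value=fisher_exact(t))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U test with group medians and IQRs.

    Exact enumeration is used for small samples (n1 + n2 <= 12, no ties);
    otherwise the tie-corrected normal approximation.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CohortValidationError("mann_whitney requires two non-empty samples")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankTestResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_x=float(np.median(x)),
        median_y=float(np.median(y)),
        iqr_x=(float(np.percentile(x, 25)), float(np.percentile(x, 75))),
        iqr_y=(float(np.percentile(y, 25)), float(np.percentile(y, 75))),
    )


# ---------------------------------------------------------------------------
# cohort -> 2x2 tables
# ---------------------------------------------------------------------------


def _either_kidney(field: str) -> Callable[[PatientRecord], bool]:
    return lambda r: getattr(r.kidney_left, field) or getattr(r.kidney_right, field)


#: Presence predicates for the clinical features tabulated against mutation
#: status, in the study's reporting order.
FEATURE_PREDICATES: dict[str, Callable[[PatientRecord], bool]] = {
    "antenatal_renal_abnormalities": lambda r: r.antenatal_abnormality,
    "hyperechogenicity": _either_kidney("hyperechogenicity"),
    "renal_cysts": _either_kidney("cysts"),
    "hypoplasia": _either_kidney("hypoplasia"),
    "multicystic_dysplastic_kidney": _either_kidney("multicystic_dysplastic"),
    "urinary_tract_malformations": _either_kidney("urinary_tract_malformation"),
    "solitary_kidney": lambda r: r.solitary_kidney,
    "glomerular_cysts_or_oligomeganephronia": lambda r: r.biopsy_glomerular_cysts_or_oligomeganephronia,
    "diabetes_young_onset": lambda r: r.diabetes_young_onset,
    "pancreatic_hypoplasia_or_exocrine_failure": lambda r: r.pancreatic_hypoplasia_or_exocrine_failure,
    "family_history": lambda r: r.family_history,
    "genital_tract_malformations": lambda r: r.genital_tract_malformation,
    "liver_test_abnormalities": lambda r: r.liver_test_abnormality,
    "hypomagnesaemia": lambda r: r.hypomagnesaemia,
    "early_onset_gout": lambda r: r.early_onset_gout,
}

FEATURES: tuple[str, ...] = tuple(FEATURE_PREDICATES)


def feature_table(cohort: Cohort, feature: str, subgroup: str = "all") -> TwoByTwoTable:
    """Cross-tabulate one feature against mutation status in a subgroup.

    Records with unknown mutation status are excluded (and counted in a log
    line); ``subgroup`` is one of ``all``, ``child``, ``adult``.
    """
    if feature not in FEATURE_PREDICATES:
        raise KeyError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    if subgroup not in {"all", "child", "adult"}:
        raise CohortValidationError(f"subgroup must be all/child/adult, got {subgroup!r}")
    present = FEATURE_PREDICATES[feature]

    a = b = c = d = n_unknown = 0
    for rec in cohort:
        if subgroup != "all" and rec.age_group != AgeGroup(subgroup):
            continue
        if rec.mutation_status is MutationStatus.UNKNOWN:
            n_unknown += 1
            continue
        case = rec.mutation_status is MutationStatus.MUTATION
        if present(rec):
            a, c = (a + 1, c) if case else (a, c + 1)
        else:
            b, d = (b + 1, d) if case else (b, d + 1)
    if n_unknown:
        logger.info("feature_table(%s, %s): excluded %d records with unknown status", feature, subgroup, n_unknown)
    if a + b + c + d == 0:
        raise CohortValidationError(f"no records with known mutation status in subgroup {subgroup!r}")
    return TwoByTwoTable(a, b, c, d, feature_label=feature)


def format_or(value: float) -> str:
    """Round to 1 dp below 100 and whole numbers at >=100; infinity as 'inf'."""
    if math.isnan(value):
        return "nan"
    if math.isinf(value):
        return "inf"
    return f"{value:.0f}" if value >= 100 else f"{value:.1f}"


def association_report(cohort: Cohort, subgroup: str = "all", level: float = 0.95, midp: bool = False):
    """One row per feature mirroring the study's characteristics table."""
    import pandas as pd

    rows = []
    for feature in FEATURES:
        t = feature_table(cohort, feature, subgroup)
        res = or_result(t, level, midp=midp)
        n_case, n_ctrl = t.a + t.b, t.c + t.d
        rows.append(
            {
                "feature": feature,
                "subgroup": subgroup,
                "n_mutation": t.a,
                "pct_mutation": 100 * t.a / n_case if n_case else math.nan,
                "n_normal": t.c,
                "pct_normal": 100 * t.c / n_ctrl if n_ctrl else math.nan,
                "p_value": res.p_value,
                "odds_ratio": res.or_point,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "ci_method": res.ci_method,
                "or_formatted": f"{format_or(res.or_point)} ({format_or(res.ci_low)}-{format_or(res.ci_high)})",
            }
        )
    return pd.DataFrame(rows)
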