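"""Mantel-Haenszel pooling of stratum 2x2 tables with RBG confidence intervals.

The fixed-effect pooled odds ratio across strata i is

    OR_MH = sum_i(a_i d_i / n_i) / sum_i(b_i c_i / n_i)

with the Robins-Breslow-Greenland (RBG) estimator of Var(log OR_MH):

    V = sum(P R) / (2 R.^2) + sum(P S + Q R) / (2 R. S.) + sum(Q S) / (2 S.^2)

where P = (a+d)/n, Q = (b+c)/n, R = ad/n, S = bc/n and R., S. are their sums.
Zero cells within a stratum need no continuity correction — the stratum simply
contributes its defined terms; a stratum with an empty margin carries no
information about the odds ratio and is dropped with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd
from scipy import stats

from .association_stats import OrResult, TwoByTwoTable, or_result
from .errors import CohortValidationError, DegenerateTableError

logger = logging.getLogger(__name__)


@dataclass
class StratumSet:
    """Ordered (stratum label, 2x2 table) pairs for one clinical feature."""

    feature_label: str
    strata: list[tuple[str, TwoByTwoTable]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.strata:
            raise CohortValidationError(f"{self.feature_label}: a stratum set needs >= 1 stratum")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.strata)


@dataclass
class PooledOrResult:
    feature_label: str
    or_mh: float
    ci_low: float
    ci_high: float
    k: int  # number of informative strata pooled
    per_stratum: dict[str, OrResult]


def mh_pooled_or(s: StratumSet, level: float = 0.95) -> PooledOrResult:
    """Pool a stratum set into a Mantel-Haenszel OR with an RBG-variance CI."""
    usable: list[TwoByTwoTable] = []
    per_stratum: dict[str, OrResult] = {}
    for label, t in s.strata:
        if t.degenerate_margin():
            logger.warning("%s: dropping stratum %r with an empty margin", s.feature_label, label)
            continue
        usable.append(t)
        per_stratum[label] = or_result(t, level)
    if not usable:
        raise DegenerateTableError(f"{s.feature_label}: all strata degenerate")

    # exact rational arithmetic for the point estimate: a single stratum then
    # reduces to its cross-product OR without floating-point drift
    r_frac = sum(Fraction(t.a * t.d, t.n) for t in usable)
    s_frac = sum(Fraction(t.b * t.c, t.n) for t in usable)
    if s_frac == 0 or r_frac == 0:
        raise DegenerateTableError(
            f"{s.feature_label}: Mantel-Haenszel OR undefined (sum of ad/n or bc/n is zero)"
        )
    or_mh = float(r_frac / s_frac)
    r_sum, s_sum = float(r_frac), float(s_frac)

    pr = sum(((t.a + t.d) / t.n) * (t.a * t.d / t.n) for t in usable)
    ps_qr = sum(
        ((t.a + t.d) / t.n) * (t.b * t.c / t.n) + ((t.b + t.c) / t.n) * (t.a * t.d / t.n)
        for t in usable
    )
    qs = sum(((t.b + t.c) / t.n) * (t.b * t.c / t.n) for t in usable)
    var_log = pr / (2 * r_sum**2) + ps_qr / (2 * r_sum * s_sum) + qs / (2 * s_sum**2)

    z = stats.norm.ppf((1 + level) / 2)
    half_width = z * math.sqrt(var_log)
    return PooledOrResult(
        feature_label=s.feature_label,
        or_mh=or_mh,
        ci_low=math.exp(math.log(or_mh) - half_width),
        ci_high=math.exp(math.log(or_mh) + half_width),
        k=len(usable),
        per_stratum=per_stratum,
    )


def forest_table(features: list[StratumSet], level: float = 0.95) -> pd.DataFrame:
    """Forest-plot table: one row per feature with the pooled and stratum ORs.

    All stratum sets must share the same ordered stratum labels.  The result is
    directly serialisable to CSV and usable as a plot-ready structure.
    """
    if not features:
        return pd.DataFrame(
            columns=["feature", "or_mh", "ci_low", "ci_high", "k"]
        )
    labels = features[0].labels
    rows = []
    for s in features:
        if s.labels != labels:
            raise CohortValidationError(
                f"{s.feature_label}: stratum labels {s.labels} do not match {labels}"
            )
        pooled = mh_pooled_or(s, level)
        row: dict[str, object] = {
            "feature": s.feature_label,
            "or_mh": pooled.or_mh,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "k": pooled.k,
        }
        for label in labels:
            res = pooled.per_stratum.get(label)
            row[f"or_{label}"] = res.or_point if res is not None else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
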