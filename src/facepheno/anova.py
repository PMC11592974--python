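"""One-way ANOVA significance screening of the 18 coarse features.

Each binary coarse feature V1..V18 is tested for a group difference
(ASD vs TD) with a textbook one-way decomposition:

    SS_between = sum_g n_g (mean_g - grand_mean)^2,   df_between = g - 1
    SS_within  = sum_g sum_i (x_gi - mean_g)^2,       df_within  = n - g
    F = MS_between / MS_within,  p = upper tail of F(df_between, df_within)

The reporting order follows the slice-major variable table: V_{3(k-1)+1}
is the head-pose (attention) flag of slice k, V_{3(k-1)+2} the expression-
category (happy) flag, V_{3(k-1)+3} the expression-intensity flag.  This
differs from the coarse vector's block order, so the report carries the
mapping between the two.  The ANOVA runs on the 0/1 features directly (no
continuity correction); printed p-values use 3 decimals, with "0.000"
meaning p < 0.0005, and a Bonferroni-adjusted column is included as an
optional extra beyond the reference analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateVarianceError",
    "AnovaResult",
    "one_way_anova",
    "feature_label_map",
    "significance_report",
    "format_p",
]

_SS_TOL = 1e-9

FEATURE_TYPES = ("head pose", "expression category", "expression intensity")


class DegenerateVarianceError(ValueError):
    """Zero within-group variance: the F statistic is undefined."""


@dataclass(frozen=True)
class AnovaResult:
    """One feature's decomposition (a row of the significance table)."""

    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    F: float
    p: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within


def one_way_anova(values, groups) -> AnovaResult:
    """Textbook one-way ANOVA of ``values`` across the levels of ``groups``."""
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if x.shape != g.shape or x.ndim != 1:
        raise ValueError("values and groups must be equal-length 1-D")
    levels, inverse = np.unique(g, return_inverse=True)
    n, k = x.size, levels.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    if n <= k:
        raise ValueError("need more observations than groups")
    grand = x.mean()
    ss_b = 0.0
    ss_w = 0.0
    for j in range(k):
        xj = x[inverse == j]
        if xj.size == 0:
            raise ValueError("every group must be non-empty")
        ss_b += xj.size * (xj.mean() - grand) ** 2
        ss_w += float(((xj - xj.mean()) ** 2).sum())
    df_b, df_w = k - 1, n - k
    # Conservation check: SS_total computed independently must match.
    ss_t = float(((x - grand) ** 2).sum())
    assert abs(ss_t - (ss_b + ss_w)) <= _SS_TOL * max(1.0, ss_t)
    if ss_w <= 0.0:
        raise DegenerateVarianceError(
            "zero within-group variance; F undefined"
        )
    F = (ss_b / df_b) / (ss_w / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(ss_between=float(ss_b), ss_within=float(ss_w),
                       df_between=df_b, df_within=df_w, F=float(F), p=p)


def feature_label_map(K: int = 6) -> pd.DataFrame:
    """V1..V3K <-> (slice, feature type) <-> coarse-vector position.

    The coarse vector is block-ordered [intensity | happy | attention];
    the variable table is slice-major (head pose, category, intensity per
    slice), so this bijection is emitted alongside every report.
    """
    rows = []
    for k in range(1, K + 1):
        positions = {"head pose": 2 * K + (k - 1),
                     "expression category": K + (k - 1),
                     "expression intensity": k - 1}
        for j, ftype in enumerate(FEATURE_TYPES):
            rows.append({
                "variable": f"V{3 * (k - 1) + j + 1}",
                "feature": f"{ftype.capitalize()} in slice {k}",
                "slice": k,
                "feature_type": ftype,
                "coarse_index": positions[ftype],
            })
    return pd.DataFrame(rows)


def format_p(p: float) -> str:
    """3-decimal p with the "0.000" = p < 0.0005 convention."""
    return f"{p:.3f}"


def significance_report(coarse_features, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable ANOVA table over a cohort's coarse feature matrix.

    ``coarse_features`` is (n_subjects, 3K); ``groups`` the subject labels.
    Degenerate features (identical for every subject within groups) are
    reported as not testable rather than erroring the whole report.
    Full-precision p-values are kept in ``p``; ``p_printed`` applies the
    3-decimal display convention.  ``p_bonferroni`` is an optional extra
    (not part of the reference analysis).
    """
    X = np.asarray(coarse_features, dtype=float)
    g = np.asarray(groups)
    levels, counts = np.unique(g, return_counts=True)
    if (counts < 2).any():
        raise ValueError("need at least 2 subjects per group")
    K = X.shape[1] // 3
    label_map = feature_label_map(K)
    m = X.shape[1]
    rows = []
    for _, entry in label_map.iterrows():
        col = X[:, int(entry["coarse_index"])]
        row = dict(entry)
        try:
            res = one_way_anova(col, g)
            row.update(
                ss_between=res.ss_between, ss_within=res.ss_within,
                ss_total=res.ss_total, df_between=res.df_between,
                df_within=res.df_within, ms_between=res.ms_between,
                ms_within=res.ms_within, F=res.F, p=res.p,
                p_printed=format_p(res.p), significant=bool(res.p < alpha),
                p_bonferroni=min(1.0, res.p * m), testable=True,
            )
        except DegenerateVarianceError:
            row.update(
                ss_between=np.nan, ss_within=0.0, ss_total=np.nan,
                df_between=len(levels) - 1, df_within=len(g) - len(levels),
                ms_between=np.nan, ms_within=0.0, F=np.nan, p=np.nan,
                p_printed="not testable", significant=False,
                p_bonferroni=np.nan, testable=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)
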