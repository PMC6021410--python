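"""Group statistics: normality gate, location comparisons, Mankin classes.

Routing follows common biomedical practice for small-cohort morphometry:
each group's values are tested with the D'Agostino-Pearson omnibus
normality test; parametric tests (one-way ANOVA, two-sample t) are used
when every group passes at alpha = 0.05, non-parametric equivalents
(Kruskal-Wallis, Mann-Whitney U) otherwise.  Which branch ran is recorded
in every result so reports can flag non-parametric entries.

Pairwise location p-values are reported raw by default; Holm correction is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normality_test",
    "compare_locations",
    "classify_mankin",
    "compare_classes",
    "LocationComparison",
    "ClassComparison",
]

ALPHA = 0.05
MIN_N_NORMALITY = 8


def normality_test(values) -> tuple[float, float, bool]:
    """D'Agostino-Pearson omnibus K^2 test.

    Returns (statistic, p, passed) with passed = (p > 0.05).  Requires
    n >= 8 (the skewness/kurtosis z-scores are undefined below that).
    """
    x = np.asarray(values, dtype=float)
    if x.size < MIN_N_NORMALITY:
        raise ValueError(
            f"normality test needs n >= {MIN_N_NORMALITY}, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant sample")
    stat, p = stats.normaltest(x)
    return float(stat), float(p), bool(p > ALPHA)


@dataclass
class LocationComparison:
    parameter: str
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    pairwise_test: str
    pairwise_p: pd.DataFrame
    all_normal: bool
    group_normality: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.omnibus_p < ALPHA


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_locations(
    table: pd.DataFrame,
    parameter: str,
    group_col: str = "location",
    holm: bool = False,
) -> LocationComparison:
    """Omnibus + pairwise comparison of a parameter across locations.

    ANOVA + pairwise t when every group passes normality; Kruskal-Wallis +
    pairwise Mann-Whitney otherwise.  Groups smaller than the normality
    test's minimum are treated as non-normal (conservative routing).
    """
    groups = {g: sub[parameter].to_numpy(dtype=float) for g, sub in table.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    normality: dict[str, bool] = {}
    for g, v in groups.items():
        if v.size >= MIN_N_NORMALITY and np.ptp(v) > 0:
            _, _, passed = normality_test(v)
        else:
            passed = False
        normality[g] = passed
    all_normal = all(normality.values())

    names = sorted(groups)
    values = [groups[g] for g in names]
    if all_normal:
        stat, p = stats.f_oneway(*values)
        omnibus = "anova"
        pair_name = "t-test"

        def pair(a, b):
            return stats.ttest_ind(a, b).pvalue
    else:
        stat, p = stats.kruskal(*values)
        omnibus = "kruskal-wallis"
        pair_name = "mann-whitney"

        def pair(a, b):
            return stats.mannwhitneyu(a, b, alternative="two-sided").pvalue

    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    raw = []
    pairs = []
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            a, b = groups[gi], groups[gj]
            if np.ptp(np.concatenate([a, b])) == 0:
                pv = 1.0  # identical constant groups: no evidence of difference
            else:
                pv = float(pair(a, b))
            raw.append(pv)
            pairs.append((gi, gj))
    if holm and raw:
        raw = list(_holm(np.array(raw)))
    for (gi, gj), pv in zip(pairs, raw):
        pmat.loc[gi, gj] = pv
        pmat.loc[gj, gi] = pv

    return LocationComparison(
        parameter=parameter,
        omnibus_test=omnibus,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        pairwise_test=pair_name,
        pairwise_p=pmat,
        all_normal=all_normal,
        group_normality=normality,
    )


def classify_mankin(scores) -> np.ndarray:
    """Class1 for Mankin < 4, Class2 for > 4, unclassified at exactly 4.

    Score 4 sits on neither side of the two strict inequalities defining the
    classes, so such samples are excluded from class comparisons.
    """
    s = np.asarray(scores)
    if np.any((s < 0) | (s > 14)):
        raise ValueError("Mankin scores must lie in the 0-14 scale")
    return np.where(s < 4, "Class1", np.where(s > 4, "Class2", "unclassified"))


@dataclass
class ClassComparison:
    parameter: str
    test: str
    statistic: float
    p_value: float
    summaries: pd.DataFrame  # mean, 95 % CI bounds, n per class
    normal: bool
    n_unclassified: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    m = float(values.mean())
    if values.size < 2:
        return m, np.nan, np.nan
    half = stats.t.ppf(0.5 + level / 2, values.size - 1) * stats.sem(values)
    return m, m - half, m + half


def compare_classes(
    table: pd.DataFrame,
    parameter: str,
    score_col: str = "mankin",
) -> ClassComparison:
    """Class1 vs Class2 comparison of a parameter, normality-gated.

    Two-sample t-test when both classes pass the omnibus normality test,
    Mann-Whitney U otherwise.  Summaries are mean with 95 % t-interval.
    """
    labels = classify_mankin(table[score_col].to_numpy())
    n_uncl = int((labels == "unclassified").sum())
    vals = {
        c: table.loc[labels == c, parameter].to_numpy(dtype=float)
        for c in ("Class1", "Class2")
    }
    for c, v in vals.items():
        if v.size == 0:
            raise ValueError(f"{c} is empty; cannot compare classes")

    normal = True
    for v in vals.values():
        if v.size < MIN_N_NORMALITY or np.ptp(v) == 0:
            normal = False
            break
        _, _, passed = normality_test(v)
        normal = normal and passed

    a, b = vals["Class1"], vals["Class2"]
    if np.ptp(np.concatenate([a, b])) == 0:
        test, stat, p = ("t-test" if normal else "mann-whitney"), 0.0, 1.0
    elif normal:
        res = stats.ttest_ind(a, b)
        test, stat, p = "t-test", float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test, stat, p = "mann-whitney", float(res.statistic), float(res.pvalue)

    rows = []
    for c in ("Class1", "Class2"):
        m, lo, hi = _mean_ci(vals[c])
        rows.append({"class": c, "n": vals[c].size, "mean": m, "ci_lo": lo, "ci_hi": hi})
    return ClassComparison(
        parameter=parameter,
        test=test,
        statistic=stat,
        p_value=p,
        summaries=pd.DataFrame(rows).set_index("class"),
        normal=normal,
        n_unclassified=n_uncl,
    )
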