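"""Group statistics: D'Agostino normality gate, Mann-Whitney, paired t.

All tests are two-tailed.  The unpaired contrast between age groups is always
reported with the Mann-Whitney test (normality is recorded but does not switch
the test); the central-vs-peripheral contrast within animals uses a paired
two-tailed t-test.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

MIN_DAGOSTINO_N = 8


def dagostino_normality(sample) -> Tuple[float, float]:
    """D'Agostino-Pearson omnibus K^2 test (skewness + kurtosis z-scores).

    Requires at least 8 observations; below that the kurtosis z-score is
    undefined and an error is raised naming the minimum.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < MIN_DAGOSTINO_N:
        raise ValueError(
            f"D'Agostino normality test requires n >= {MIN_DAGOSTINO_N} "
            f"(got n = {x.size})"
        )
    stat, p = sps.normaltest(x)
    return float(stat), float(p)


def mann_whitney(a, b) -> Tuple[float, float]:
    """Two-tailed Mann-Whitney U.

    Exact enumeration when n_a * n_b <= 400 and the pooled data are tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size * b.size <= 400 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def paired_t(a, b) -> Tuple[float, float]:
    """Paired two-tailed t-test on per-animal differences.

    All-zero differences return (0, 1) by convention; non-zero constant
    differences leave t undefined and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError(
            "paired differences are constant and non-zero; t is undefined"
        )
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass
class GroupComparison:
    measure: str
    test: str
    statistic: float
    p_value: float
    group_summaries: dict  # name -> dict(mean, sd, n)
    normality: dict  # name -> (K2, p) or None when n < 8

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def compare_groups(
    table: pd.DataFrame,
    measure: str,
    paired: bool = False,
    group_col: str = "age_group",
    value_col: str = "value",
    pair_col: str = "animal_id",
    paired_measures: Optional[Tuple[str, str]] = None,
) -> GroupComparison:
    """Compare one measure between two groups from a long per-animal table.

    Unpaired: two-tailed Mann-Whitney between the two levels of
    ``group_col``.  Paired (``paired=True`` with ``paired_measures`` naming
    the two measures, e.g. central vs peripheral density): paired two-tailed
    t-test on per-animal pairs matched by ``pair_col``.  Normality of each
    sample is recorded (when n >= 8) but does not switch the test.
    """
    if paired:
        if paired_measures is None:
            raise ValueError("paired comparison requires paired_measures")
        m1, m2 = paired_measures
        t1 = table[table["measure"] == m1].set_index(pair_col)[value_col]
        t2 = table[table["measure"] == m2].set_index(pair_col)[value_col]
        if t1.index.duplicated().any() or t2.index.duplicated().any():
            raise ValueError("paired comparison needs one value per animal")
        common = t1.index.intersection(t2.index)
        if len(common) < len(t1) or len(common) < len(t2):
            raise ValueError("pairing key mismatch between the two measures")
        a = t1.loc[common].to_numpy()
        b = t2.loc[common].to_numpy()
        stat, p = paired_t(a, b)
        samples = {m1: a, m2: b}
        test = "paired_t"
    else:
        sub = table[table["measure"] == measure]
        groups = sub[group_col].unique()
        if len(groups) != 2:
            raise ValueError(
                f"expected exactly 2 groups for {measure!r}, got {list(groups)}"
            )
        samples = {
            g: sub.loc[sub[group_col] == g, value_col].to_numpy() for g in groups
        }
        a, b = samples[groups[0]], samples[groups[1]]
        stat, p = mann_whitney(a, b)
        test = "mann_whitney"

    normality = {}
    for name, x in samples.items():
        normality[name] = (
            dagostino_normality(x) if len(x) >= MIN_DAGOSTINO_N else None
        )
    summaries = {
        name: dict(mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)), n=len(x))
        for name, x in samples.items()
    }
    return GroupComparison(measure, test, stat, p, summaries, normality)
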