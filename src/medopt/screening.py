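"""One-factor-at-a-time screening statistics.

Carbon and nitrogen sources are screened by one-way ANOVA on inhibition-zone
diameters (mm), followed by Duncan's multiple range test, the step-down
multiple comparison whose least significant range for a stretch of p ordered
means is

    R_p = q*(alpha_p, p, df_error) * sqrt(MS_error / n),

with Duncan's protection level alpha_p = 1 - (1 - alpha)^(p - 1) and q* the
studentized-range quantile.  Groups sharing a letter are statistically
indistinguishable at the protected level; the letter 'a' goes to the stretch
containing the smallest mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .doe import DesignMatrix
from .errors import ValidationError

__all__ = [
    "AnovaTable",
    "DuncanGrouping",
    "one_way_anova",
    "duncan_mrt",
    "correlation_screen",
]


class AnovaTable:
    """Source/SS/DF/MS/F/p table with additivity invariants.

    Thin wrapper over a DataFrame with columns source, SS, DF, MS, F, p.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"source", "SS", "DF", "MS", "F", "p"}
        if not required.issubset(frame.columns):
            raise ValidationError(f"ANOVA table needs columns {sorted(required)}")
        if (frame["SS"] < -1e-9).any():
            raise ValidationError("negative sum of squares")
        self.frame = frame.reset_index(drop=True)
        self.r2: float | None = None

    def row(self, source: str) -> pd.Series:
        match = self.frame[self.frame["source"] == source]
        if match.empty:
            raise KeyError(source)
        return match.iloc[0]

    def __repr__(self) -> str:  # pragma: no cover
        return f"AnovaTable(\n{self.frame}\n)"


def _validate_screening(data: pd.DataFrame, group_col: str, value_col: str) -> pd.DataFrame:
    if group_col not in data.columns or value_col not in data.columns:
        raise ValidationError(f"screening data needs columns {group_col!r} and {value_col!r}")
    vals = data[value_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValidationError("replicate values must be finite and positive")
    sizes = data.groupby(group_col, sort=False)[value_col].size()
    if len(sizes) < 2:
        raise ValidationError("need at least 2 groups")
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValidationError(
            f"group(s) with fewer than 2 replicates leave no error degrees of "
            f"freedom: {list(small.index)}"
        )
    return data


def one_way_anova(
    data: pd.DataFrame,
    group_col: str = "source",
    value_col: str = "zone_mm",
) -> AnovaTable:
    """One-way fixed-effects ANOVA of replicate measurements by group.

    Accepts balanced or unbalanced groups in long format.  Between-group SS
    is sum_i n_i (mean_i - grand_mean)^2; F = MS_between / MS_within with the
    p-value from the upper tail of the F distribution.  With zero
    within-group variance and unequal means, F is +inf with p = 0.
    """
    data = _validate_screening(data, group_col, value_col)
    d = data.rename(columns={group_col: "grp", value_col: "val"})
    fit = smf.ols("val ~ C(grp)", data=d).fit()
    aov = sm.stats.anova_lm(fit, typ=1)
    ss_b, df_b = float(aov["sum_sq"].iloc[0]), int(aov["df"].iloc[0])
    ss_w, df_w = float(aov["sum_sq"].iloc[1]), int(aov["df"].iloc[1])
    ms_b, ms_w = ss_b / df_b, ss_w / df_w
    # guard degenerate partitions against floating-point dust in the SS
    scale = float(np.sum(d["val"].to_numpy() ** 2))
    tiny = 1e-12 * max(scale, 1.0)
    if ss_b <= tiny:
        f_val, p_val = 0.0, 1.0
        ss_b = ms_b = 0.0
    elif ss_w <= tiny:
        f_val, p_val = float("inf"), 0.0
    else:
        f_val = ms_b / ms_w
        p_val = float(stats.f.sf(f_val, df_b, df_w))
    rows = [
        ("between", ss_b, df_b, ms_b, f_val, round(p_val, 6)),
        ("within", ss_w, df_w, ms_w, np.nan, np.nan),
        ("total", ss_b + ss_w, df_b + df_w, np.nan, np.nan, np.nan),
    ]
    return AnovaTable(pd.DataFrame(rows, columns=["source", "SS", "DF", "MS", "F", "p"]))


@dataclass(frozen=True)
class DuncanGrouping:
    """Letter display of Duncan's multiple range test.

    ``letters[label]`` is the set of homogeneity letters the group belongs
    to; groups sharing any letter are not significantly different.
    """

    means: dict[str, float]
    letters: dict[str, frozenset[str]]
    alpha: float
    least_significant_ranges: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        order = sorted(self.means, key=self.means.get)
        return pd.DataFrame(
            {
                "group": order,
                "mean": [self.means[g] for g in order],
                "letters": ["".join(sorted(self.letters[g])) for g in order],
            }
        )

    def share_letter(self, a: str, b: str) -> bool:
        return bool(self.letters[a] & self.letters[b])


def _letter(i: int) -> str:
    # a, b, ..., z, aa, ab, ... for pathological group counts
    s = ""
    while True:
        s = chr(ord("a") + i % 26) + s
        i = i // 26 - 1
        if i < 0:
            return s


def duncan_mrt(
    means: dict[str, float],
    n_per_group: int,
    ms_error: float,
    df_error: int,
    alpha: float = 0.05,
) -> DuncanGrouping:
    """Duncan's multiple range test over balanced group means.

    Step-down procedure: the full stretch of g ordered means is tested
    against R_g; a significant stretch is split into its two (p-1)-subsets
    and retested; a non-significant stretch is declared homogeneous and its
    interior is not tested further.  Maximal homogeneous stretches receive
    letters in ascending-mean order.  Quantiles of the studentized range are
    computed numerically (no table lookup), so any error df is supported.
    """
    if ms_error <= 0:
        raise ValidationError("ms_error must be positive")
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2 (balanced groups)")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    labels = sorted(means, key=lambda k: (means[k], k))
    m = np.asarray([means[k] for k in labels], dtype=float)
    g = len(m)
    if g < 2:
        raise ValidationError("need at least 2 groups")

    se = np.sqrt(ms_error / n_per_group)
    lsr: dict[int, float] = {}
    for p in range(2, g + 1):
        protected = 1.0 - (1.0 - alpha) ** (p - 1)
        lsr[p] = float(stats.studentized_range.ppf(1.0 - protected, p, df_error) * se)

    homogeneous: set[tuple[int, int]] = set()
    tested: set[tuple[int, int]] = set()

    def step_down(i: int, j: int) -> None:
        if j <= i or (i, j) in tested:
            return
        tested.add((i, j))
        p = j - i + 1
        if m[j] - m[i] >= lsr[p]:
            step_down(i, j - 1)
            step_down(i + 1, j)
        else:
            homogeneous.add((i, j))

    step_down(0, g - 1)
    # drop stretches nested inside a larger homogeneous stretch
    maximal = [
        (i, j)
        for (i, j) in homogeneous
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in homogeneous)
    ]
    covered = set()
    for i, j in maximal:
        covered.update(range(i, j + 1))
    for i in range(g):
        if i not in covered:
            maximal.append((i, i))
    maximal.sort()

    letters: dict[str, set[str]] = {lab: set() for lab in labels}
    for idx, (i, j) in enumerate(maximal):
        for pos in range(i, j + 1):
            letters[labels[pos]].add(_letter(idx))
    return DuncanGrouping(
        means=dict(means),
        letters={lab: frozenset(v) for lab, v in letters.items()},
        alpha=alpha,
        least_significant_ranges=lsr,
    )


def correlation_screen(table: DesignMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations over all factor and response columns.

    Returns a symmetric matrix with unit diagonal; a constant column has no
    defined correlation and yields NaN entries rather than zeros.
    """
    if isinstance(table, DesignMatrix):
        df = table.to_frame("natural").drop(columns=["run"])
    else:
        df = table.copy()
    if len(df) < 3:
        raise ValidationError("correlation screen needs at least 3 rows")
    if df.isna().any().any():
        raise ValidationError("correlation screen does not accept missing values")
    return df.corr(method="pearson")
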