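"""Group-comparison statistics for pipeline outputs.

Unpaired t-tests (Welch by default, pooled-variance available), paired
t-tests with one- or two-tailed p-values, and fixed-effects two-way
ANOVA with interaction (classical decomposition for balanced designs,
Type-II sums of squares for unbalanced ones, via statsmodels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["TestResult", "t_test", "two_way_anova", "benjamini_hochberg"]


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    tail: str
    test: str
    group_summaries: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)


def _summaries(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, v in groups.items():
        v = np.asarray(v, dtype=float)
        sem = float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else math.nan
        rows.append({"group": name, "mean": float(v.mean()), "sem": sem, "n": len(v)})
    return pd.DataFrame(rows)


def t_test(
    groups: dict[str, np.ndarray],
    paired: bool = False,
    tail: str = "two",
    alternative: str | None = None,
    equal_var: bool = False,
) -> TestResult:
    """t-test between exactly two groups.

    ``tail="two"`` gives the two-sided p; ``tail="one"`` requires
    ``alternative`` ("greater" or "less", referring to the first group
    minus the second).  Unpaired tests use Welch's correction unless
    ``equal_var=True`` selects the classical pooled-variance form.
    Degenerate zero-variance cases are flagged: identical constant groups
    give p = 1 by convention, and a constant nonzero paired difference
    gives p = 0.
    """
    if len(groups) != 2:
        raise ValueError("t_test requires exactly two groups")
    (name_a, a), (name_b, b) = groups.items()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if tail == "one" and alternative not in ("greater", "less"):
        raise ValueError("one-tailed test needs alternative 'greater' or 'less'")
    alt = "two-sided" if tail == "two" else alternative
    flags: list[str] = []

    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires complete pairs (equal n)")
        d = a - b
        if np.std(d, ddof=1) == 0:
            df = len(d) - 1.0
            if np.all(d == 0):
                return TestResult(0.0, df, 1.0, tail, "paired t (degenerate)",
                                  _summaries(groups), ["zero_variance_identical"])
            return TestResult(math.inf if d[0] > 0 else -math.inf, df, 0.0, tail,
                              "paired t (degenerate)", _summaries(groups),
                              ["constant_nonzero_difference"])
        res = sps.ttest_rel(a, b, alternative=alt)
        name = "paired t"
        df = float(res.df)
    else:
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            df = len(a) + len(b) - 2.0
            if a.mean() == b.mean():
                return TestResult(0.0, df, 1.0, tail, "unpaired t (degenerate)",
                                  _summaries(groups), ["zero_variance_identical"])
            return TestResult(math.copysign(math.inf, a.mean() - b.mean()), df, 0.0,
                              tail, "unpaired t (degenerate)", _summaries(groups),
                              ["zero_variance_distinct_means"])
        res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=alt)
        name = "pooled t" if equal_var else "Welch t"
        df = float(res.df)
    return TestResult(
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        tail=tail,
        test=name,
        group_summaries=_summaries(groups),
        flags=flags,
    )


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction.

    Returns a tidy table with rows for each main effect, the interaction
    and the residual: columns effect, sum_sq, df, F, p.  Balanced designs
    yield the standard decomposition (for which Type-II equals the
    classical sums of squares and SS_total = sum of effect SS +
    residual SS); unbalanced designs use Type-II sums of squares.  Every
    factor-level cell must be non-empty.
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    counts = data.groupby([factor_a, factor_b], observed=True).size().unstack()
    if counts.isna().any().any() or (counts == 0).any().any():
        raise ValueError("two-way ANOVA requires every A x B cell to be non-empty")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("each factor needs >= 2 levels")
    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    label_map = {
        "C(_a)": factor_a,
        "C(_b)": factor_b,
        "C(_a):C(_b)": f"{factor_a}:{factor_b}",
        "Residual": "residual",
    }
    out = table.reset_index().rename(
        columns={"index": "effect", "PR(>F)": "p", "F": "F", "sum_sq": "sum_sq"}
    )
    out["effect"] = out["effect"].map(lambda k: label_map.get(k, k))
    return out[["effect", "sum_sq", "df", "F", "p"]]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default in pipelines)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out
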