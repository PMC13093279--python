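"""Statistical comparison layer: Welch's t, Brown-Forsythe, Holm-Bonferroni.

Setup methods are compared pairwise: differences in *means* with Welch's
unequal-variance t-test and differences in *variances* with the
Brown-Forsythe test (one-way ANOVA on absolute deviations from group
medians). For families of pairwise comparisons (all six pairs of the four
head-and-neck setups) p-values are adjusted with the Holm-Bonferroni
step-down procedure; the single abdominal pair is reported unadjusted.
All tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "welch_t",
    "brown_forsythe",
    "holm_bonferroni",
    "compare_setups",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    pvalue: float
    test: str
    group_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    ``t = (mean(x) - mean(y)) / sqrt(s1^2/n1 + s2^2/n2)`` with
    Welch-Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        pvalue=float(res.pvalue),
        test="welch_t",
        group_sizes=(x.size, y.size),
    )


def brown_forsythe(groups) -> TestResult:
    """Brown-Forsythe homogeneity-of-variance test.

    One-way ANOVA F statistic on ``z_ij = |y_ij - median(group_j)|``.
    """
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    z = [np.abs(a - np.median(a)) for a in arrs]
    if all(np.all(zi == 0) for zi in z):
        raise ValueError("degenerate: all absolute deviations are zero")
    stat, p = sps.levene(*arrs, center="median")
    n = sum(a.size for a in arrs)
    k = len(arrs)
    return TestResult(
        statistic=float(stat),
        df=float(k - 1),  # numerator df; denominator is n - k
        pvalue=float(p),
        test="brown_forsythe",
        group_sizes=tuple(a.size for a in arrs),
    )


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce monotone
    non-decrease, cap at 1.
    """
    p = np.asarray(pvals, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def compare_setups(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    alpha: float = DEFAULT_ALPHA,
    adjust: bool = True,
) -> pd.DataFrame:
    """Pairwise setup comparisons of a per-subject metric.

    ``table`` columns: ``subject``, ``setup``, ``value``. For every pair the
    Welch (means) and Brown-Forsythe (variances) tests are run; when
    ``adjust`` is true, Holm-Bonferroni is applied across the pair family,
    separately within each test. Returns one row per (pair, test) with raw
    and adjusted p plus the significance flag at ``alpha``.
    """
    for col in ("subject", "setup", "value"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    known = set(table["setup"].unique())
    rows = []
    for a, b in pairs:
        if a not in known or b not in known:
            raise ValueError(f"unknown setup label in pair ({a}, {b})")
        x = table.loc[table["setup"] == a, "value"].to_numpy()
        y = table.loc[table["setup"] == b, "value"].to_numpy()
        for res in (welch_t(x, y), brown_forsythe([x, y])):
            rows.append({
                "pair": f"{a}-{b}",
                "test": res.test,
                "statistic": res.statistic,
                "df": res.df,
                "p_raw": res.pvalue,
            })
    out = pd.DataFrame(rows)
    if adjust and len(pairs) > 1:
        out["p_adj"] = np.nan
        for test in out["test"].unique():
            sel = out["test"] == test
            out.loc[sel, "p_adj"] = holm_bonferroni(out.loc[sel, "p_raw"].to_numpy())
    else:
        out["p_adj"] = out["p_raw"]
    out["significant"] = out["p_adj"] < alpha
    out.attrs["alpha"] = alpha
    out.attrs["adjusted"] = bool(adjust and len(pairs) > 1)
    return out
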