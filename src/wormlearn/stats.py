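"""Shared statistical kernels: Welch t, two-factor ANOVA interaction, KS p.

All kernels are pure functions; two-sided tests throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .types import ValidationError

__all__ = ["TestResult", "welch_t", "anova2_interaction", "ks_asymptotic_p"]


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    test_name: str
    n_per_group: tuple
    correction: str = "none"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p-value {self.p} outside [0, 1]")

    def tier(self) -> str:
        """Significance tier string as conventionally reported."""
        if self.p < 0.001:
            return "p<0.001 (**)"
        if self.p < 0.05:
            return "p<0.05 (*)"
        return "n.s."


def welch_t(a, b) -> TestResult:
    """Two-sided t-test with correction for unequal variance.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), df by
    Welch-Satterthwaite.  Two zero-variance samples with equal means return
    t=0, p=1 by convention; with unequal means the df is degenerate and an
    error is raised.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValidationError("welch_t needs at least two observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, float(na + nb - 2), 1.0, "welch_t", (na, nb))
        raise ValidationError("both groups have zero variance but unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "welch_t", (na, nb))


def anova2_interaction(values, factor_a, factor_b) -> tuple[TestResult, pd.DataFrame]:
    """Interaction F test of a two-factor linear model (type-II SS, sum-to-zero coding).

    Returns the interaction TestResult plus a per-cell table of means and
    counts.  Every (a, b) cell must contain at least two observations.
    """
    df = pd.DataFrame(
        {"y": np.asarray(values, float), "a": list(factor_a), "b": list(factor_b)}
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValidationError("each factor needs at least two levels")
    cells = df.groupby(["a", "b"], observed=True)["y"].agg(["mean", "count"]).reset_index()
    full = {(a, b) for a in df["a"].unique() for b in df["b"].unique()}
    present = set(zip(cells["a"], cells["b"]))
    missing = sorted(full - present)
    if missing:
        raise ValidationError(f"empty design cell(s): {missing}")
    thin = sorted(
        (a, b) for a, b, n in zip(cells["a"], cells["b"], cells["count"]) if n < 2
    )
    if thin:
        raise ValidationError(f"cell(s) with fewer than two plates: {thin}")
    model = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(a, Sum):C(b, Sum)"]
    F = float(row["F"])
    p = float(row["PR(>F)"])
    dof = float(row["df"])
    result = TestResult(
        F, dof, p, "anova2_interaction", tuple(cells["count"].tolist())
    )
    return result, cells.rename(columns={"mean": "cell_mean", "count": "n"})


def ks_asymptotic_p(D: float, n_a: int, n_b: int) -> float:
    """Asymptotic two-sample Kolmogorov-Smirnov p-value.

    Evaluates the Kolmogorov survival function at D*sqrt(n_a*n_b/(n_a+n_b)).
    """
    if not (0.0 <= D <= 1.0):
        raise ValidationError("D must lie in [0, 1]")
    en = np.sqrt(n_a * n_b / (n_a + n_b))
    return float(np.clip(scipy.special.kolmogorov(en * D), 0.0, 1.0))
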