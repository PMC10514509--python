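"""Inferential layer: SEM, pooled-variance t-test, one-way ANOVA at α = 0.05.

Group comparisons between conditions use the classical equal-variance
Student's t-test and one-way ANOVA; dispersion is reported as mean ± SEM
with n counting organoids.  Tests are two-sided and uncorrected by default;
Holm adjustment is available for per-bin comparison families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: tuple
    significant: bool
    test: str
    degenerate: bool = False


def sem(values) -> float:
    """Standard error of the mean: sample SD (n−1 denominator) / √n."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("SEM requires n >= 2")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def t_test_unpaired(a, b, alpha: float = ALPHA) -> TestResult:
    """Two-sided Student's unpaired t-test with pooled variance.

    df = n_a + n_b − 2.  Degenerate zero-variance inputs are handled
    explicitly: equal means give t = 0, p = 1; unequal means give p = 0 with
    the degenerate flag set.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    df = na + nb - 2
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / df
    diff = float(a.mean() - b.mean())
    if sp2 == 0:
        if diff == 0:
            return TestResult(0.0, 1.0, (df,), False, "t", degenerate=True)
        return TestResult(np.inf if diff > 0 else -np.inf, 0.0, (df,),
                          True, "t", degenerate=True)
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(float(t), p, (df,), p < alpha, "t")


def one_way_anova(groups, alpha: float = ALPHA) -> TestResult:
    """One-way ANOVA: F = MS_between / MS_within; for two groups F = t²."""
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups, each n >= 2")
    n_tot = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = len(gs) - 1, n_tot - len(gs)
    if ss_within == 0:
        if ss_between == 0:
            return TestResult(0.0, 1.0, (df_b, df_w), False, "anova", degenerate=True)
        return TestResult(np.inf, 0.0, (df_b, df_w), True, "anova", degenerate=True)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(float(f), p, (df_b, df_w), p < alpha, "anova")


def holm(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional, off by default upstream)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def summarize_comparisons(comparisons: dict[str, tuple], alpha: float = ALPHA,
                          holm_adjust: bool = False) -> pd.DataFrame:
    """Run t-test and ANOVA for each labeled (a, b) pair; tidy summary table."""
    rows = []
    for label, (a, b) in comparisons.items():
        for res in (t_test_unpaired(a, b, alpha), one_way_anova([a, b], alpha)):
            rows.append({"comparison": label, "test": res.test,
                         "statistic": res.statistic,
                         "df": "/".join(str(d) for d in res.df),
                         "p_value": res.p_value, "significant": res.significant,
                         "degenerate": res.degenerate})
    df = pd.DataFrame(rows)
    if holm_adjust and len(df):
        for test in df["test"].unique():
            sel = df["test"] == test
            df.loc[sel, "p_adjusted"] = holm(df.loc[sel, "p_value"].to_numpy())
        df["significant"] = df.get("p_adjusted", df["p_value"]) < alpha
    return df
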