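"""Group statistics for turning-rate tables.

The assay's summary layer: per-cell mean ± SEM (n) for a chosen minute,
two-group Student's t comparisons of the 5th-minute rates, and the
genotype × osmolarity two-way fixed-effects ANOVA whose interaction term
asks whether a genotype alters the response to the osmotic upshift.
Designs are frequently unbalanced (cells differ in n), so Type II sums
of squares are used; on balanced designs they coincide with Type I.
"""

from __future__ import annotations

import warnings
from collections import namedtuple

import numpy as np
import pandas as pd
from scipy import stats as sps

TTestResult = namedtuple("TTestResult", ["t", "df", "p"])


def summarize(table: pd.DataFrame, minute: int = 5,
              factors: tuple[str, str] = ("genotype", "condition"),
              value: str = "turns_per_min") -> pd.DataFrame:
    """Per-cell mean ± SEM (n) of the chosen minute's rates.

    ``table`` is long-format with one row per animal × minute.  SEM is
    SD/√n with ddof=1; a single-observation cell reports SEM as missing
    (NaN).  Cells absent from the data are omitted with a warning.
    """
    sel = table[table["minute"] == minute]
    if sel.empty:
        raise ValueError(f"minute {minute} not present in table")
    expected = 1
    for f in factors:
        expected *= table[f].nunique()
    grouped = sel.groupby(list(factors), observed=True)[value]
    out = grouped.agg(mean="mean",
                      sem=lambda x: (x.std(ddof=1) / np.sqrt(len(x))
                                     if len(x) > 1 else np.nan),
                      n="count").reset_index()
    if len(out) < expected:
        warnings.warn("some factor cells have no observations and are "
                      "omitted", RuntimeWarning)
    return out


def two_group_t(group1: np.ndarray, group2: np.ndarray,
                welch: bool = False) -> TTestResult:
    """Two-sided Student's t test on two samples of per-animal rates.

    Pooled-variance (classical Student) by default, matching the assay's
    reporting; ``welch=True`` switches to the unequal-variance form.
    Raises on zero pooled variance (p would be undefined).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need n >= 2")
    if not welch and x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, df=len(x) + len(y) - 2, p=1.0)
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else len(x) + len(y) - 2
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def two_group_t_from_summary(mean1: float, sem1: float, n1: int,
                             mean2: float, sem2: float, n2: int,
                             welch: bool = False) -> TTestResult:
    """Student's t test from per-group summary statistics (mean, SEM, n).

    Exactly equal to :func:`two_group_t` applied to any raw samples with
    these summaries.  Accepts the mean ± SEM (n) values the assay's
    tables print.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    sd1 = sem1 * np.sqrt(n1)
    sd2 = sem2 * np.sqrt(n2)
    if welch:
        se2 = sd1 ** 2 / n1 + sd2 ** 2 / n2
        if se2 == 0:
            raise ValueError("zero variance in both groups")
        t = (mean1 - mean2) / np.sqrt(se2)
        df = se2 ** 2 / ((sd1 ** 2 / n1) ** 2 / (n1 - 1)
                         + (sd2 ** 2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
        if sp2 == 0:
            if mean1 == mean2:
                return TTestResult(t=0.0, df=n1 + n2 - 2, p=1.0)
            raise ValueError("zero pooled variance with unequal means")
        t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def minute_groups(table: pd.DataFrame, factor: str, levels: tuple[str, str],
                  minute: int = 5, value: str = "turns_per_min",
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Extract two groups' per-animal rates for a minute from a long table."""
    sel = table[table["minute"] == minute]
    g1 = sel.loc[sel[factor] == levels[0], value].to_numpy(dtype=float)
    g2 = sel.loc[sel[factor] == levels[1], value].to_numpy(dtype=float)
    return g1, g2


def interaction_anova(table: pd.DataFrame,
                      factors: tuple[str, str] = ("genotype", "condition"),
                      minute: int = 5,
                      value: str = "turns_per_min") -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction, Type II SS.

    Requires a complete crossed design (every factor-level combination
    observed, each cell n ≥ 2; no imputation of missing cells).  Returns
    the ANOVA table with sums of squares, df, F and p for both main
    effects and the interaction — the interaction row is the statistic
    the assay's tables report.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sel = table[table["minute"] == minute].copy()
    if sel.empty:
        raise ValueError(f"minute {minute} not present in table")
    fa, fb = factors
    counts = sel.groupby([fa, fb], observed=True)[value].count()
    n_a = sel[fa].nunique()
    n_b = sel[fb].nunique()
    if len(counts) < n_a * n_b:
        raise ValueError("missing design cell(s): two-way ANOVA with "
                         "interaction needs every cell observed")
    if (counts < 2).any():
        raise ValueError("every design cell needs n >= 2")
    sel = sel.rename(columns={value: "_y", fa: "_fa", fb: "_fb"})
    model = smf.ols("_y ~ C(_fa) * C(_fb)", data=sel).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(index={"C(_fa)": fa, "C(_fb)": fb,
                            "C(_fa):C(_fb)": f"{fa}:{fb}"})
    return aov


def adjust_pvalues(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment across a screen of candidate tests.

    The assay's original screens report unadjusted interaction p values;
    this Benjamini–Hochberg (or any statsmodels ``multipletests`` method)
    wrapper supports reanalysis across many genotypes.
    """
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float),
                         method=method)[1]


def interaction_p(aov: pd.DataFrame) -> float:
    """Interaction p value from an :func:`interaction_anova` table."""
    inter = [ix for ix in aov.index if ":" in str(ix)]
    if not inter:
        raise ValueError("no interaction row in ANOVA table")
    return float(aov.loc[inter[0], "PR(>F)"])
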