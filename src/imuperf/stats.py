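"""Between-group statistical battery for cohort feature tables.

The comparison protocol: each variable is tested for normality per group
(Shapiro-Wilk, alpha 0.05); normally distributed variables go to a one-way
ANOVA with partial eta squared and a Tukey-Kramer post hoc (valid for unequal
group sizes), non-normal ones to a Mann-Whitney U test (two groups) or
Kruskal-Wallis test (three or more).  Categorical proportions across k groups
are compared with a Pearson chi-square test of homogeneity on the 2 x k
table, without continuity correction.  All tests are two-sided at alpha 0.05.

Standard distributions and test statistics come from scipy.stats; this module
adds the dispatch logic, effect sizes, and the printed-percentage -> integer
count reconstruction used when re-analysing published contingency tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "ContingencyTable",
    "shapiro_wilk",
    "one_way_anova",
    "tukey_hsd_unequal",
    "mann_whitney",
    "kruskal_wallis",
    "k_proportions_chi2",
    "reconstruct_counts",
    "compare_variable",
    "compare_many",
    "eta_squared_label",
]

ALPHA = 0.05

#: conventional partial-eta-squared effect-size thresholds
ETA2P_SMALL, ETA2P_MEDIUM, ETA2P_LARGE = 0.01, 0.06, 0.14


@dataclass(frozen=True)
class GroupComparison:
    """One variable compared across groups."""

    variable: str
    group_labels: tuple
    group_ns: tuple
    statistic_kind: str  # ANOVA_F | MWU_U | KW_H | CHI2
    statistic: float
    df: tuple
    p: float
    effect_eta2p: float | None = None
    posthoc: dict = field(default_factory=dict)
    group_means: tuple = ()
    group_sds: tuple = ()


@dataclass(frozen=True)
class ContingencyTable:
    """Per-group success counts out of totals (a 2 x k homogeneity layout)."""

    group_labels: tuple
    successes: tuple
    totals: tuple

    def __post_init__(self):
        s = np.asarray(self.successes)
        t = np.asarray(self.totals)
        if s.shape != t.shape:
            raise ValueError("successes and totals must align")
        if np.any(t < 1):
            raise ValueError("every group must have total >= 1")
        if np.any((s < 0) | (s > t)):
            raise ValueError("successes must lie in [0, total] per group")


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk W and p.  Constant samples are reported as non-normal (p=0)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(x) == 0.0:
        return float("nan"), 0.0
    w, p = sps.shapiro(x)
    return float(w), float(p)


def one_way_anova(groups) -> tuple[float, int, int, float, float]:
    """One-way fixed-effects ANOVA: (F, df1, df2, p, partial eta squared).

    eta2p = SS_between / (SS_between + SS_within); with a single factor this
    coincides with eta squared.  Zero between- and within-group variation
    leaves F undefined (NaN).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 observations each")
    ns = np.array([g.size for g in gs])
    grand = np.concatenate(gs).mean()
    ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, gs)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df1 = len(gs) - 1
    df2 = int(ns.sum()) - len(gs)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return float("nan"), df1, df2, float("nan"), 0.0
        return float("inf"), df1, df2, 0.0, 1.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    eta2p = ss_between / (ss_between + ss_within)
    return float(f), df1, df2, p, float(eta2p)


def eta_squared_label(eta2p: float) -> str:
    """Conventional verbal label for a partial eta squared."""
    if eta2p >= ETA2P_LARGE:
        return "large"
    if eta2p >= ETA2P_MEDIUM:
        return "medium"
    if eta2p >= ETA2P_SMALL:
        return "small"
    return "negligible"


def tukey_hsd_unequal(groups, labels=None) -> dict:
    """Tukey-Kramer studentized-range p-values for every group pair.

    Valid for unequal sample sizes (harmonic-mean form of the HSD).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("post hoc needs >= 2 groups with >= 2 observations each")
    if labels is None:
        labels = list(range(len(gs)))
    res = sps.tukey_hsd(*gs)
    out = {}
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            out[(labels[i], labels[j])] = float(res.pvalue[i, j])
    return out


def mann_whitney(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U (exact for small tie-free samples, else
    normal approximation with tie correction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; (H, df, p) with df = k - 1.

    All-identical observations give H = 0 by convention.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups")
    df = len(gs) - 1
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0.0:
        return 0.0, df, 1.0
    h, p = sps.kruskal(*gs)
    return float(h), df, float(p)


def k_proportions_chi2(
    table: ContingencyTable, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square of homogeneity on the 2 x k table; (chi2, df, p).

    No continuity correction by default.  A table where one margin is empty
    (all successes or all failures) has no variation to test; it returns
    chi2 = 0 with p = 1.
    """
    s = np.asarray(table.successes, dtype=float)
    t = np.asarray(table.totals, dtype=float)
    df = s.size - 1
    if s.sum() == 0.0 or (t - s).sum() == 0.0:
        return 0.0, df, 1.0
    obs = np.vstack([s, t - s])
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=correction)
    return float(chi2), int(dof), float(p)


def reconstruct_counts(percentages, totals, tol_pct: float = 0.05) -> np.ndarray:
    """Integer per-group counts from printed percentages and group sizes.

    Each count is ``round(pct / 100 * n)`` (half away from zero).  Groups
    whose rounded count re-prints more than ``tol_pct`` percentage points away
    from the stated percentage are flagged with a warning — a sign the printed
    numbers are mutually inconsistent.
    """
    pct = np.asarray(percentages, dtype=float)
    n = np.asarray(totals, dtype=float)
    if np.any((pct < 0) | (pct > 100)):
        raise ValueError("percentages must lie in [0, 100]")
    counts = np.floor(pct / 100.0 * n + 0.5).astype(int)
    back = counts / n * 100.0
    for i, (b, p) in enumerate(zip(back, pct)):
        if abs(b - p) > tol_pct:
            warnings.warn(
                f"group {i}: reconstructed count {counts[i]}/{int(n[i])} prints as "
                f"{b:.2f}%, stated {p:.2f}%"
            )
    return counts


def compare_variable(
    cohort: pd.DataFrame,
    variable: str,
    grouping: str,
    alpha: float = ALPHA,
    posthoc: bool = True,
) -> GroupComparison:
    """Normality-gated between-group comparison of one numeric variable.

    Shapiro-Wilk per group at ``alpha``; all groups normal -> one-way ANOVA
    (plus Tukey-Kramer post hoc), otherwise Mann-Whitney U for two groups or
    Kruskal-Wallis for three or more.
    """
    sub = cohort[[variable, grouping]].dropna()
    labels = sorted(sub[grouping].unique())
    gs = [sub.loc[sub[grouping] == lab, variable].to_numpy(float) for lab in labels]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("grouping must have >= 2 nonempty levels")
    normal = all(shapiro_wilk(g)[1] >= alpha for g in gs)
    means = tuple(float(g.mean()) for g in gs)
    sds = tuple(float(g.std(ddof=1)) if g.size > 1 else 0.0 for g in gs)
    ns = tuple(int(g.size) for g in gs)

    if normal:
        f, df1, df2, p, eta2p = one_way_anova(gs)
        ph = tukey_hsd_unequal(gs, labels) if posthoc and len(gs) > 2 else {}
        return GroupComparison(
            variable=variable, group_labels=tuple(labels), group_ns=ns,
            statistic_kind="ANOVA_F", statistic=f, df=(df1, df2), p=p,
            effect_eta2p=eta2p, posthoc=ph, group_means=means, group_sds=sds,
        )
    if len(gs) == 2:
        u, p = mann_whitney(gs[0], gs[1])
        return GroupComparison(
            variable=variable, group_labels=tuple(labels), group_ns=ns,
            statistic_kind="MWU_U", statistic=u, df=(), p=p,
            group_means=means, group_sds=sds,
        )
    h, df, p = kruskal_wallis(gs)
    return GroupComparison(
        variable=variable, group_labels=tuple(labels), group_ns=ns,
        statistic_kind="KW_H", statistic=h, df=(df,), p=p,
        group_means=means, group_sds=sds,
    )


def compare_many(
    cohort: pd.DataFrame, variables, grouping: str, alpha: float = ALPHA
) -> pd.DataFrame:
    """Run :func:`compare_variable` over several variables; tidy results table."""
    rows = []
    for v in variables:
        c = compare_variable(cohort, v, grouping, alpha=alpha)
        row = {
            "variable": v,
            "test": c.statistic_kind,
            "statistic": c.statistic,
            "df": "/".join(str(d) for d in c.df),
            "p": c.p,
            "eta2p": c.effect_eta2p if c.effect_eta2p is not None else np.nan,
        }
        for lab, n, m, s in zip(c.group_labels, c.group_ns, c.group_means, c.group_sds):
            row[f"{lab} (n={n})"] = f"{m:.2f} ± {s:.2f}"
        rows.append(row)
    return pd.DataFrame(rows)
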