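"""Group statistics and prevalence summaries for organoid measurements.

One-way ANOVA is implemented directly from the between/within sums-of-squares
decomposition (the F distribution itself comes from scipy), followed by
Bonferroni-adjusted pairwise t tests using the pooled within-group variance —
the classical post-hoc reading of "ANOVA with Bonferroni's comparisons".
Prevalence computes a binomial proportion with an exact Clopper-Pearson 95%
interval, suited to small case counts such as birth-surveillance NTD rates.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ANOVAResult",
    "PairwiseResult",
    "PrevalenceResult",
    "one_way_anova",
    "bonferroni_pairwise",
    "prevalence",
    "significance_stars",
]


@dataclass(frozen=True)
class ANOVAResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    ms_within: float
    degenerate: bool = False  # zero within-group variance with equal means


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    t_statistic: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int
    stars: str


@dataclass(frozen=True)
class PrevalenceResult:
    cases: int
    denominator: int
    percent: float  # 100*k/n rounded to 2 decimal places
    ci_low: float  # proportions, exact binomial 95% CI
    ci_high: float

    @property
    def proportion(self) -> float:
        return self.cases / self.denominator


def significance_stars(p: float) -> str:
    """Figure-caption star notation at the 0.05 / 0.001 / 0.0001 levels."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.05:
        return "*"
    return "ns"


def _groups_from_table(
    table: pd.DataFrame, value_col: str, group_col: str
) -> dict[str, np.ndarray]:
    groups = {
        str(g): sub[value_col].to_numpy(dtype=float)
        for g, sub in table.groupby(group_col, sort=False)
    }
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {g!r} contains non-finite values")
    return groups


def one_way_anova(
    table: pd.DataFrame, value_col: str = "value", group_col: str = "arm"
) -> ANOVAResult:
    """Classical one-way ANOVA from the sums-of-squares decomposition.

    SS_between = Σ n_i (ȳ_i − ȳ)², SS_within = Σ_i Σ_j (y_ij − ȳ_i)²,
    F = MS_between / MS_within with df (k−1, N−k).  A table with zero
    within-group variance and equal group means has an undefined F and is
    flagged as degenerate rather than returning a number.
    """
    groups = _groups_from_table(table, value_col, group_col)
    k = len(groups)
    all_vals = np.concatenate(list(groups.values()))
    N = all_vals.size
    grand = all_vals.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values())
    df_b, df_w = k - 1, N - k
    ms_w = ss_within / df_w
    means = {g: float(v.mean()) for g, v in groups.items()}
    sds = {g: float(v.std(ddof=1)) for g, v in groups.items()}
    ns = {g: int(v.size) for g, v in groups.items()}
    if ms_w == 0.0:
        if ss_between == 0.0:
            return ANOVAResult(
                float("nan"), df_b, df_w, float("nan"),
                means, sds, ns, 0.0, degenerate=True,
            )
        return ANOVAResult(float("inf"), df_b, df_w, 0.0, means, sds, ns, 0.0)
    f = (ss_between / df_b) / ms_w
    p = float(sps.f.sf(f, df_b, df_w))
    return ANOVAResult(float(f), df_b, df_w, p, means, sds, ns, ms_w)


def bonferroni_pairwise(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "arm",
    welch: bool = False,
    versus_control: str | None = None,
) -> list[PairwiseResult]:
    """All-pairs (or versus-control) t tests with Bonferroni adjustment.

    By default each pair is tested with the pooled within-group variance
    from the full ANOVA (df = N − k), the classical Bonferroni post-hoc;
    ``welch=True`` switches to per-pair Welch tests.  Adjusted p-values are
    min(1, m * p_raw) with m the number of comparisons performed.
    """
    groups = _groups_from_table(table, value_col, group_col)
    names = list(groups)
    if versus_control is not None:
        if versus_control not in groups:
            raise ValueError(f"control group {versus_control!r} not in table")
        pairs = [(versus_control, g) for g in names if g != versus_control]
    else:
        pairs = list(combinations(names, 2))
    m = len(pairs)
    anova = one_way_anova(table, value_col, group_col)
    results = []
    for a, b in pairs:
        va, vb = groups[a], groups[b]
        if welch:
            t, p = sps.ttest_ind(va, vb, equal_var=False)
        else:
            if anova.ms_within == 0.0:
                raise ValueError("zero pooled within-group variance; use welch=True")
            se = np.sqrt(anova.ms_within * (1.0 / va.size + 1.0 / vb.size))
            t = (va.mean() - vb.mean()) / se
            p = 2.0 * float(sps.t.sf(abs(t), anova.df_within))
        p_adj = min(1.0, m * float(p))
        results.append(
            PairwiseResult(
                group_a=a, group_b=b, t_statistic=float(t),
                p_raw=float(p), p_adjusted=p_adj, n_comparisons=m,
                stars=significance_stars(p_adj),
            )
        )
    return results


def prevalence(k: int, n: int, alpha: float = 0.05) -> PrevalenceResult:
    """Case prevalence with an exact (Clopper-Pearson) binomial CI.

    ``percent`` is 100*k/n rounded to two decimal places — the convention of
    surveillance reports (e.g. 4 NTD cases among 426 exposures -> 0.94%).
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("cases must satisfy 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    return PrevalenceResult(
        cases=k,
        denominator=n,
        percent=round(100.0 * k / n, 2),
        ci_low=float(lo),
        ci_high=float(hi),
    )
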