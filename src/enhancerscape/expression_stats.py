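"""Expression specificity and enrichment statistics.

The Normalized Difference ND(x) = (max(g_x) - min(g_x)) / mean(g_x) over
the three cell populations (ESC, Eo-, Eo+) measures how population-
specific a gene is; for k nonnegative values it is bounded by [0, k]
(mean >= max/k), so 0..3 here. Distributions of ND between gene classes
are compared with one-tailed Wilcoxon rank-sum tests and summarized by
Gaussian kernel densities. Fold-change enriched sets, DESeq-style
median-of-ratios size factors, and a Welch-t differential test round out
the plumbing for synthetic end-to-end runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("ESC", "Eo-", "Eo+")
DEFAULT_PSEUDOCOUNT = 0.01


def collapse_replicates(
    matrix: pd.DataFrame, condition_of: Mapping[str, str]
) -> pd.DataFrame:
    """Mean expression per condition from a gene x sample matrix."""
    groups: dict[str, list[str]] = {}
    for sample, cond in condition_of.items():
        groups.setdefault(cond, []).append(sample)
    return pd.DataFrame(
        {cond: matrix[cols].mean(axis=1) for cond, cols in groups.items()}
    )


def normalized_difference(values: Sequence[float]) -> float:
    """ND = (max - min) / mean over condition means; NaN if all zero.

    Scale-invariant, 0 iff constant, and bounded by the number of
    conditions for nonnegative input.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("expression must be nonnegative")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float((v.max() - v.min()) / m)


def nd_table(condition_means: pd.DataFrame) -> pd.Series:
    """ND per gene over a gene x condition-mean table."""
    v = condition_means.to_numpy(dtype=float)
    m = v.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nd = (v.max(axis=1) - v.min(axis=1)) / m
    nd[m == 0] = np.nan
    return pd.Series(nd, index=condition_means.index, name="ND")


@dataclass
class RankSumResult:
    p_value: float
    statistic: float  # Mann-Whitney U of group A
    method: str  # "exact" or "asymptotic"
    density_a: tuple[np.ndarray, np.ndarray]  # (grid, density)
    density_b: tuple[np.ndarray, np.ndarray]


def _gaussian_kde(values: np.ndarray, n_grid: int = 256):
    """Silverman-bandwidth Gaussian KDE evaluated on a padded grid."""
    if len(values) < 2 or np.ptp(values) == 0:
        g = np.linspace(values.min() - 1, values.max() + 1, n_grid)
        d = np.zeros(n_grid)
        d[np.argmin(np.abs(g - values.mean()))] = 1.0
        return g, d
    kde = stats.gaussian_kde(values, bw_method="silverman")
    pad = 3 * values.std(ddof=1)
    g = np.linspace(values.min() - pad, values.max() + pad, n_grid)
    return g, kde(g)


def compare_nd_distributions(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "greater",
    exact_max_n: int = 20,
) -> RankSumResult:
    """One-tailed Wilcoxon rank-sum test of A vs B, plus KDE summaries.

    ``alternative='greater'`` tests whether A is stochastically greater.
    The exact null distribution is used when the smaller group has at
    most ``exact_max_n`` observations and the pooled data is tie-free;
    otherwise the tie-corrected normal approximation (with continuity
    correction) applies.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = (min(a.size, b.size) <= exact_max_n) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    ga, da = _gaussian_kde(a)
    gb, db = _gaussian_kde(b)
    return RankSumResult(
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        method=method,
        density_a=(ga, da),
        density_b=(gb, db),
    )


def rank_sum_enumeration_oracle(
    group_a: Sequence[float], group_b: Sequence[float], alternative: str = "greater"
) -> float:
    """Brute-force exact rank-sum p by enumerating all C(n, nA) splits.

    Independent oracle for small groups: p = fraction of reassignments of
    the pooled values whose U statistic (ties counted half) is at least /
    at most as extreme as observed. Feasible only for tiny n.
    """
    from itertools import combinations

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    def u_stat(x, y):
        x = x[:, None]
        return float(np.sum(x > y) + 0.5 * np.sum(x == y))

    observed = u_stat(a, b)
    count = 0
    total = 0
    idx = np.arange(n)
    for comb in combinations(idx, na):
        sel = np.zeros(n, dtype=bool)
        sel[list(comb)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        if alternative == "greater":
            count += u >= observed - 1e-12
        else:
            count += u <= observed + 1e-12
        total += 1
    return count / total


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enriched_set(
    condition_means: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    min_fold: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    p_values: pd.Series | None = None,
    p_adjusted: bool = False,
    alpha: float = 0.05,
) -> list[str]:
    """Genes enriched in ``cond_a`` over ``cond_b`` (> ``min_fold`` FC).

    A pseudocount is added to both means before the ratio. If p-values
    are supplied they are BH-adjusted (unless already adjusted) and genes
    must additionally reach adjusted p <= alpha.
    """
    for cond in (cond_a, cond_b):
        if cond not in condition_means.columns:
            raise KeyError(f"unknown condition {cond!r}")
    fold = (condition_means[cond_a] + pseudocount) / (
        condition_means[cond_b] + pseudocount
    )
    keep = fold > min_fold
    if p_values is not None:
        adj = p_values if p_adjusted else pd.Series(
            bh_adjust(p_values.to_numpy()), index=p_values.index
        )
        keep &= adj.reindex(condition_means.index) <= alpha
    return list(condition_means.index[keep.fillna(False)])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq median-of-ratios size factors (gene x sample count matrix).

    Reference = per-gene geometric mean across samples, over genes with
    all-positive counts; factor_s = median over genes of count/reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >=2 samples")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples")
    sub = counts.loc[positive].to_numpy(dtype=float)
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def welch_de(
    matrix: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2(x + pseudocount), plus log2FC of means.

    Plumbing differential test so the synthetic pipeline runs end to end;
    not an empirical-Bayes model.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >=2 replicates per condition")
    la = np.log2(matrix[list(samples_a)].to_numpy(dtype=float) + pseudocount)
    lb = np.log2(matrix[list(samples_b)].to_numpy(dtype=float) + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    # identical groups give 0/0 -> NaN; no evidence of change
    p = np.where(np.isnan(p), 1.0, p)
    mean_a = matrix[list(samples_a)].mean(axis=1)
    mean_b = matrix[list(samples_b)].mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pd.DataFrame(
        {"log2FC": log2fc, "t": t, "p": p, "adj_p": bh_adjust(p)},
        index=matrix.index,
    )
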