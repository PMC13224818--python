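"""Per-species family-size statistics: Kruskal–Wallis with the rank-based
epsilon-squared effect size, and pairwise Wilcoxon rank-sum tests with
Benjamini–Hochberg correction."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "epsilon_squared",
    "pairwise_wilcoxon_bh",
    "family_size_tests",
]


@dataclass
class TestResult:
    H: float
    df: int
    p: float
    epsilon2: float
    qmatrix: pd.DataFrame


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, int, float]:
    """Kruskal–Wallis H (chi-squared scale, mid-ranks with tie correction),
    degrees of freedom k-1, and the chi-squared p-value.

    With zero rank variance (all observations identical) H is 0 and p is 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
        arrays.append(vals)
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), df, float(p)


def epsilon_squared(H: float, n: int) -> float:
    """Rank-based epsilon-squared effect size for Kruskal–Wallis:
    eps^2 = H * (n + 1) / (n^2 - 1), with n the total observation count."""
    if n < 2:
        raise ValueError("need at least two observations")
    return H * (n + 1) / (n**2 - 1)


def _ranksum_p(a: np.ndarray, b: np.ndarray, exact_max: int = 50) -> float:
    """Two-sided Wilcoxon rank-sum p-value: exact enumeration when both
    groups are small and tie-free, otherwise the normal approximation with
    continuity and tie correction."""
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if not has_ties and max(len(a), len(b)) <= exact_max:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def pairwise_wilcoxon_bh(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Symmetric species x species matrix of BH-adjusted q-values from
    two-sided rank-sum tests over every unordered pair (diagonal NaN)."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, vals in arrays.items():
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
    pairs = list(itertools.combinations(names, 2))
    pvals = [_ranksum_p(arrays[a], arrays[b]) for a, b in pairs]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    q = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), qv in zip(pairs, qvals):
        q.loc[a, b] = qv
        q.loc[b, a] = qv
    return q


def family_size_tests(
    counts: pd.DataFrame, cap: int | None = None
) -> TestResult:
    """Run the full battery on a superfamilies x species count table.

    Counts are used uncapped by default; pass ``cap`` to clip them first
    (capping is otherwise only applied for display).
    """
    if cap is not None:
        counts = counts.clip(upper=cap)
    groups = {sp: counts[sp].to_numpy(dtype=float) for sp in counts.columns}
    H, df, p = kruskal_wallis(groups)
    eps2 = epsilon_squared(H, sum(len(v) for v in groups.values()))
    q = pairwise_wilcoxon_bh(groups)
    return TestResult(H=H, df=df, p=p, epsilon2=eps2, qmatrix=q)
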