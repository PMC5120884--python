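"""The study's statistical comparisons.

Two-group metrics are compared with the two-sided Mann-Whitney U test and
multi-group metrics with Kruskal-Wallis followed by Dunn's pairwise post-hoc
comparisons; paired ON/OFF velocity differences use the Wilcoxon
matched-pairs signed-rank test.  Exact small-sample p-values are used where
the sample size permits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupComparison", "compare_groups", "dunn_posthoc", "paired_test"]

EXACT_MAX_N = 12


@dataclass
class GroupComparison:
    """Result of a two- or multi-group comparison on one metric."""

    metric: str
    groups: dict[str, np.ndarray]
    test: str
    statistic: float
    p: float
    posthoc: pd.DataFrame | None = None
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def compare_groups(
    groups: dict[str, np.ndarray],
    metric: str = "",
    alpha: float = 0.05,
    posthoc_adjust: str = "bonferroni",
) -> GroupComparison:
    """Mann-Whitney U for two groups, Kruskal-Wallis + Dunn's for more.

    Exact Mann-Whitney p-values are used for groups of up to 12 tie-free
    observations, the tie-corrected normal approximation otherwise.  Every
    group needs at least two observations.
    """
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in clean.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    vals = list(clean.values())
    if len(clean) == 2:
        x, y = vals
        pooled = np.concatenate(vals)
        method = (
            "exact"
            if max(len(x), len(y)) <= EXACT_MAX_N and not _has_ties(pooled)
            else "asymptotic"
        )
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return GroupComparison(
            metric, clean, "mann-whitney", float(res.statistic),
            float(res.pvalue), None, alpha,
        )
    res = sps.kruskal(*vals)
    posthoc = dunn_posthoc(clean, adjust=posthoc_adjust)
    return GroupComparison(
        metric, clean, "kruskal-wallis", float(res.statistic),
        float(res.pvalue), posthoc, alpha,
    )


def dunn_posthoc(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise rank-sum comparisons after Kruskal-Wallis.

    Pairwise z statistics use pooled mid-ranks with the tie correction
    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values are adjusted
    for multiplicity (``bonferroni`` by default, any statsmodels method
    name accepted).  Returns a symmetric p-value matrix.
    """
    names = list(groups)
    pooled = np.concatenate([groups[k] for k in names])
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank, sizes, start = {}, {}, 0
    for k in names:
        n = len(groups[k])
        mean_rank[k] = ranks[start : start + n].mean()
        sizes[k] = n
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    pairs, raw = [], []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_rank[a] - mean_rank[b]) / se
            pairs.append((a, b))
            raw.append(2.0 * sps.norm.sf(abs(z)))
    adj = multipletests(raw, method=adjust)[1]
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names,
                       columns=names)
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def paired_test(
    pre: np.ndarray, post: np.ndarray
) -> tuple[float, float, str | None]:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped first; if all differences are zero the
    result is (0, 1) flagged ``"degenerate"``.  Exact p-values are used for
    up to 12 tie-free nonzero differences.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) != len(post):
        raise ValueError("pre and post must have equal length")
    d = post - pre
    nz = d[d != 0]
    if len(nz) == 0:
        return 0.0, 1.0, "degenerate"
    if len(nz) < 2:
        return float(nz.sum() > 0), 1.0, "degenerate"
    if len(nz) <= EXACT_MAX_N:
        if _has_ties(np.abs(nz)):
            # exact with midranks: enumerate all sign assignments
            return _exact_signed_rank(nz)
        res = sps.wilcoxon(nz, alternative="two-sided", method="exact")
    else:
        res = sps.wilcoxon(nz, alternative="two-sided", method="approx")
    return float(res.statistic), float(res.pvalue), None


def _exact_signed_rank(d: np.ndarray) -> tuple[float, float, None]:
    """Exact two-sided signed-rank p over all 2^n sign assignments (midranks)."""
    ranks = sps.rankdata(np.abs(d))
    n = len(d)
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    dev = abs(w_obs - mu)
    count = 0
    for mask in range(2**n):
        w = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return float(min(w_obs, ranks.sum() - w_obs)), count / 2**n, None
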