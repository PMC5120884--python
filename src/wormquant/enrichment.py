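"""Subtractive sorted-cell transcriptome enrichment.

Within each genotype, sorted GFP+ cells are tested against the matched
AllCells reference: counts are normalised with median-of-ratios size
factors, each gene gets a negative-binomial Wald p-value for the GFP+ vs
AllCells difference, p-values are Benjamini-Hochberg adjusted, and a gene
is *enriched* when q < 0.05 and mean GFP+ counts / mean AllCells counts
exceed 1.  Because the mutant lacks the target cell, subtracting the mutant
enriched set from the wild-type one nominates that cell's transcripts:
``shared`` = intersection, ``wt_only`` / ``mut_only`` = set differences,
``preferential`` = symmetric difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .simulate import CountMatrix

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "size_factors",
    "nb_test",
    "permutation_test",
    "bh_fdr",
    "fold_change",
    "call_enrichment",
    "subtract_sets",
    "validate_markers",
    "run_enrichment_pipeline",
]


@dataclass
class EnrichmentConfig:
    """Filter thresholds and modes of the enrichment call.

    ``ratio_mode`` selects the enrichment ratio filter: ``"plain"`` requires
    mean GFP+ / mean AllCells > ``ratio_threshold`` (the reading consistent
    with the printed fold changes); ``"log2_quotient"`` requires
    log2(mean GFP+) / log2(mean AllCells) > threshold instead.
    """

    fdr_threshold: float = 0.05
    ratio_threshold: float = 1.0
    ratio_mode: str = "plain"
    use_normalized_means: bool = True

    def __post_init__(self) -> None:
        if self.ratio_mode not in ("plain", "log2_quotient"):
            raise ValueError(f"unknown ratio_mode {self.ratio_mode!r}")


@dataclass
class EnrichmentResult:
    """Per-genotype gene tables, enriched sets and subtractive categories."""

    tables: dict[str, pd.DataFrame]
    enriched: dict[str, set[str]]
    categories: pd.Series
    venn: dict[str, int]
    config: EnrichmentConfig = field(default_factory=EnrichmentConfig)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scaling factors.

    factor_j = median over genes of count_gj / geometric-mean_g, computed
    over genes whose geometric mean is positive (i.e. nonzero in every
    sample).  Raises for an all-zero sample.
    """
    mat = counts.to_numpy(dtype=float)
    zero_samples = counts.columns[(mat <= 0).all(axis=0)]
    if len(zero_samples):
        raise ValueError(
            f"sample(s) with all-zero counts: {', '.join(map(str, zero_samples))}"
        )
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    ref_ok = np.isfinite(logs).all(axis=1)
    if not ref_ok.any():
        raise ValueError("no gene is nonzero in every sample")
    log_gm = logs[ref_ok].mean(axis=1)
    ratios = logs[ref_ok] - log_gm[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)


def _mom_dispersion(y: np.ndarray, groups: list[np.ndarray],
                    inv_sf: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion pooled across groups.

    For normalised counts y = c/s with true group mean q:
    Var(y_j) = q / s_j + disp * q^2, so within each group
    disp ~ (sample var - mean * mean(1/s)) / mean^2; estimates are pooled
    with df weights and floored at zero.
    """
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for idx in groups:
        n = len(idx)
        if n < 2:
            continue
        yg = y[:, idx]
        m = yg.mean(axis=1)
        v = yg.var(axis=1, ddof=1)
        h = inv_sf[idx].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(m > 0, (v - m * h) / np.square(m), 0.0)
        num += (n - 1) * d
        den += n - 1
    disp = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    disp = np.clip(disp, 0.0, None)
    # share information across genes: with 3-4 replicates the per-gene
    # moment estimate is very noisy (and often truncates to zero), so each
    # gene's dispersion is floored by the experiment-wide median of the
    # positive estimates, a conservative moderation in the spirit of the
    # classic count-based DE tools
    positive = disp[disp > 0]
    if positive.size:
        disp = np.maximum(disp, float(np.median(positive)))
    return disp


def _wald_z(
    y: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, inv_sf: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Wald z on the log difference of NB group means of normalised counts."""
    disp = _mom_dispersion(y, [idx_a, idx_b], inv_sf)
    means, ses = [], []
    for idx in (idx_a, idx_b):
        n = len(idx)
        m = y[:, idx].mean(axis=1)
        # half a normalised count keeps the log finite for empty groups
        eps = 0.5 * inv_sf[idx].mean() / n
        m_adj = np.maximum(m, eps)
        var_mean = (
            m_adj * inv_sf[idx].sum() + n * disp * np.square(m_adj)
        ) / n**2
        ses.append(np.sqrt(var_mean) / m_adj)
        means.append((m, m_adj))
    (ma, ma_adj), (mb, mb_adj) = means
    log_ratio = np.log(ma_adj) - np.log(mb_adj)
    se = np.sqrt(ses[0] ** 2 + ses[1] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log_ratio / se
    return z, ma, mb, log_ratio, disp


def nb_test(
    counts: pd.DataFrame,
    group_labels: pd.Series | np.ndarray,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene two-sided NB Wald test between two sample groups.

    Counts are normalised by median-of-ratios size factors (computed here
    unless supplied); normalised counts are modelled as negative binomial
    with a per-gene method-of-moments dispersion pooled across the two
    groups, and the Wald statistic tests the log difference of group means.
    Genes with all-zero counts get p = 1 and ``all_zero`` flagged.

    Returns a DataFrame indexed by gene with columns ``mean_a``, ``mean_b``
    (normalised group means), ``log_ratio``, ``stat``, ``p``, ``all_zero``.
    """
    labels = np.asarray(group_labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    idx_a = np.flatnonzero(labels == levels[0])
    idx_b = np.flatnonzero(labels == levels[1])
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("need at least 2 samples per group")

    if factors is None:
        factors = size_factors(counts)
    sf = factors.to_numpy(dtype=float)
    inv_sf = 1.0 / sf
    y = counts.to_numpy(dtype=float) * inv_sf[None, :]

    z, ma, mb, log_ratio, disp = _wald_z(y, idx_a, idx_b, inv_sf)
    from scipy import stats as sps

    p = 2.0 * sps.norm.sf(np.abs(z))
    all_zero = (counts.to_numpy() == 0).all(axis=1)
    p = np.where(all_zero, 1.0, np.clip(p, np.nextafter(0, 1), 1.0))

    out = pd.DataFrame(
        {
            "mean_a": ma,
            "mean_b": mb,
            "log_ratio": log_ratio,
            "dispersion": disp,
            "stat": z,
            "p": p,
            "all_zero": all_zero,
        },
        index=counts.index,
    )
    out.attrs["group_a"] = levels[0]
    out.attrs["group_b"] = levels[1]
    return out


def permutation_test(
    counts: pd.DataFrame,
    group_labels: pd.Series | np.ndarray,
    n_perm: int = 2000,
    seed: int = 0,
    factors: pd.Series | None = None,
) -> np.ndarray:
    """Label-permutation reference for the NB Wald statistic.

    The observed |z| of :func:`nb_test` is compared with its distribution
    under random relabelling of the samples, replacing the normal reference
    with an empirical one.  Returns one p-value per gene (add-one
    estimator).
    """
    labels = np.asarray(group_labels)
    levels = pd.unique(labels)
    if factors is None:
        factors = size_factors(counts)
    inv_sf = 1.0 / factors.to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float) * inv_sf[None, :]
    idx_a = np.flatnonzero(labels == levels[0])
    idx_b = np.flatnonzero(labels != levels[0])
    obs = np.abs(_wald_z(y, idx_a, idx_b, inv_sf)[0])
    rng = np.random.default_rng(seed)
    n_samples = y.shape[1]
    n_a = len(idx_a)
    hits = np.zeros(y.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        stat = np.abs(_wald_z(y, perm[:n_a], perm[n_a:], inv_sf)[0])
        hits += stat >= obs - 1e-12
    return (hits + 1.0) / (n_perm + 1.0)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean_gfp: float, mean_all: float) -> float:
    """Enrichment fold change: mean GFP+ counts / mean AllCells counts.

    Printed to one decimal in tables.  A non-positive AllCells mean makes
    the ratio undefined (inf for positive GFP+, NaN otherwise).
    """
    if mean_all > 0:
        return mean_gfp / mean_all
    return float("inf") if mean_gfp > 0 else float("nan")


def call_enrichment(
    mean_gfp: np.ndarray,
    mean_all: np.ndarray,
    q: np.ndarray,
    cfg: EnrichmentConfig | None = None,
) -> np.ndarray:
    """Enriched flag: q < threshold AND ratio filter passed (strict).

    With a zero AllCells mean the ratio is treated as infinite, so the call
    reduces to the FDR criterion.
    """
    cfg = cfg or EnrichmentConfig()
    mean_gfp = np.asarray(mean_gfp, dtype=float)
    mean_all = np.asarray(mean_all, dtype=float)
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if cfg.ratio_mode == "plain":
            ratio = np.where(
                mean_all > 0,
                mean_gfp / np.where(mean_all > 0, mean_all, 1.0),
                np.where(mean_gfp > 0, np.inf, np.nan),
            )
        else:
            ratio = np.log2(np.maximum(mean_gfp, 1e-300)) / np.log2(
                np.maximum(mean_all, 1e-300)
            )
    ratio_ok = np.nan_to_num(ratio, nan=0.0) > cfg.ratio_threshold
    return (q < cfg.fdr_threshold) & ratio_ok


def subtract_sets(
    enriched_wt: set[str], enriched_mut: set[str]
) -> dict:
    """Venn arithmetic over the two enriched sets.

    shared = intersection; wt_only / mut_only = set differences;
    preferential = symmetric difference.  Counts are reported alongside the
    sets.
    """
    wt = set(enriched_wt)
    mut = set(enriched_mut)
    shared = wt & mut
    wt_only = wt - mut
    mut_only = mut - wt
    preferential = wt_only | mut_only
    return {
        "shared": shared,
        "wt_only": wt_only,
        "mut_only": mut_only,
        "preferential": preferential,
        "counts": {
            "wt": len(wt),
            "mut": len(mut),
            "shared": len(shared),
            "wt_only": len(wt_only),
            "mut_only": len(mut_only),
            "preferential": len(preferential),
        },
    }


def validate_markers(
    table: pd.DataFrame,
    positive_markers: list[str],
    negative_markers: list[str],
) -> dict:
    """Check expected-enriched and expected-absent marker genes.

    ``table`` must carry a boolean ``enriched`` column indexed by gene.
    Unknown marker ids are listed as unresolved, not fatal.  The report
    passes when every resolvable positive is enriched and no resolvable
    negative is.
    """
    status: dict[str, bool] = {}
    unresolved: list[str] = []
    for g in list(positive_markers) + list(negative_markers):
        if g in table.index:
            status[g] = bool(table.loc[g, "enriched"])
        else:
            unresolved.append(g)
    pos_ok = [g for g in positive_markers if status.get(g) is True]
    pos_fail = [g for g in positive_markers if status.get(g) is False]
    neg_ok = [g for g in negative_markers if status.get(g) is False]
    neg_fail = [g for g in negative_markers if status.get(g) is True]
    return {
        "status": status,
        "unresolved": unresolved,
        "positives_pass": len(pos_ok),
        "positives_fail": len(pos_fail),
        "negatives_pass": len(neg_ok),
        "negatives_fail": len(neg_fail),
        "passed": not pos_fail and not neg_fail,
    }


def run_enrichment_pipeline(
    cm: CountMatrix, cfg: EnrichmentConfig | None = None
) -> EnrichmentResult:
    """GFP+ vs AllCells enrichment per genotype, then set subtraction.

    For each genotype the GFP+ samples are tested against the matched
    AllCells samples (size factors computed within the genotype design);
    genes passing the FDR and ratio filters form that genotype's enriched
    set, and the subtractive categories (shared / wt_only / mut_only / none)
    are assigned per gene.
    """
    cfg = cfg or EnrichmentConfig()
    tables: dict[str, pd.DataFrame] = {}
    enriched: dict[str, set[str]] = {}
    for genotype in ("wt", "mut"):
        keep = cm.meta["genotype"] == genotype
        samples = cm.meta.index[keep]
        if not len(samples):
            continue
        counts = cm.counts.loc[:, samples]
        labels = cm.meta.loc[samples, "fraction"].to_numpy()
        factors = size_factors(counts)
        res = nb_test(counts, labels, factors=factors)
        if res.attrs["group_a"] != "GFP+":
            res[["mean_a", "mean_b"]] = res[["mean_b", "mean_a"]].to_numpy()
            res["log_ratio"] = -res["log_ratio"]
            res["stat"] = -res["stat"]
        res = res.rename(columns={"mean_a": "mean_gfp", "mean_b": "mean_all"})
        # raw (unnormalised) means, the form printed in result tables
        gfp_cols = samples[labels == "GFP+"]
        all_cols = samples[labels != "GFP+"]
        res["raw_mean_gfp"] = cm.counts.loc[:, gfp_cols].mean(axis=1)
        res["raw_mean_all"] = cm.counts.loc[:, all_cols].mean(axis=1)
        res["q"] = bh_fdr(res["p"].to_numpy())
        m_gfp = (
            res["mean_gfp"] if cfg.use_normalized_means else res["raw_mean_gfp"]
        ).to_numpy()
        m_all = (
            res["mean_all"] if cfg.use_normalized_means else res["raw_mean_all"]
        ).to_numpy()
        res["fold_change"] = [
            fold_change(a, b) for a, b in zip(m_gfp, m_all)
        ]
        res["enriched"] = call_enrichment(m_gfp, m_all, res["q"].to_numpy(), cfg)
        tables[genotype] = res
        enriched[genotype] = set(res.index[res["enriched"]])

    venn = subtract_sets(enriched.get("wt", set()), enriched.get("mut", set()))
    cat = pd.Series("none", index=cm.counts.index, name="category")
    cat[list(venn["shared"])] = "shared"
    cat[list(venn["wt_only"])] = "wt_only"
    cat[list(venn["mut_only"])] = "mut_only"
    return EnrichmentResult(
        tables=tables,
        enriched=enriched,
        categories=cat,
        venn=venn["counts"],
        config=cfg,
    )
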