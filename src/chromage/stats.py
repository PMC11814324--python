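"""Normalization and statistics for region x sample count matrices.

The normalization is the median-of-ratios method: each sample's size
factor is the median, over reference regions, of its counts divided by
the row-wise geometric mean. Differential enrichment is a
moment-based negative-binomial Wald test on normalized group means with
Benjamini-Hochberg correction; the field's working convention of calling a
region differential at adjusted p < 0.1 is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CountMatrix

LN2 = np.log(2.0)


def size_factors_median_of_ratios(counts: CountMatrix) -> pd.Series:
    """Per-sample size factors by the median-of-ratios method.

    The reference for region g is the geometric mean of its counts over
    samples; regions with a zero in any sample are excluded from the
    reference set. The factor for sample s is the median over reference
    regions of count_gs / reference_g.
    """
    x = counts.data.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no region has strictly positive counts in every sample; "
            "median-of-ratios needs at least one all-positive row "
            "(consider a pseudo-reference on filtered regions)"
        )
    ref = np.exp(np.log(x[all_positive]).mean(axis=1))
    ratios = x[all_positive] / ref[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalize_counts(counts: CountMatrix, size_factors: pd.Series) -> CountMatrix:
    """Divide each sample column by its size factor; result flagged normalized."""
    missing = [s for s in counts.sample_ids if s not in size_factors.index]
    if missing:
        raise ValueError(f"missing size factor for sample(s): {missing}")
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    norm = counts.data.astype(float) / size_factors[counts.sample_ids].to_numpy()[None, :]
    return CountMatrix(norm, mark=counts.mark, normalized=True)


@dataclass
class ZScoreMatrix:
    """Per-region z-scores with the row means/SDs used to compute them."""

    data: pd.DataFrame
    mark: str
    row_means: pd.Series
    row_sds: pd.Series


def gene_zscores(norm: CountMatrix, sample_subset: Sequence[str] | None = None) -> ZScoreMatrix:
    """Row-wise z-scores over the chosen samples (population SD).

    Rows with zero SD (constant signal) are set to all zeros so that
    constant genes stay neutral downstream.
    """
    samples = list(sample_subset) if sample_subset is not None else counts_samples(norm)
    if len(samples) < 2:
        raise ValueError("z-scores need at least 2 samples")
    x = norm.data[samples].to_numpy(dtype=float)
    means = x.mean(axis=1)
    sds = x.std(axis=1)  # population SD
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - means[:, None]) / sds[:, None]
    z[sds == 0, :] = 0.0
    df = pd.DataFrame(z, index=norm.data.index, columns=samples)
    idx = norm.data.index
    return ZScoreMatrix(df, norm.mark, pd.Series(means, index=idx), pd.Series(sds, index=idx))


def counts_samples(counts: CountMatrix) -> list[str]:
    return counts.sample_ids


def estimate_dispersion_mom(
    counts: CountMatrix,
    size_factors: pd.Series,
    groups: Mapping[str, Sequence[str]],
    alpha_min: float = 1e-8,
    shrink_weight: float = 0.3,
) -> pd.Series:
    """Per-region NB dispersion by pooled method of moments.

    Within-group mean/variance of normalized counts give
    alpha_hat = max(alpha_min, (s^2 - mean) / mean^2), pooled over groups
    with >= 2 replicates, then shrunk toward the median:
    alpha' = (1 - w) * alpha_hat + w * median(alpha_hat).
    """
    usable = {g: list(s) for g, s in groups.items() if len(s) >= 2}
    if not usable:
        raise ValueError("dispersion estimation needs a group with >= 2 replicates")
    norm = normalize_counts(counts, size_factors) if not counts.normalized else counts
    n_regions = norm.data.shape[0]
    ss_resid = np.zeros(n_regions)
    dof = 0
    mean_accum = np.zeros(n_regions)
    n_total = 0
    for samples in usable.values():
        x = norm.data[samples].to_numpy(dtype=float)
        m = x.mean(axis=1)
        ss_resid += ((x - m[:, None]) ** 2).sum(axis=1)
        dof += x.shape[1] - 1
        mean_accum += m * len(samples)
        n_total += len(samples)
    s2 = ss_resid / dof
    mu = mean_accum / n_total
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_hat = (s2 - mu) / mu**2
    alpha_hat = np.where(np.isfinite(alpha_hat), alpha_hat, alpha_min)
    alpha_hat = np.maximum(alpha_min, alpha_hat)
    med = float(np.median(alpha_hat))
    alpha = (1.0 - shrink_weight) * alpha_hat + shrink_weight * med
    return pd.Series(alpha, index=norm.data.index, name="alpha")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted ascending, adj_(i) = min over j >= i of p_(j) * m / j, capped
    at 1, returned in the original order. Tied p-values share the
    adjusted value of their common rank position.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def nb_wald_differential(
    counts: CountMatrix,
    size_factors: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: pd.Series | float,
    padj_threshold: float = 0.1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Moment-based NB Wald test of group B vs group A per region.

    With group means mu_A, mu_B of normalized counts and pseudocount pc:
    LFC = log2((mu_B + pc) / (mu_A + pc)),
    SE = (1/ln 2) * sqrt(sum_g (1/n_g) * (1/(mu_g + pc) + alpha)),
    z = LFC/SE, two-sided normal p, BH-adjusted. Regions with adjusted
    p below the threshold are flagged up or down by the LFC sign.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    norm = counts if counts.normalized else normalize_counts(counts, size_factors)
    if np.isscalar(alpha):
        alpha_vec = np.full(norm.data.shape[0], float(alpha))
    else:
        if len(alpha) != norm.data.shape[0]:
            raise ValueError("alpha vector not aligned with regions")
        alpha_vec = np.asarray(alpha.reindex(norm.data.index), dtype=float)
        if np.isnan(alpha_vec).any():
            raise ValueError("alpha vector not aligned with regions")
    pc = pseudocount
    mu_a = norm.data[group_a].to_numpy(dtype=float).mean(axis=1)
    mu_b = norm.data[group_b].to_numpy(dtype=float).mean(axis=1)
    lfc = np.log2((mu_b + pc) / (mu_a + pc))
    var = (1.0 / len(group_a)) * (1.0 / (mu_a + pc) + alpha_vec) + (
        1.0 / len(group_b)
    ) * (1.0 / (mu_b + pc) + alpha_vec)
    se = np.sqrt(var) / LN2
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    padj = bh_adjust(p)
    status = np.where(
        padj < padj_threshold, np.where(lfc > 0, "up", "down"), "ns"
    )
    status = np.where((padj < padj_threshold) & (lfc == 0), "ns", status)
    return pd.DataFrame(
        {
            "base_mean": (mu_a + mu_b) / 2.0,
            "log2fc": lfc,
            "se": se,
            "wald_stat": z,
            "pvalue": p,
            "padj": padj,
            "status": status,
        },
        index=norm.data.index,
    )


@dataclass
class RankTestReport:
    """Result of a rank test, with post-hoc pairwise comparisons for k > 2."""

    test: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None = None


def rank_tests(
    values: Sequence[float],
    grouping: Sequence,
    test: Literal["mannwhitney_two_sided", "kruskal_wallis"] = "mannwhitney_two_sided",
    pairwise_correction: Literal["bonferroni"] = "bonferroni",
) -> RankTestReport:
    """Mann-Whitney U (two groups, two-sided) or Kruskal-Wallis (>= 2 groups).

    The MWU uses exact enumeration when both group sizes are <= 8 and there
    are no ties, otherwise the tie-corrected normal approximation. For
    Kruskal-Wallis, post-hoc pairwise MWU p-values are Bonferroni-scaled
    by the number of comparisons and capped at 1.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    labels = list(pd.unique(grouping))
    groups = [values[grouping == g] for g in labels]
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise ValueError("need >= 2 nonempty groups")

    def _mwu(a, b):
        ab = np.concatenate([a, b])
        no_ties = len(np.unique(ab)) == len(ab)
        method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)

    if test == "mannwhitney_two_sided":
        if len(groups) != 2:
            raise ValueError("Mann-Whitney requires exactly 2 groups")
        stat, p = _mwu(groups[0], groups[1])
        return RankTestReport(test, stat, p)
    if test == "kruskal_wallis":
        if np.ptp(np.concatenate(groups)) == 0:
            # all observations identical: H = 0 by definition, no separation
            return RankTestReport(test, 0.0, 1.0, _pairwise_all_one(labels))
        stat, p = sps.kruskal(*groups)
        n_comp = len(labels) * (len(labels) - 1) // 2
        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                _, pij = _mwu(groups[i], groups[j])
                rows.append((labels[i], labels[j], min(1.0, pij * n_comp)))
        pw = pd.DataFrame(rows, columns=["group_a", "group_b", "p_bonferroni"])
        return RankTestReport(test, float(stat), float(p), pw)
    raise ValueError(f"unknown test {test!r}")


def _pairwise_all_one(labels) -> pd.DataFrame:
    rows = [
        (labels[i], labels[j], 1.0)
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    return pd.DataFrame(rows, columns=["group_a", "group_b", "p_bonferroni"])


def percent_signal_change(
    group_a_means: Sequence[float],
    group_b_means: Sequence[float],
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Per-region percent change, 100 * (B - A) / (A + pseudocount)."""
    a = np.asarray(group_a_means, dtype=float)
    b = np.asarray(group_b_means, dtype=float)
    if a.shape != b.shape:
        raise ValueError("group mean vectors must be aligned")
    denom = a + pseudocount
    if (denom == 0).any():
        raise ValueError("zero denominator; use a positive pseudocount")
    return 100.0 * (b - a) / denom
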