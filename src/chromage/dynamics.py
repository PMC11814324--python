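"""Temporal and gene-family analyses.

Trajectory-shape classification calls each gene's ordered group-mean
trajectory (three ages) as up / down / peaked / dipped / flat relative
to a tolerance epsilon — e.g. a stress-response module that peaks at the
middle age in healthy animals but declines monotonically under
accelerated aging. The paralog-switch score formalizes coordinated
up/down regulation within a gene family (e.g. polycomb CBX paralogs:
Cbx2/4/8 up, Cbx6/7 down) as a contrast of mean log2 fold changes with
a genome-wide resampling null. Gene-set overlap significance uses a
binomial or exact hypergeometric upper tail; GMT collections are scored
by hypergeometric enrichment with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CountMatrix
from .stats import bh_adjust

SHAPES = ("up", "down", "peaked", "dipped", "flat")


def log2fc_by_gene(
    norm: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean_B + pc) / (mean_A + pc)) on normalized counts."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    a = norm.data[group_a].to_numpy(dtype=float).mean(axis=1)
    b = norm.data[group_b].to_numpy(dtype=float).mean(axis=1)
    return pd.Series(np.log2((b + pseudocount) / (a + pseudocount)),
                     index=norm.data.index, name="log2fc")


@dataclass
class SwitchResult:
    """Paralog-switch statistic for one gene family."""

    family: str
    up_set: list[str]
    down_set: list[str]
    gene_lfc: pd.Series
    score: float
    pvalue: float
    n_permutations: int
    seed: int


def paralog_switch_score(
    lfc: pd.Series,
    up_set: Sequence[str],
    down_set: Sequence[str],
    background_genes: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
    family: str = "family",
) -> SwitchResult:
    """Contrast-of-means switch score with a resampling null.

    score = mean LFC(up set) - mean LFC(down set). The null resamples
    |up| + |down| genes without replacement from the background and
    splits them randomly into same-sized sets; the one-sided p-value is
    (1 + #{null >= observed}) / (B + 1).
    """
    up_set, down_set = list(up_set), list(down_set)
    background = list(background_genes)
    if not up_set or not down_set:
        raise ValueError("up and down sets must be nonempty")
    if set(up_set) & set(down_set):
        raise ValueError("up and down sets overlap")
    outside = (set(up_set) | set(down_set)) - set(background)
    if outside:
        raise ValueError(f"gene(s) outside the background: {sorted(outside)}")
    if len(up_set) + len(down_set) > len(background):
        raise ValueError("sets larger than the background")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")

    observed = float(lfc.loc[up_set].mean() - lfc.loc[down_set].mean())
    rng = np.random.default_rng(seed)
    bg_vals = lfc.loc[background].to_numpy(dtype=float)
    n_up, n_tot = len(up_set), len(up_set) + len(down_set)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        pick = rng.choice(bg_vals.size, size=n_tot, replace=False)
        chosen = bg_vals[pick]
        rng.shuffle(chosen)
        null[i] = chosen[:n_up].mean() - chosen[n_up:].mean()
    p = (1.0 + np.sum(null >= observed)) / (n_permutations + 1.0)
    return SwitchResult(family, up_set, down_set, lfc, observed, float(p),
                        n_permutations, seed)


def classify_trajectory(means_by_age: Sequence[float], epsilon: float) -> str:
    """Shape of an ordered three-point trajectory relative to epsilon.

    Rules, evaluated in order on (m1, m2, m3):
    peaked if m2 > max(m1, m3) + eps; dipped if m2 < min(m1, m3) - eps;
    up if m3 - m1 > eps and m2 >= m1 - eps; down if m1 - m3 > eps and
    m2 <= m1 + eps; else flat.
    """
    if len(means_by_age) != 3:
        raise ValueError("trajectory classification expects exactly 3 timepoints")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    m1, m2, m3 = (float(v) for v in means_by_age)
    if m2 > max(m1, m3) + epsilon:
        return "peaked"
    if m2 < min(m1, m3) - epsilon:
        return "dipped"
    if m3 - m1 > epsilon and m2 >= m1 - epsilon:
        return "up"
    if m1 - m3 > epsilon and m2 <= m1 + epsilon:
        return "down"
    return "flat"


def epsilon_from_replicates(group_means: pd.DataFrame,
                            replicate_sds: pd.DataFrame,
                            n_replicates: pd.DataFrame | int) -> float:
    """Data-driven epsilon: pooled between-replicate SD of group means.

    Group-mean SD per cell is replicate SD / sqrt(n); epsilon is the
    root-mean-square over all cells.
    """
    if np.isscalar(n_replicates):
        n = float(n_replicates)
        sem2 = (replicate_sds.to_numpy(dtype=float) ** 2) / n
    else:
        sem2 = (replicate_sds.to_numpy(dtype=float) ** 2) / n_replicates.to_numpy(dtype=float)
    eps = float(np.sqrt(np.nanmean(sem2)))
    if eps <= 0:
        raise ValueError("pooled replicate SD is zero; pass an explicit epsilon")
    return eps


@dataclass
class TrajectoryCall:
    gene_id: str
    genotype: str
    means: tuple[float, float, float]
    epsilon: float
    shape: str


def classify_trajectories(
    group_means: pd.DataFrame,
    genotype: str,
    epsilon: float,
) -> list[TrajectoryCall]:
    """Classify every row of a gene x (3 ordered ages) group-mean table."""
    if group_means.shape[1] != 3:
        raise ValueError("expect exactly 3 ordered age columns")
    calls = []
    for gene, row in group_means.iterrows():
        m = tuple(float(v) for v in row)
        calls.append(TrajectoryCall(gene, genotype, m, epsilon,
                                    classify_trajectory(m, epsilon)))
    return calls


def gene_set_overlap_test(
    set_a: Sequence[str],
    set_b: Sequence[str],
    universe: Sequence[str],
    test: Literal["binomial", "hypergeometric"] = "binomial",
) -> dict:
    """Significance and fold enrichment of the overlap of two gene sets.

    With k = |A intersect B|: binomial tests k successes in |A| draws at
    rate |B|/|U| (upper tail, P(X >= k)); hypergeometric is the exact
    upper tail of drawing |A| genes from the universe without
    replacement. Fold enrichment is k / (|A| |B| / |U|).
    """
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= u or not b <= u:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    if k == 0:
        p = 1.0
    elif test == "binomial":
        p = float(sps.binom.sf(k - 1, len(a), len(b) / len(u)))
    elif test == "hypergeometric":
        p = float(sps.hypergeom.sf(k - 1, len(u), len(b), len(a)))
    else:
        raise ValueError(f"unknown test {test!r}")
    expected = len(a) * len(b) / len(u)
    fold = k / expected if expected > 0 else np.nan
    return {"overlap": k, "pvalue": min(1.0, p), "fold_enrichment": fold,
            "expected": expected, "test": test}


def gmt_enrichment(
    query: Sequence[str],
    universe: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query against a GMT collection.

    Each set is intersected with the universe first; p-values are
    BH-corrected across sets and the report is sorted by p.
    """
    u = set(universe)
    q = set(query) & u
    if not set(query):
        raise ValueError("empty query")
    if not q:
        raise ValueError("query has no genes in the universe")
    rows = []
    for name, members in gene_sets.items():
        s = set(members) & u
        k = len(q & s)
        if not s:
            p, fold = 1.0, np.nan
        else:
            p = 1.0 if k == 0 else float(sps.hypergeom.sf(k - 1, len(u), len(s), len(q)))
            expected = len(q) * len(s) / len(u)
            fold = k / expected if expected > 0 else np.nan
        rows.append({"gene_set": name, "set_size": len(s), "overlap": k,
                     "pvalue": min(1.0, p), "fold_enrichment": fold})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out.sort_values(["pvalue", "gene_set"], kind="mergesort").reset_index(drop=True)
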