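"""Chromatin-state partitioning of regions over histone-mark profiles.

k-means (k-means++ initialization, Lloyd iterations, best of several
restarts) partitions promoters by their multi-mark signal profiles;
rule-based selectors then identify the bivalent cluster (jointly high
H3K4me3 and H3K27me3) and split a region subset into signal-high /
signal-low subclusters. Cluster numbering follows the field's
convention: "cluster 1" is always the high-signal subcluster, derived
from mean signal, never from raw k-means label order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import BinnedSignalMatrix
from .stats import percent_signal_change


@dataclass
class ClusterAssignment:
    """Region-to-cluster labels (1..k) with centroids and fit diagnostics."""

    labels: pd.Series                  # region_id -> label in 1..k
    centroids: np.ndarray              # k x n_features, row i is cluster i+1
    inertia: float
    seed: int
    n_restarts: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def kmeans_cluster(
    features: pd.DataFrame,
    k: int,
    seed: int,
    n_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
    standardize_rows: bool = False,
) -> ClusterAssignment:
    """k-means over a region x feature grid; deterministic given the seed.

    With ``standardize_rows`` each region profile is centered and scaled
    (population SD; constant rows become zeros) before clustering, so
    marks with different dynamic ranges contribute equally.
    """
    x = features.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("features contain missing values")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of regions ({x.shape[0]})")
    if k < 1:
        raise ValueError("k must be >= 1")
    if standardize_rows:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(sd > 0, (x - mu) / sd, 0.0)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(x)
    labels = pd.Series(km.labels_ + 1, index=features.index, name="cluster")
    return ClusterAssignment(labels, km.cluster_centers_, float(km.inertia_),
                             seed, n_restarts)


def select_bivalent_cluster(
    assignment: ClusterAssignment,
    k4_means: Mapping[int, float],
    k27me3_means: Mapping[int, float],
) -> int:
    """Pick the cluster jointly high in H3K4me3 and H3K27me3.

    Per-cluster mean signals of the two marks are standardized across
    clusters; the winner maximizes min(z_K4me3, z_K27me3). Exact ties
    break toward the larger z sum, then the smaller label.
    """
    labels = sorted(set(assignment.labels))
    if len(labels) < 2:
        raise ValueError("bivalent-cluster selection needs >= 2 clusters")
    missing = [c for c in labels if c not in k4_means or c not in k27me3_means]
    if missing:
        raise ValueError(f"missing per-cluster means for cluster(s) {missing}")

    def _z(values: np.ndarray) -> np.ndarray:
        sd = values.std()
        return (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)

    z4 = _z(np.array([k4_means[c] for c in labels], dtype=float))
    z27 = _z(np.array([k27me3_means[c] for c in labels], dtype=float))
    key = [(min(a, b), a + b, -c) for a, b, c in zip(z4, z27, labels)]
    return labels[int(np.argmax(pd.Series(key)))]


def cluster_mark_means(assignment: ClusterAssignment,
                       signal: pd.Series) -> dict[int, float]:
    """Mean of a per-region signal within each cluster."""
    out = {}
    for label in sorted(set(assignment.labels)):
        members = assignment.members(label)
        out[label] = float(signal.loc[members].mean())
    return out


def split_high_low(
    region_ids: Sequence[str],
    signal: pd.Series,
    seed: int,
    log_transform: bool = False,
) -> tuple[list[str], list[str]]:
    """Two-way k-means split of a region subset by a single signal.

    Returns (high set, low set); the cluster with the larger mean signal
    is "cluster 1 (high)". A constant signal cannot be split and raises.
    """
    region_ids = list(region_ids)
    if len(region_ids) < 2:
        raise ValueError("need >= 2 regions to split")
    v = signal.loc[region_ids].to_numpy(dtype=float)
    if np.ptp(v) == 0:
        raise ValueError("constant signal: no high/low split exists")
    x = np.log1p(v) if log_transform else v
    km = KMeans(n_clusters=2, init="k-means++", n_init=10, random_state=seed).fit(
        x.reshape(-1, 1)
    )
    means = [v[km.labels_ == i].mean() for i in (0, 1)]
    high_label = int(np.argmax(means))
    high = [r for r, l in zip(region_ids, km.labels_) if l == high_label]
    low = [r for r, l in zip(region_ids, km.labels_) if l != high_label]
    return high, low


@dataclass
class Metaprofile:
    """Per-bin group mean signals with difference/percent-change profiles."""

    group_means: pd.DataFrame  # bins x groups

    def difference(self, group_a: str, group_b: str) -> pd.Series:
        return self.group_means[group_b] - self.group_means[group_a]

    def percent_change(self, group_a: str, group_b: str,
                       pseudocount: float = 0.0) -> pd.Series:
        pc = percent_signal_change(
            self.group_means[group_a].to_numpy(),
            self.group_means[group_b].to_numpy(),
            pseudocount,
        )
        return pd.Series(pc, index=self.group_means.index)


def metaprofile(
    binned_by_sample: Mapping[str, BinnedSignalMatrix],
    groups: Mapping[str, Sequence[str]],
) -> Metaprofile:
    """Average binned signal over regions and samples within each group."""
    n_bins = {b.scheme.n_bins for b in binned_by_sample.values()}
    if len(n_bins) > 1:
        raise ValueError("inconsistent bin schemes across samples")
    cols = {}
    for group, sample_ids in groups.items():
        sample_ids = list(sample_ids)
        if not sample_ids:
            raise ValueError(f"empty group {group!r}")
        missing = [s for s in sample_ids if s not in binned_by_sample]
        if missing:
            raise ValueError(f"no binned signal for sample(s) {missing}")
        stack = np.stack(
            [binned_by_sample[s].data.to_numpy(dtype=float) for s in sample_ids]
        )
        cols[group] = stack.mean(axis=(0, 1))
    return Metaprofile(pd.DataFrame(cols))
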