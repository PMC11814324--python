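"""Euchromatin score and the histone-modification epigenetic-age clock.

The euchromatin score of a gene in a paired sample is
z(H3K27ac) - z(H3K27me3), where each z-score is computed per gene across
all samples of that mark (both genotypes, all ages jointly, so WT and HD
share one scale). Pairing joins the two marks' samples on
(genotype, age, replicate) — the experimental design splits one nuclear
extract across antibodies, so replicate-level pairing is exact.

The clock is an ordinary least squares regression of the mean
euchromatin score over a reference gene set (the bivalent developmental
transcription-factor cluster) on chronological age, fitted on WT pairs.
Epigenetic age of any pair is read off by inverting the fitted line:
predicted = (score - intercept) / slope, and age acceleration is
predicted minus chronological age. A multiplicative aging acceleration
kappa in the data surfaces as predicted age = kappa * age, e.g. a
3-month distortion at chronological age 6 for kappa = 1.5.

``EuchromatinClock`` / ``ClockResults`` follow the model/results split:
the model holds the design (per-pair mean scores, ages, genotypes),
``fit()`` returns results carrying estimates, diagnostics and
``summary()``; prediction and simulation-style helpers hang off the
results object. ``fit_clock`` and ``predict_epigenetic_age`` are thin
functional wrappers over the same objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import SampleSheet
from .stats import ZScoreMatrix


@dataclass
class SamplePairing:
    """Replicate-level pairing of two marks' samples.

    One row per (genotype, age, replicate) key present in both marks;
    ``unmatched`` lists sample ids present in only one mark.
    """

    pairs: pd.DataFrame  # pair_id, sample_a, sample_b, genotype, age_months, replicate
    mark_a: str
    mark_b: str
    unmatched: list[str]

    @property
    def pair_ids(self) -> list[str]:
        return list(self.pairs["pair_id"])


def pair_samples(sheet: SampleSheet, mark_a: str, mark_b: str) -> SamplePairing:
    """Join the two marks' samples on (genotype, age_months, replicate)."""
    key = ["genotype", "age_months", "replicate"]
    a = sheet.for_mark(mark_a)
    b = sheet.for_mark(mark_b)
    if a.empty or b.empty:
        raise ValueError(f"no samples for mark {mark_a if a.empty else mark_b!r}")
    for df, mark in ((a, mark_a), (b, mark_b)):
        if df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key, keep=False)]
            raise ValueError(
                f"duplicate (genotype, age, replicate) within mark {mark}: "
                f"{dup[key].drop_duplicates().to_dict('records')}"
            )
    merged = a.merge(b, on=key, suffixes=("_a", "_b"), how="outer", indicator=True)
    unmatched = [
        sid
        for sid in pd.concat(
            [
                merged.loc[merged["_merge"] == "left_only", "sample_id_a"],
                merged.loc[merged["_merge"] == "right_only", "sample_id_b"],
            ]
        )
        if pd.notna(sid)
    ]
    if unmatched:
        warnings.warn(f"unpaired sample(s) dropped: {unmatched}", stacklevel=2)
    both = merged[merged["_merge"] == "both"]
    if both.empty:
        raise ValueError("zero pairs: no (genotype, age, replicate) key shared")
    pairs = pd.DataFrame(
        {
            "pair_id": [
                f"{g}_{a_:g}m_r{r}"
                for g, a_, r in zip(both["genotype"], both["age_months"], both["replicate"])
            ],
            "sample_a": both["sample_id_a"].to_numpy(),
            "sample_b": both["sample_id_b"].to_numpy(),
            "genotype": both["genotype"].to_numpy(),
            "age_months": both["age_months"].to_numpy(),
            "replicate": both["replicate"].to_numpy(),
        }
    ).reset_index(drop=True)
    return SamplePairing(pairs, mark_a, mark_b, unmatched)


@dataclass
class EuchromatinScoreMatrix:
    """Gene x pair euchromatin scores: z(mark A) - z(mark B) per pair."""

    data: pd.DataFrame
    pairing: SamplePairing

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)


def euchromatin_score(
    z_ac: ZScoreMatrix, z_me3: ZScoreMatrix, pairing: SamplePairing
) -> EuchromatinScoreMatrix:
    """Per-gene, per-pair score: z(H3K27ac sample) - z(H3K27me3 sample)."""
    if list(z_ac.data.index) != list(z_me3.data.index):
        raise ValueError("z-score matrices cover different gene ids")
    for col, zm in (("sample_a", z_ac), ("sample_b", z_me3)):
        missing = [s for s in pairing.pairs[col] if s not in zm.data.columns]
        if missing:
            raise ValueError(f"pairing references missing sample(s): {missing}")
    a = z_ac.data[list(pairing.pairs["sample_a"])].to_numpy()
    b = z_me3.data[list(pairing.pairs["sample_b"])].to_numpy()
    df = pd.DataFrame(a - b, index=z_ac.data.index, columns=pairing.pair_ids)
    return EuchromatinScoreMatrix(df, pairing)


def gene_set_mean_score(
    scores: EuchromatinScoreMatrix,
    gene_set: Sequence[str],
    on_missing: str = "warn",
) -> pd.Series:
    """Unweighted mean score over a gene set, per pair."""
    gene_set = list(dict.fromkeys(gene_set))
    present = [g for g in gene_set if g in scores.data.index]
    missing = [g for g in gene_set if g not in scores.data.index]
    if not present:
        raise ValueError("gene set has empty intersection with the score matrix")
    if missing:
        if on_missing == "error":
            raise ValueError(f"gene(s) absent from score matrix: {missing}")
        warnings.warn(f"{len(missing)} gene(s) absent from score matrix; excluded",
                      stacklevel=2)
    return scores.data.loc[present].mean(axis=0)


class EuchromatinClock:
    """Linear epigenetic-age model: mean reference-set score vs age.

    Parameters
    ----------
    pair_means : per-pair mean euchromatin score over the reference genes.
    ages, genotypes : chronological age (months) and genotype per pair,
        aligned with ``pair_means``.
    """

    def __init__(self, pair_means: pd.Series, ages: pd.Series, genotypes: pd.Series):
        idx = pair_means.index
        self.pair_means = pair_means.astype(float)
        self.ages = ages.reindex(idx).astype(float)
        self.genotypes = genotypes.reindex(idx)
        if self.ages.isna().any() or self.genotypes.isna().any():
            raise ValueError("ages/genotypes not aligned with pair means")

    @classmethod
    def from_scores(
        cls, scores: EuchromatinScoreMatrix, gene_set: Sequence[str],
        on_missing: str = "warn",
    ) -> "EuchromatinClock":
        means = gene_set_mean_score(scores, gene_set, on_missing=on_missing)
        meta = scores.pairing.pairs.set_index("pair_id")
        return cls(means, meta["age_months"], meta["genotype"])

    def fit(self, genotype_filter: str | None = "WT") -> "ClockResults":
        """OLS of mean score on chronological age over the chosen genotype."""
        mask = (
            self.genotypes == genotype_filter
            if genotype_filter is not None
            else pd.Series(True, index=self.pair_means.index)
        )
        y = self.pair_means[mask].to_numpy()
        x = self.ages[mask].to_numpy()
        if y.size < 3:
            raise ValueError("clock fit needs >= 3 pairs")
        if np.unique(x).size < 2:
            raise ValueError("clock fit needs >= 2 distinct ages")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
        with np.errstate(invalid="ignore"):
            rsq = float(res.rsquared)
        return ClockResults(
            model=self,
            intercept=float(res.params[0]),
            slope=float(res.params[1]),
            rsquared=rsq if np.isfinite(rsq) else 0.0,
            resid_sd=resid_sd,
            nobs=int(res.nobs),
            genotype=genotype_filter,
            _sm_results=res,
        )


@dataclass
class ClockResults:
    """Fitted clock: slope (score/month), intercept, fit diagnostics."""

    model: EuchromatinClock
    intercept: float
    slope: float
    rsquared: float
    resid_sd: float
    nobs: int
    genotype: str | None
    _sm_results: object = None

    def predict_age(
        self,
        pair_means: pd.Series | None = None,
        ages: pd.Series | None = None,
        genotypes: pd.Series | None = None,
        slope_min: float = 1e-6,
    ) -> pd.DataFrame:
        """Epigenetic age per pair by inverting the calibration line.

        predicted = (score - intercept) / slope;
        acceleration = predicted - chronological.
        """
        if abs(self.slope) <= slope_min:
            raise ValueError(
                f"clock slope {self.slope:.2e} is below {slope_min:.0e}: the score "
                "does not track age in the fitting data, so inversion is uninformative"
            )
        if pair_means is None:
            pair_means = self.model.pair_means
            ages = self.model.ages
            genotypes = self.model.genotypes
        predicted = (pair_means.astype(float) - self.intercept) / self.slope
        out = pd.DataFrame(
            {
                "score": pair_means.astype(float),
                "chronological_age": ages.reindex(pair_means.index).astype(float),
                "predicted_age": predicted,
            }
        )
        out["acceleration"] = out["predicted_age"] - out["chronological_age"]
        if genotypes is not None:
            out.insert(0, "genotype", genotypes.reindex(pair_means.index))
        return out

    def group_summary(self, estimates: pd.DataFrame | None = None) -> pd.DataFrame:
        """Mean +/- SD of predicted age and acceleration per genotype x age."""
        est = estimates if estimates is not None else self.predict_age()
        if "genotype" not in est.columns:
            raise ValueError("estimates lack a genotype column")
        g = est.groupby(["genotype", "chronological_age"])
        return g.agg(
            n=("predicted_age", "size"),
            predicted_mean=("predicted_age", "mean"),
            predicted_sd=("predicted_age", "std"),
            acceleration_mean=("acceleration", "mean"),
            acceleration_sd=("acceleration", "std"),
        ).reset_index()

    def summary(self) -> str:
        lines = [
            "Euchromatin-score epigenetic clock (OLS)",
            "----------------------------------------",
            f"fitted on genotype : {self.genotype or 'all'} ({self.nobs} pairs)",
            f"slope              : {self.slope:+.5f} score units / month",
            f"intercept          : {self.intercept:+.5f}",
            f"r-squared          : {self.rsquared:.4f}",
            f"residual SD        : {self.resid_sd:.5f}",
        ]
        return "\n".join(lines)


def fit_clock(
    pair_means: pd.Series,
    ages: pd.Series,
    genotypes: pd.Series,
    genotype_filter: str | None = "WT",
) -> ClockResults:
    """Functional wrapper: build the clock model and fit in one call."""
    return EuchromatinClock(pair_means, ages, genotypes).fit(genotype_filter)


def predict_epigenetic_age(
    results: ClockResults,
    pair_means: pd.Series,
    chronological_ages: pd.Series,
    genotypes: pd.Series | None = None,
    slope_min: float = 1e-6,
) -> pd.DataFrame:
    """Functional wrapper over ``ClockResults.predict_age``."""
    return results.predict_age(pair_means, chronological_ages, genotypes, slope_min)


@dataclass
class ScoreModules:
    """Gene modules with per-genotype mean score trajectories."""

    labels: pd.Series              # gene_id -> module 1..k (retained genes only)
    k: int
    silhouette_by_k: dict[int, float]
    trajectories: pd.DataFrame     # (module, genotype) x ordered (genotype, age) columns
    retained_genes: list[str]


def detect_score_modules(
    scores: EuchromatinScoreMatrix,
    variance_keep_fraction: float = 0.2,
    k_range: Sequence[int] = range(2, 9),
    seed: int = 0,
) -> ScoreModules:
    """Co-regulated euchromatin-score modules by trajectory clustering.

    Keeps the top ``variance_keep_fraction`` of genes by across-pair
    score variance, represents each gene by its standardized trajectory
    of (genotype, age) group means, clusters trajectories with k-means
    over ``k_range`` and selects k by maximum mean silhouette. Reports
    the mean module trajectory per genotype.
    """
    if not 0 < variance_keep_fraction <= 1:
        raise ValueError("variance_keep_fraction must be in (0, 1]")
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 1:
        raise ValueError("k_range must contain positive integers")
    meta = scores.pairing.pairs.set_index("pair_id")
    group_cols = sorted(
        {(g, a) for g, a in zip(meta["genotype"], meta["age_months"])},
        key=lambda t: (t[0] != "WT", t[0], t[1]),
    )

    var = scores.data.var(axis=1, ddof=0)
    n_keep = max(1, int(round(variance_keep_fraction * len(var))))
    if var.max() == 0:
        raise ValueError("all scores constant: no variable genes to cluster")
    retained = list(var.sort_values(ascending=False, kind="mergesort").index[:n_keep])
    if len(retained) < max(k_range):
        raise ValueError(
            f"{len(retained)} retained genes < max k {max(k_range)}; "
            "lower k_range or raise variance_keep_fraction"
        )

    traj = np.empty((len(retained), len(group_cols)))
    for j, (g, a) in enumerate(group_cols):
        cols = meta.index[(meta["genotype"] == g) & (meta["age_months"] == a)]
        traj[:, j] = scores.data.loc[retained, cols].mean(axis=1).to_numpy()
    mu = traj.mean(axis=1, keepdims=True)
    sd = traj.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (traj - mu) / sd, 0.0)

    sils: dict[int, float] = {}
    fits = {}
    for k in k_range:
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed).fit(z)
        fits[k] = km
        if k == 1 or len(set(km.labels_)) < 2:
            sils[k] = -1.0
        else:
            sils[k] = float(silhouette_score(z, km.labels_))
    best_k = max(k_range, key=lambda k: (sils[k], -k))
    km = fits[best_k]
    labels = pd.Series(km.labels_ + 1, index=retained, name="module")

    rows = []
    idx = []
    col_names = [f"{g}_{a:g}m" for g, a in group_cols]
    for module in range(1, best_k + 1):
        genes = labels.index[labels == module]
        for genotype in sorted(set(meta["genotype"]), key=lambda g: g != "WT"):
            sel = [j for j, (g, _) in enumerate(group_cols) if g == genotype]
            row = np.full(len(group_cols), np.nan)
            row[sel] = traj[np.isin(retained, genes)][:, sel].mean(axis=0)
            rows.append(row)
            idx.append((module, genotype))
    trajectories = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(idx, names=["module", "genotype"]),
        columns=col_names,
    )
    return ScoreModules(labels, best_k, sils, trajectories, retained)
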