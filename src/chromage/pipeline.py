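"""End-to-end orchestration of the synthetic-study analysis.

Runs the full chain on one study: median-of-ratios normalization per
mark, per-gene z-scores, replicate-paired euchromatin scores, five-way
promoter-state clustering with bivalent-cluster selection, the
H2AK119ub high/low split, the WT-calibrated epigenetic-age clock with
HD age prediction, and score-module detection. All randomness derives
from the study seed, so a fixed configuration reproduces byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import stats
from .clock import (
    ClockResults,
    EuchromatinClock,
    EuchromatinScoreMatrix,
    ScoreModules,
    detect_score_modules,
    euchromatin_score,
    pair_samples,
)
from .io import CountMatrix
from .synthetic import StudyConfig, SyntheticStudy, generate_study


@dataclass
class StudyAnalysis:
    """All intermediate and final products of one pipeline run."""

    study: SyntheticStudy
    size_factors: dict[str, pd.Series]
    normalized: dict[str, CountMatrix]
    zscores: dict[str, stats.ZScoreMatrix]
    scores: EuchromatinScoreMatrix
    promoter_clusters: cl.ClusterAssignment
    bivalent_cluster: int
    bivalent_genes: list[str]
    ub_high: list[str]
    ub_low: list[str]
    clock: ClockResults
    age_estimates: pd.DataFrame
    modules: ScoreModules | None


def cluster_features(normalized: dict[str, CountMatrix],
                     samples, marks: list[str] | None = None) -> pd.DataFrame:
    """Region x feature grid for promoter-state clustering.

    Per mark, genes are represented on the log2(normalized + 1) scale by
    (a) their trajectory: per-(genotype, age) group means centered on the
    gene's own mark mean, scaled by the mark's pooled deviation SD so
    marks with different dynamic ranges contribute equally while flat
    genes stay near the origin; and (b) one relative-level feature per
    mark: the gene's mark mean minus its cross-mark mean, standardized
    across genes. Relative levels capture mark-usage signatures (e.g.
    promoters high in both H3K4me3 and H3K27me3) while cancelling the
    per-gene coverage component shared by all marks.
    """
    if marks is None:
        marks = list(normalized)
    blocks = []
    levels = {}
    for mark, norm in ((m, normalized[m]) for m in marks):
        log = np.log2(norm.data + 1.0)
        meta = samples.for_mark(mark).set_index("sample_id")
        cols = {}
        for (genotype, age), grp in meta.groupby(["genotype", "age_months"]):
            cols[f"{mark}:{genotype}:{age:g}m"] = log[list(grp.index)].mean(axis=1)
        grouped = pd.DataFrame(cols)
        level = grouped.mean(axis=1)
        dev = grouped.sub(level, axis=0)
        pooled = float(np.sqrt((dev.to_numpy() ** 2).mean()))
        if pooled > 0:
            dev = dev / pooled
        blocks.append(dev)
        levels[mark] = level
    level_df = pd.DataFrame(levels)
    if level_df.shape[1] > 1:
        rel = level_df.sub(level_df.mean(axis=1), axis=0)
    else:
        rel = level_df
    sd = rel.std(ddof=0)
    rel = (rel - rel.mean()) / sd.where(sd > 0, 1.0)
    rel.columns = [f"{m}:rel_level" for m in rel.columns]
    blocks.append(rel)
    return pd.concat(blocks, axis=1)


def relative_mark_level(normalized: dict[str, CountMatrix], mark: str) -> pd.Series:
    """Per-gene log2 level of one mark relative to the gene's mean level
    over all marks, cancelling the shared coverage component."""
    levels = pd.DataFrame(
        {m: np.log2(norm.data + 1.0).mean(axis=1) for m, norm in normalized.items()}
    )
    if levels.shape[1] == 1:
        return levels[mark]
    return levels[mark] - levels.mean(axis=1)


def run_study_analysis(
    config: StudyConfig,
    k_promoter: int = 5,
    module_k_range=range(2, 6),
    detect_modules: bool = True,
) -> StudyAnalysis:
    """Generate a study under ``config`` and run the full analysis on it."""
    study = generate_study(config)
    size_factors, normalized, zscores = {}, {}, {}
    for mark, counts in study.counts.items():
        sf = stats.size_factors_median_of_ratios(counts)
        size_factors[mark] = sf
        normalized[mark] = stats.normalize_counts(counts, sf)
        zscores[mark] = stats.gene_zscores(normalized[mark])

    pairing = pair_samples(study.samples, "H3K27ac", "H3K27me3")
    scores = euchromatin_score(zscores["H3K27ac"], zscores["H3K27me3"], pairing)

    # bivalency clustering sees only the two bivalency-defining marks, so
    # PRC1-dependent and -independent bivalent genes land in one cluster
    # and the H2AK119ub high/low split below can separate them
    bivalency_marks = [m for m in ("H3K4me3", "H3K27me3") if m in normalized]
    features = cluster_features(normalized, study.samples, bivalency_marks or None)
    assignment = cl.kmeans_cluster(features, k=k_promoter, seed=config.seed)

    mean_level = {
        mark: normalized[mark].data.mean(axis=1)
        for mark in normalized
    }
    bivalent_label = cl.select_bivalent_cluster(
        assignment,
        cl.cluster_mark_means(assignment, mean_level["H3K4me3"]),
        cl.cluster_mark_means(assignment, mean_level["H3K27me3"]),
    )
    bivalent_genes = assignment.members(bivalent_label)

    if "H2AK119ub" in mean_level and len(bivalent_genes) >= 2:
        ub_high, ub_low = cl.split_high_low(
            bivalent_genes,
            relative_mark_level(normalized, "H2AK119ub"),
            seed=config.seed,
        )
    else:
        ub_high, ub_low = [], []

    reference_genes = ub_high if ub_high else bivalent_genes
    clock_model = EuchromatinClock.from_scores(scores, reference_genes)
    clock = clock_model.fit(genotype_filter="WT")
    age_estimates = clock.predict_age()

    modules = (
        detect_score_modules(
            scores, variance_keep_fraction=0.2, k_range=module_k_range,
            seed=config.seed,
        )
        if detect_modules
        else None
    )

    return StudyAnalysis(
        study=study,
        size_factors=size_factors,
        normalized=normalized,
        zscores=zscores,
        scores=scores,
        promoter_clusters=assignment,
        bivalent_cluster=bivalent_label,
        bivalent_genes=bivalent_genes,
        ub_high=ub_high,
        ub_low=ub_low,
        clock=clock,
        age_estimates=age_estimates,
        modules=modules,
    )


def write_analysis_outputs(analysis: StudyAnalysis, directory) -> dict[str, Path]:
    """Write the analysis products as deterministic TSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame, index_label: str | None = None) -> None:
        path = directory / f"{name}.tsv"
        df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
        manifest[name] = path

    sf = pd.DataFrame({m: s for m, s in analysis.size_factors.items()})
    _write("size_factors", sf, "sample_id")
    _write("euchromatin_scores", analysis.scores.data, "gene_id")
    _write("promoter_clusters", analysis.promoter_clusters.labels.to_frame(), "gene_id")
    _write("age_estimates", analysis.age_estimates, "pair_id")
    if analysis.modules is not None:
        _write("score_modules", analysis.modules.labels.to_frame(), "gene_id")
        _write("module_trajectories", analysis.modules.trajectories)
    summary = pd.DataFrame(
        {
            "key": ["bivalent_cluster", "n_bivalent_genes", "n_ub_high", "n_ub_low",
                    "clock_slope", "clock_intercept", "clock_r2"],
            "value": [analysis.bivalent_cluster, len(analysis.bivalent_genes),
                      len(analysis.ub_high), len(analysis.ub_low),
                      analysis.clock.slope, analysis.clock.intercept,
                      analysis.clock.rsquared],
        }
    )
    _write("run_summary", summary.set_index("key"), "key")
    return manifest
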