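"""Synthetic multi-mark histone-modification study generator.

Emulates the post-alignment shape of a two-genotype (WT vs HD knock-in),
three-age (2/6/10 months) striatal-neuron profiling design: per-gene
negative-binomial counts for up to four histone marks (H3K27ac, H3K27me3,
H3K4me3, H2AK119ub), with library-size factors, replicates, and planted
gene classes whose chromatin trajectories differ:

* ``background`` — flat signal, no aging trend.
* ``identity`` — neuron-identity genes: strongly acetylated, active
  promoters (high H3K27ac/H3K4me3, low H3K27me3); under HD only,
  H3K27ac declines and H3K27me3 accumulates with age
  (identity-gene heterochromatinization).
* ``bivalent_c1`` — bivalent developmental transcription factors with
  high H3K4me3 and elevated H3K27me3 baseline; with effective age,
  H3K27ac rises, H3K27me3 falls and H2AK119ub falls (PRC1-dependent
  de-repression).
* ``bivalent_c2`` — same H3K27ac/H3K27me3 de-repression but H2AK119ub
  pinned near background (PRC1-independent subcluster), making the
  high/low H2AK119ub split bimodal.
* ``stress`` — stress-response genes with a moderate active signature
  whose euchromatin-determining marks follow an inverted-U in effective
  age (peaking at the configured age on the WT trajectory; monotone
  non-increasing under HD acceleration).

Per-gene baselines share one coverage component across marks (real
signal tracks region length, mappability and accessibility in every
assay) plus a small mark-specific jitter, so mark-vs-mark comparisons
within a gene are informative, as they are in real data.

HD aging acceleration is multiplicative by default: effective age =
kappa * chronological age, so kappa = 1.5 plants a 3-month epigenetic-age
distortion at chronological age 6. An additive mode (effective age =
age + kappa_add) is also provided.

The same seed always yields byte-identical output; each mark draws from
its own RNG stream split from the master seed, so adding or removing a
mark never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    MARKS,
    CountMatrix,
    Region,
    RegionSet,
    SampleSheet,
    write_count_matrix,
    write_gmt,
    write_regions_bed,
    write_sample_sheet,
)

GENE_CLASSES = ("background", "identity", "bivalent_c1", "bivalent_c2", "stress")

# canonical stream index per mark, so per-mark streams are stable
_MARK_STREAM = {m: i for i, m in enumerate(MARKS)}
_GENE_LEVEL_STREAM = 100

_DEFAULT_BASELINES: dict[str, tuple[float, float]] = {
    "H3K27ac": (5.0, 8.0),
    "H3K27me3": (5.0, 8.0),
    "H3K4me3": (5.5, 8.5),
    "H2AK119ub": (4.5, 7.5),
}


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the simulated study design.

    Slopes are in log2 units per month of effective age. ``dispersion``
    is the NB alpha in the mean/dispersion parameterization
    (var = mu + alpha * mu^2); alpha = 0 degenerates to Poisson.
    """

    seed: int = 0
    n_background: int = 300
    n_identity: int = 20
    n_bivalent_c1: int = 30
    n_bivalent_c2: int = 20
    n_stress: int = 20
    ages: tuple[float, ...] = (2.0, 6.0, 10.0)
    genotypes: tuple[str, ...] = ("WT", "HD")
    n_replicates: int = 3
    marks: tuple[str, ...] = MARKS
    dispersion: float = 0.05
    baseline_log2_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINES)
    )
    size_factor_range: tuple[float, float] = (0.6, 1.6)
    baseline_mark_jitter_sd: float = 0.3
    acceleration_kappa: float = 1.5
    acceleration_mode: Literal["multiplicative", "additive"] = "multiplicative"
    # class-effect knobs
    slope_bivalent: float = 0.1      # +- on H3K27ac / H3K27me3 per effage month
    slope_ub: float = 0.08           # H2AK119ub decline at bivalent_c1 genes
    slope_identity: float = 0.1      # HD-only identity-gene drift per chronological month
    bivalent_k4_offset: float = 1.5  # flat-high H3K4me3 at bivalent promoters
    bivalent_me3_offset: float = 1.0  # bivalent promoters carry H3K27me3 above background
    c2_ub_low_log2: float = 2.0      # absolute low, flat H2AK119ub level at bivalent_c2
    identity_ac_offset: float = 1.5  # identity genes are strongly acetylated
    identity_k4_offset: float = 1.0  # ... with active promoters
    identity_me3_offset: float = -1.0  # ... and depleted of H3K27me3
    stress_active_offset: float = 0.5  # stress genes carry a moderate active signature
    stress_amplitude: float = 1.5    # height of the inverted-U (log2 units)
    stress_peak_age: float = 6.0     # effective age at which the WT trajectory peaks
    stress_halfwidth: float = 6.0    # months from peak to zero-crossing of the quadratic

    def __post_init__(self) -> None:
        if self.acceleration_kappa <= 0:
            raise ValueError("acceleration_kappa must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        ages = tuple(float(a) for a in self.ages)
        if any(a2 <= a1 for a1, a2 in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly increasing")
        if any(a <= 0 for a in ages):
            raise ValueError("ages must be positive")
        unknown = set(self.marks) - set(MARKS)
        if unknown:
            raise ValueError(f"unknown mark(s): {sorted(unknown)}")
        for n in (self.n_background, self.n_identity, self.n_bivalent_c1,
                  self.n_bivalent_c2, self.n_stress):
            if n < 0:
                raise ValueError("gene counts must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")

    @property
    def n_genes(self) -> int:
        return (self.n_background + self.n_identity + self.n_bivalent_c1
                + self.n_bivalent_c2 + self.n_stress)

    @classmethod
    def five_profile_benchmark(cls, seed: int = 0, **overrides) -> "StudyConfig":
        """Balanced-class configuration for promoter-profile clustering.

        A genome-wide promoter heatmap shows each epigenetic profile as a
        sizeable block, so the clustering benchmark uses comparable class
        sizes; the default (background-dominated) configuration instead
        mirrors the genome-wide rarity of changing regions that
        normalization relies on.
        """
        defaults = dict(n_background=60, n_identity=20, n_bivalent_c1=30,
                        n_bivalent_c2=20, n_stress=20)
        defaults.update(overrides)
        return cls(seed=seed, **defaults)

    def class_sizes(self) -> dict[str, int]:
        return {
            "background": self.n_background,
            "identity": self.n_identity,
            "bivalent_c1": self.n_bivalent_c1,
            "bivalent_c2": self.n_bivalent_c2,
            "stress": self.n_stress,
        }


@dataclass
class GroundTruth:
    """Planted parameters of a simulated study."""

    gene_class: pd.Series                  # gene_id -> class
    acceleration_kappa: float
    size_factors: pd.Series                # sample_id -> true factor
    baseline_log2_mean: pd.DataFrame       # gene x mark
    module: pd.Series                      # gene_id -> trajectory archetype

    def genes_of(self, cls: str) -> list[str]:
        return list(self.gene_class.index[self.gene_class == cls])


@dataclass
class SyntheticStudy:
    counts: dict[str, CountMatrix]
    samples: SampleSheet
    regions: RegionSet
    truth: GroundTruth
    config: StudyConfig


def effective_age(age: float, genotype: str, config: StudyConfig) -> float:
    """Effective (epigenetic) age of a sample: accelerated under HD."""
    if genotype != "HD":
        return float(age)
    if config.acceleration_mode == "multiplicative":
        return config.acceleration_kappa * float(age)
    return float(age) + config.acceleration_kappa


def _stress_curve(effage: float, config: StudyConfig) -> float:
    u = (effage - config.stress_peak_age) / config.stress_halfwidth
    return config.stress_amplitude * (1.0 - u * u)


def class_log2_effect(cls: str, mark: str, genotype: str, age: float,
                      config: StudyConfig) -> float:
    """Log2 shift of the NB mean for a gene class at one mark and sample.

    This is the planted biology; the baseline and size factor are added
    on top of it. Deterministic, so tests can use it as a closed form.
    """
    effage = effective_age(age, genotype, config)
    b = config.slope_bivalent
    if cls == "background":
        return 0.0
    if cls == "identity":
        offset = {
            "H3K27ac": config.identity_ac_offset,
            "H3K4me3": config.identity_k4_offset,
            "H3K27me3": config.identity_me3_offset,
        }.get(mark, 0.0)
        if genotype != "HD":
            return offset
        if mark == "H3K27ac":
            return offset - config.slope_identity * age
        if mark == "H3K27me3":
            return offset + config.slope_identity * age
        return offset
    if cls == "bivalent_c1":
        if mark == "H3K27ac":
            return b * effage
        if mark == "H3K27me3":
            return config.bivalent_me3_offset - b * effage
        if mark == "H2AK119ub":
            return -config.slope_ub * effage
        if mark == "H3K4me3":
            return config.bivalent_k4_offset
    if cls == "bivalent_c2":
        if mark == "H3K27ac":
            return b * effage
        if mark == "H3K27me3":
            return config.bivalent_me3_offset - b * effage
        if mark == "H2AK119ub":
            return 0.0  # level set absolutely via class_baseline_override
        if mark == "H3K4me3":
            return config.bivalent_k4_offset
    if cls == "stress":
        q = _stress_curve(effage, config)
        if mark == "H3K27ac":
            return config.stress_active_offset + q
        if mark == "H3K27me3":
            return -q
        if mark == "H3K4me3":
            return config.stress_active_offset
        return 0.0
    return 0.0


def class_baseline_override(cls: str, mark: str, config: StudyConfig) -> float | None:
    """Absolute log2 baseline for (class, mark) cells detached from the
    shared per-gene level, or None to use the drawn baseline.

    Only the H2AK119ub-low bivalent subcluster uses this: its signal sits
    near background regardless of how covered the gene otherwise is, which
    is what makes the high/low split bimodal.
    """
    if cls == "bivalent_c2" and mark == "H2AK119ub":
        return config.c2_ub_low_log2
    return None


def expected_log2_mean(gene_class: str, mark: str, genotype: str, age: float,
                       baseline: float, size_factor: float,
                       config: StudyConfig) -> float:
    """Closed-form log2 of the NB mean for one gene/mark/sample cell.

    ``baseline`` is the gene's realized baseline for the mark (as stored
    in ``GroundTruth.baseline_log2_mean``, which already reflects any
    absolute class override).
    """
    return (baseline
            + class_log2_effect(gene_class, mark, genotype, age, config)
            + np.log2(size_factor))


def _sample_design(config: StudyConfig, mark: str) -> pd.DataFrame:
    rows = []
    for genotype in config.genotypes:
        for age in config.ages:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{mark}_{genotype}_{age:g}m_r{rep}",
                        "mark": mark,
                        "genotype": genotype,
                        "age_months": float(age),
                        "replicate": rep,
                        "fraction": "NeuN+",
                    }
                )
    return pd.DataFrame(rows)


def _draw_nb(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with var = mu + alpha mu^2; alpha = 0 is Poisson."""
    if alpha == 0.0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Simulate count matrices, sample sheet, regions and ground truth.

    Counts for gene g, mark m, sample s are NB with mean
    2^(baseline_gm + class effect(m, genotype_s, effective age_s)) * sf_s
    and variance mu + alpha mu^2. One RNG stream per mark.
    """
    classes = []
    for cls, n in config.class_sizes().items():
        classes.extend([cls] * n)
    gene_ids = [f"gene_{i:04d}_{cls}" for i, cls in enumerate(classes)]
    gene_class = pd.Series(classes, index=gene_ids, name="class")

    module_map = {
        "background": "flat",
        "identity": "hd_down",
        "bivalent_c1": "accelerated_up",
        "bivalent_c2": "accelerated_up",
        "stress": "inverted_u",
    }
    module = gene_class.map(module_map).rename("module")

    counts: dict[str, CountMatrix] = {}
    sheets = []
    sf_all = {}
    baselines = pd.DataFrame(index=gene_ids, columns=list(config.marks), dtype=float)

    # shared per-gene coverage level (region length, mappability, local
    # accessibility act on every mark alike); drawn from its own stream so
    # the mark set never perturbs it
    rng_gene = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_GENE_LEVEL_STREAM,))
    )
    gene_level = rng_gene.uniform(0.0, 1.0, size=len(gene_ids))

    for mark in config.marks:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(_MARK_STREAM[mark],))
        )
        design = _sample_design(config, mark)
        lo, hi = config.baseline_log2_range.get(mark, (5.0, 8.0))
        jitter = rng.normal(0.0, config.baseline_mark_jitter_sd, size=len(gene_ids))
        base = lo + gene_level * (hi - lo) + jitter
        for i, cls in enumerate(classes):
            override = class_baseline_override(cls, mark, config)
            if override is not None:
                base[i] = override + jitter[i]
        baselines[mark] = base
        sf = rng.uniform(*config.size_factor_range, size=len(design))
        for sid, f in zip(design["sample_id"], sf):
            sf_all[sid] = f
        mat = np.empty((len(gene_ids), len(design)), dtype=np.int64)
        for j, row in design.iterrows():
            eff = np.array(
                [
                    class_log2_effect(cls, mark, row["genotype"], row["age_months"], config)
                    for cls in classes
                ]
            )
            mu = 2.0 ** (base + eff) * sf[j]
            mat[:, j] = _draw_nb(rng, mu, config.dispersion)
        df = pd.DataFrame(mat, index=gene_ids, columns=list(design["sample_id"]))
        counts[mark] = CountMatrix(df, mark=mark, normalized=False)
        sheets.append(design)

    samples = SampleSheet(pd.concat(sheets, ignore_index=True))
    regions = RegionSet(
        Region("chrSim", 10_000 * (i + 1), 10_000 * (i + 1) + 2_000, g, 0.0,
               "+" if i % 2 == 0 else "-")
        for i, g in enumerate(gene_ids)
    )
    truth = GroundTruth(
        gene_class=gene_class,
        acceleration_kappa=config.acceleration_kappa,
        size_factors=pd.Series(sf_all, name="size_factor"),
        baseline_log2_mean=baselines,
        module=module,
    )
    return SyntheticStudy(counts, samples, regions, truth, config)


def write_study_fixtures(study: SyntheticStudy, directory) -> dict[str, Path]:
    """Write a study to plain-text fixtures; round-trips through the readers.

    Emits counts_<mark>.tsv per mark, samples.tsv, regions.bed, truth.tsv
    and genesets.gmt (one gene set per planted class).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    for mark, cm in study.counts.items():
        path = directory / f"counts_{mark}.tsv"
        write_count_matrix(cm, path)
        manifest[f"counts_{mark}"] = path

    path = directory / "samples.tsv"
    write_sample_sheet(study.samples, path)
    manifest["samples"] = path

    path = directory / "regions.bed"
    write_regions_bed(study.regions, path)
    manifest["regions"] = path

    path = directory / "truth.tsv"
    truth_df = study.truth.gene_class.rename("class").to_frame()
    truth_df.index.name = "gene_id"
    truth_df.to_csv(path, sep="\t")
    manifest["truth"] = path

    path = directory / "genesets.gmt"
    sets = {cls: study.truth.genes_of(cls) for cls in GENE_CLASSES
            if (study.truth.gene_class == cls).any()}
    write_gmt(sets, path, descriptions={c: "planted gene class" for c in sets})
    manifest["genesets"] = path
    return manifest
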