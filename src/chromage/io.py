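"""Readers, writers and interval arithmetic for the pipeline's file formats.

Covers BED3–BED6 region sets, bedGraph coverage, tab-separated count
matrices and sample sheets, and GMT gene-set collections, plus promoter
derivation and signal binning around TSSs or along scaled gene bodies.

All genomic coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

MARKS = ("H3K27ac", "H3K27me3", "H3K4me3", "H2AK119ub")
GENOTYPES = ("WT", "HD")
FRACTIONS = ("NeuN+", "NeuN-", "bulk")

SAMPLE_SHEET_COLUMNS = ["sample_id", "mark", "genotype", "age_months", "replicate", "fraction"]

_STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A file violated its format contract."""


@dataclass(frozen=True)
class Region:
    """A genomic interval with BED6 attributes (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionSet:
    """Ordered collection of uniquely named regions."""

    def __init__(self, regions: Iterable[Region]):
        self.regions: list[Region] = list(regions)
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region names: {dupes[:5]}")
        self._by_name = {r.name: r for r in self.regions}

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, name: str) -> Region:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def sorted(self) -> "RegionSet":
        return RegionSet(sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "name": [r.name for r in self.regions],
                "score": [r.score for r in self.regions],
                "strand": [r.strand for r in self.regions],
            }
        )


class SampleSheet:
    """Sample metadata table: one row per sequencing sample.

    Columns: sample_id, mark, genotype (WT/HD), age_months (> 0),
    replicate (int), fraction (NeuN+/NeuN-/bulk).
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        df = df[SAMPLE_SHEET_COLUMNS]
        if df["sample_id"].duplicated().any():
            dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        df["genotype"] = df["genotype"].astype(str).str.strip()
        df["fraction"] = df["fraction"].astype(str).str.strip()
        bad_gt = set(df["genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise ValueError(f"unknown genotype(s): {sorted(bad_gt)}")
        bad_fr = set(df["fraction"]) - set(FRACTIONS)
        if bad_fr:
            raise ValueError(f"unknown fraction(s): {sorted(bad_fr)}")
        try:
            df["age_months"] = df["age_months"].astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"unparseable age_months: {exc}") from exc
        if (df["age_months"] <= 0).any():
            raise ValueError("age_months must be > 0")
        df["replicate"] = df["replicate"].astype(int)
        if df.isna().any().any():
            raise ValueError("sample sheet has missing values")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records["sample_id"])

    def subset(self, **criteria) -> "SampleSheet":
        """Rows matching all keyword criteria, e.g. subset(mark="H3K27ac", genotype="WT")."""
        df = self.records
        for col, val in criteria.items():
            df = df[df[col] == val]
        return SampleSheet(df)

    def for_mark(self, mark: str) -> pd.DataFrame:
        return self.records[self.records["mark"] == mark].reset_index(drop=True)


class CountMatrix:
    """Region x sample signal matrix for one histone mark.

    Raw matrices hold nonnegative integers (read counts); normalized
    matrices hold nonnegative reals (counts divided by size factors).
    """

    def __init__(self, data: pd.DataFrame, mark: str, normalized: bool = False):
        if (data.values < 0).any():
            raise ValueError("count matrix has negative entries")
        if not normalized:
            vals = data.values
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("raw count matrix must contain integers")
            data = data.round().astype(np.int64)
        else:
            data = data.astype(float)
        if data.index.duplicated().any() or data.columns.duplicated().any():
            raise ValueError("duplicate region or sample ids")
        self.data = data
        self.mark = mark
        self.normalized = normalized

    @property
    def region_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.mark == other.mark
            and self.normalized == other.normalized
            and self.data.equals(other.data)
        )


@dataclass
class BinScheme:
    """TSS-centered binning: ``flank`` bp either side, fixed ``bin_width``."""

    flank: int
    bin_width: int
    kind: Literal["tss"] = "tss"

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.flank <= 0:
            raise ValueError("flank and bin_width must be positive")
        if self.bin_width > self.flank:
            raise ValueError("bin_width larger than flank")
        if (2 * self.flank) % self.bin_width != 0:
            raise ValueError("2*flank must be a multiple of bin_width")

    @property
    def n_bins(self) -> int:
        return (2 * self.flank) // self.bin_width


@dataclass
class BodyBinScheme:
    """Scaled-gene-body binning: flanks in bp plus ``n_body_bins`` over the body."""

    flank: int
    n_body_bins: int
    n_flank_bins: int = 10
    kind: Literal["body"] = "body"

    def __post_init__(self) -> None:
        if self.n_body_bins <= 0 or self.n_flank_bins < 0:
            raise ValueError("need at least one body bin")
        if self.flank > 0 and self.n_flank_bins == 0:
            raise ValueError("nonzero flank requires flank bins")

    @property
    def n_bins(self) -> int:
        return self.n_body_bins + 2 * self.n_flank_bins


class BinnedSignalMatrix:
    """Per-region, per-bin mean coverage, 5' to 3' (bin 0 is always 5')."""

    def __init__(self, data: pd.DataFrame, scheme):
        if data.shape[1] != scheme.n_bins:
            raise ValueError("bin count inconsistent with scheme")
        self.data = data
        self.scheme = scheme


# ---------------------------------------------------------------------------
# sample sheets


def read_sample_sheet(path) -> SampleSheet:
    """Read and validate a tab-separated sample sheet."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED


def read_regions_bed(path) -> RegionSet:
    """Parse BED3–BED6. Missing names become ``chrom:start-end``; missing strand '.'."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"{chrom}:{start}-{end}"
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                regions.append(Region(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(regions)


def write_regions_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n")


def promoters_from_genes(genes: RegionSet, upstream: int = 2000, downstream: int = 2000,
                         suffix: str = "_promoter") -> RegionSet:
    """Promoter windows around each gene's TSS, strand-aware, clipped at 0.

    For "+" or "." strand the TSS is ``start`` and the window is
    [TSS - upstream, TSS + downstream); for "-" strand the TSS is ``end``
    and the window is [TSS - downstream, TSS + upstream).
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    if upstream < 0 or downstream < 0 or (upstream == 0 and downstream == 0):
        raise ValueError("window sizes must be nonnegative and not both zero")
    out = []
    for g in genes:
        if g.strand == "-":
            tss = g.end
            start, end = max(0, tss - downstream), tss + upstream
        else:
            tss = g.start
            start, end = max(0, tss - upstream), tss + downstream
        out.append(Region(g.chrom, start, end, g.name + suffix, g.score, g.strand))
    return RegionSet(out)


# ---------------------------------------------------------------------------
# bedGraph coverage


def _read_bedgraph(path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends, values) arrays sorted by start."""
    chroms: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph line") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            chroms.setdefault(fields[0], []).append((start, end, value))
    out = {}
    for chrom, ivals in chroms.items():
        ivals.sort()
        starts = np.array([i[0] for i in ivals], dtype=np.int64)
        ends = np.array([i[1] for i in ivals], dtype=np.int64)
        values = np.array([i[2] for i in ivals], dtype=float)
        if (starts[1:] < ends[:-1]).any():
            warnings.warn(
                f"{path}: overlapping bedGraph intervals on {chrom}; "
                "overlapping bases are summed",
                stacklevel=3,
            )
        out[chrom] = (starts, ends, values)
    return out


def _interval_weighted_sum(tracks, chrom: str, start: int, end: int) -> float:
    """Sum of value * overlap_bp over track intervals intersecting [start, end)."""
    if chrom not in tracks:
        return 0.0
    starts, ends, values = tracks[chrom]
    overlap = np.minimum(ends, end) - np.maximum(starts, start)
    mask = overlap > 0
    return float(np.sum(values[mask] * overlap[mask]))


def region_coverage_from_bedgraph(path, regions: RegionSet,
                                  mode: Literal["sum", "mean"] = "sum") -> pd.Series:
    """Per-region coverage from a 4-column bedGraph.

    ``sum``: integral of the step function over the region (value x bp);
    ``mean``: that integral divided by region length. Regions with no
    overlapping interval get 0.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    tracks = _read_bedgraph(path)
    vals = []
    for r in regions:
        s = _interval_weighted_sum(tracks, r.chrom, r.start, r.end)
        vals.append(s / r.length if mode == "mean" else s)
    return pd.Series(vals, index=regions.names, name=mode)


def _bin_edges(region: Region, scheme) -> list[tuple[int, int]]:
    """5'-to-3' list of (start, end) bin intervals in genomic coordinates."""
    if scheme.kind == "tss":
        tss = region.start if region.strand != "-" else region.end
        lo = tss - scheme.flank
        edges = [
            (lo + i * scheme.bin_width, lo + (i + 1) * scheme.bin_width)
            for i in range(scheme.n_bins)
        ]
    else:
        nb = scheme.n_body_bins
        body = np.linspace(region.start, region.end, nb + 1)
        body_bins = [(int(round(body[i])), int(round(body[i + 1]))) for i in range(nb)]
        if scheme.n_flank_bins > 0:
            fw = scheme.flank / scheme.n_flank_bins
            up = [
                (int(round(region.start - scheme.flank + i * fw)),
                 int(round(region.start - scheme.flank + (i + 1) * fw)))
                for i in range(scheme.n_flank_bins)
            ]
            down = [
                (int(round(region.end + i * fw)), int(round(region.end + (i + 1) * fw)))
                for i in range(scheme.n_flank_bins)
            ]
        else:
            up, down = [], []
        edges = up + body_bins + down
    if region.strand == "-":
        edges = edges[::-1]
    return edges


def bin_region_signal(path, regions: RegionSet, scheme) -> BinnedSignalMatrix:
    """Mean bedGraph coverage per bin around each region, strand-oriented.

    Bins of "-"-strand regions are reversed so bin 0 is always the 5' end.
    Bins that fall below coordinate 0 are truncated at 0 (mean over the
    remaining width).
    """
    tracks = _read_bedgraph(path)
    rows = np.zeros((len(regions), scheme.n_bins))
    for i, r in enumerate(regions):
        for j, (bs, be) in enumerate(_bin_edges(r, scheme)):
            bs = max(0, bs)
            if be <= bs:
                continue
            rows[i, j] = _interval_weighted_sum(tracks, r.chrom, bs, be) / (be - bs)
    df = pd.DataFrame(rows, index=regions.names, columns=range(scheme.n_bins))
    return BinnedSignalMatrix(df, scheme)


# ---------------------------------------------------------------------------
# count matrices and GMT


def read_count_matrix(path, mark: str, normalized: bool = False) -> CountMatrix:
    """TSV with a region-id first column and one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged or missing entries")
    return CountMatrix(df, mark=mark, normalized=normalized)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "region_id"
    df.to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name, description, members. Members deduplicated in order."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line with < 3 fields")
            name = fields[0]
            seen: dict[str, None] = {}
            for g in fields[2:]:
                if g and g not in seen:
                    seen[g] = None
            sets[name] = list(seen)
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
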