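"""Readers, writers and shared domain types.

All genome coordinates are 0-based half-open internally and in BED output.
Haplotype-frequency tables may be read from 1-based inclusive files with
``dialect="one-based"``.

Tabular formats:

* haplotype frequencies — TSV with columns ``chrom  start  end`` followed by
  one column per founder accession (alphabetical order, see :data:`FOUNDERS`);
* phenotypes — CSV with columns ``individual_id, population_id, replicate,
  generation, family_id, branches, flowering_days, treatment, selected``;
* pedigree — CSV with columns ``individual_id, sire_id, dam_id, generation``
  (empty parent fields mark founders);
* SNPs — TSV with columns ``chrom, pos, carriers, freq`` where ``carriers``
  is a comma-separated subset of the founder labels;
* sweep intervals — BED dialect with ``chrom, start, end, name, score``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("magicsweep")

#: The 19 founder accessions of the multiparent population, alphabetical.
FOUNDERS: tuple[str, ...] = (
    "Bur-0", "Can-0", "Col-0", "Ct-1", "Edi-0", "Hi-0", "Kn-0",
    "Ler-0", "Mt-0", "No-0", "Oy-0", "Po-0", "Rsch-4", "Sf-2",
    "Tsu-0", "Wil-2", "Ws-0", "Wu-0", "Zu-0",
)

N_FOUNDERS = len(FOUNDERS)

#: Maximum expected heterozygosity with 19 equifrequent alleles.
MAX_HETEROZYGOSITY = 1.0 - N_FOUNDERS * (1.0 / N_FOUNDERS) ** 2  # 18/19


class ValidationError(ValueError):
    """A table violated one of its declared invariants."""


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes, centromere positions and simulated locus counts.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    centromere_midpoints
        Map chromosome name -> centromere midpoint (bp).
    mask_radius
        Half-width of the centromeric mask in bp (windows within this
        distance of a centromere midpoint are flagged in scans).
    sim_loci_per_chromosome
        Number of simulated loci per chromosome; the defaults equal the
        number of 200 kb / 100 kb sliding windows on each chromosome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromere_midpoints: Mapping[str, int]
    mask_radius: int = 1_000_000
    sim_loci_per_chromosome: tuple[int, ...] = (303, 195, 233, 184, 268)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length")
        if set(self.centromere_midpoints) != set(names):
            raise ValidationError("centromere map must have one entry per chromosome")
        for name, length in self.chromosomes:
            mid = self.centromere_midpoints[name]
            if not 0 <= mid <= length:
                raise ValidationError(f"centromere of {name} outside chromosome")
        if len(self.sim_loci_per_chromosome) != len(self.chromosomes):
            raise ValidationError("one locus count per chromosome required")
        if any(c <= 0 for c in self.sim_loci_per_chromosome):
            raise ValidationError("locus counts must be positive")

    @classmethod
    def arabidopsis(cls) -> "GenomeLayout":
        """Default layout: the five A. thaliana chromosomes (TAIR10 sizes)."""
        return cls(
            chromosomes=(
                ("Chr1", 30_427_671),
                ("Chr2", 19_698_289),
                ("Chr3", 23_459_830),
                ("Chr4", 18_585_056),
                ("Chr5", 26_975_502),
            ),
            centromere_midpoints={
                "Chr1": 15_086_000,
                "Chr2": 3_608_000,
                "Chr3": 13_799_000,
                "Chr4": 3_956_000,
                "Chr5": 11_725_000,
            },
        )

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def windows(self, size: int = 200_000, step: int = 100_000) -> pd.DataFrame:
        """Sliding-window grid over the whole genome (0-based half-open)."""
        if not 0 < step <= size:
            raise ValidationError("require 0 < step <= size")
        frames = []
        for name, length in self.chromosomes:
            starts = np.arange(0, length - size + 1, step, dtype=np.int64)
            frames.append(pd.DataFrame(
                {"chrom": name, "start": starts, "end": starts + size}))
        return pd.concat(frames, ignore_index=True)

    def is_centromeric(self, chrom: np.ndarray | Sequence[str],
                       start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Flag windows whose midpoint lies within ``mask_radius`` of the
        centromere midpoint of their chromosome."""
        chrom = np.asarray(chrom)
        mid = (np.asarray(start) + np.asarray(end)) / 2.0
        cen = np.array([self.centromere_midpoints[c] for c in chrom], dtype=float)
        return np.abs(mid - cen) <= self.mask_radius


# ---------------------------------------------------------------------------
# Haplotype-frequency tables
# ---------------------------------------------------------------------------

_COORD_COLS = ["chrom", "start", "end"]


@dataclass
class HaplotypeFrequencyTable:
    """Per-window frequencies of the 19 founder haplotypes for one population.

    ``data`` holds ``chrom, start, end`` plus one column per founder label.
    Row frequency sums are within 1e-6 of 1 after validation.
    """

    population_id: str
    data: pd.DataFrame

    @classmethod
    def from_dataframe(cls, population_id: str, data: pd.DataFrame,
                       renorm_tol: float = 1e-3) -> "HaplotypeFrequencyTable":
        missing = [c for c in _COORD_COLS + list(FOUNDERS) if c not in data.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        data = data[_COORD_COLS + list(FOUNDERS)].copy()
        freqs = data[list(FOUNDERS)].to_numpy(dtype=float)
        eps = 1e-9  # tolerate float round-off from upstream renormalisation
        if np.any(freqs < -eps) or np.any(freqs > 1 + eps):
            bad = int(np.where((freqs < -eps) | (freqs > 1 + eps))[0][0])
            raise ValidationError(f"frequency outside [0, 1] in row {bad}")
        freqs = np.clip(freqs, 0.0, 1.0)
        sums = freqs.sum(axis=1)
        off = np.abs(sums - 1.0) > renorm_tol
        if np.any(off):
            bad = int(np.where(off)[0][0])
            raise ValidationError(
                f"row {bad} frequencies sum to {sums[bad]:.6g}, "
                f"beyond tolerance {renorm_tol}")
        data[list(FOUNDERS)] = freqs / sums[:, None]
        if np.any(data["end"].to_numpy() <= data["start"].to_numpy()):
            raise ValidationError("window_end must exceed window_start")
        sorted_ = data.sort_values(["chrom", "start"], kind="stable")
        if not np.array_equal(sorted_.index.to_numpy(), data.index.to_numpy()):
            raise ValidationError("windows not sorted by (chromosome, start)")
        return cls(population_id, data.reset_index(drop=True))

    @property
    def frequencies(self) -> np.ndarray:
        """(n_windows, 19) frequency matrix in founder column order."""
        return self.data[list(FOUNDERS)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def read_haplotype_frequencies(path: str | Path, population_id: str,
                               dialect: str = "bed") -> HaplotypeFrequencyTable:
    """Read a harp-style per-window haplotype-frequency TSV.

    ``dialect="bed"`` expects 0-based half-open coordinates; ``"one-based"``
    converts 1-based inclusive coordinates on read.
    """
    df = pd.read_csv(path, sep="\t")
    if dialect not in ("bed", "one-based"):
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in _COORD_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing coordinate columns: {missing}")
    if dialect == "one-based":
        df = df.assign(start=df["start"] - 1)
    return HaplotypeFrequencyTable.from_dataframe(population_id, df)


def write_haplotype_frequencies(table: HaplotypeFrequencyTable,
                                path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

TREATMENTS = ("LN", "HN")

_PHENO_COLS = ["individual_id", "population_id", "replicate", "generation",
               "family_id", "branches", "flowering_days", "treatment",
               "selected"]


@dataclass
class PhenotypeTable:
    """Individual-level phenotype records from the selection experiment."""

    data: pd.DataFrame

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "PhenotypeTable":
        missing = [c for c in _PHENO_COLS if c not in data.columns]
        if missing:
            raise ValidationError(f"missing phenotype columns: {missing}")
        data = data[_PHENO_COLS].copy()
        if (data["generation"] < 0).any():
            raise ValidationError("generation must be >= 0")
        if (data["branches"] < 0).any():
            raise ValidationError("branches must be >= 0")
        flower = data["flowering_days"]
        if (flower.dropna() <= 0).any():
            raise ValidationError("flowering_days must be positive or missing")
        bad = set(data["treatment"].dropna()) - set(TREATMENTS)
        if bad:
            raise ValidationError(f"unknown treatment labels: {sorted(bad)}")
        data["selected"] = data["selected"].astype(bool)
        return cls(data.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable.from_dataframe(pd.read_csv(path))


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pedigree tables
# ---------------------------------------------------------------------------

_PED_COLS = ["individual_id", "sire_id", "dam_id", "generation"]


@dataclass
class PedigreeTable:
    """Parent-offspring records; founders have both parents missing.

    Invariants enforced: unique ids; parents known and strictly earlier in
    generation than their offspring (which also rules out cycles); an
    individual is a founder iff both parents are missing -- individuals with
    exactly one known parent are allowed and treated downstream as having an
    unrelated phantom parent.
    """

    data: pd.DataFrame

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "PedigreeTable":
        missing = [c for c in _PED_COLS if c not in data.columns]
        if missing:
            raise ValidationError(f"missing pedigree columns: {missing}")
        data = data[_PED_COLS].copy()
        ids = data["individual_id"]
        if ids.duplicated().any():
            raise ValidationError("duplicate individual ids")
        gen = dict(zip(ids, data["generation"]))
        for parent_col in ("sire_id", "dam_id"):
            # normalise missing markers (None vs NaN) for stable round trips
            parents = data[parent_col].astype(object)
            parents = parents.where(parents.notna(), np.nan)
            data[parent_col] = parents
            known = parents.notna()
            unknown_ids = set(parents[known]) - set(ids)
            if unknown_ids:
                raise ValidationError(
                    f"unknown parent ids: {sorted(map(str, unknown_ids))[:5]}")
            parent_gen = parents[known].map(gen)
            if (parent_gen.to_numpy()
                    >= data.loc[known, "generation"].to_numpy()).any():
                raise ValidationError(
                    "parent must be in an earlier generation than offspring")
        return cls(data.reset_index(drop=True))

    @property
    def founders(self) -> pd.Series:
        return self.data.loc[
            self.data["sire_id"].isna() & self.data["dam_id"].isna(),
            "individual_id"]

    def __len__(self) -> int:
        return len(self.data)


def read_pedigree(path: str | Path) -> PedigreeTable:
    return PedigreeTable.from_dataframe(pd.read_csv(path))


def write_pedigree(table: PedigreeTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

@dataclass
class SnpTable:
    """Biallelic SNPs with their founder carrier sets and pooled frequency.

    ``data`` columns: ``chrom, pos, carriers (frozenset of founder labels),
    freq`` (observed pooled frequency at the final generation).
    """

    data: pd.DataFrame

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "SnpTable":
        missing = [c for c in ("chrom", "pos", "carriers", "freq")
                   if c not in data.columns]
        if missing:
            raise ValidationError(f"missing SNP columns: {missing}")
        data = data[["chrom", "pos", "carriers", "freq"]].copy()
        carriers = []
        for i, c in enumerate(data["carriers"]):
            s = frozenset(c.split(",")) if isinstance(c, str) else frozenset(c)
            if not s or not s < set(FOUNDERS):
                raise ValidationError(
                    f"row {i}: carrier set must be a non-empty proper subset "
                    f"of the {N_FOUNDERS} founders")
            carriers.append(s)
        data["carriers"] = carriers
        f = data["freq"].to_numpy(dtype=float)
        if np.any((f < 0) | (f > 1)):
            raise ValidationError("observed frequency outside [0, 1]")
        for _, grp in data.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValidationError("positions not sorted within chromosome")
        return cls(data.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)


def read_snps(path: str | Path) -> SnpTable:
    return SnpTable.from_dataframe(pd.read_csv(path, sep="\t"))


def write_snps(table: SnpTable, path: str | Path) -> None:
    out = table.data.copy()
    out["carriers"] = out["carriers"].map(lambda s: ",".join(sorted(s)))
    out.to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Sweep-interval BED output
# ---------------------------------------------------------------------------

_BED_HEADER = "# chrom\tstart\tend\tname\tscore"


def write_intervals(intervals: Iterable, path: str | Path) -> None:
    """Write sweep intervals as BED: name = ``population:statistic``, score =
    minimum statistic value in the interval.

    Raises if two intervals from the same population/statistic overlap
    (they should have been merged upstream).
    """
    intervals = list(intervals)
    by_key: dict[tuple, list] = {}
    for iv in intervals:
        by_key.setdefault((iv.population_id, iv.statistic, iv.chrom), []).append(iv)
    for key, ivs in by_key.items():
        ivs.sort(key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping intervals for {key[0]}/{key[1]} on {key[2]}")
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"{iv.population_id}:{iv.statistic}\t{iv.min_value:.9g}\n")


def read_intervals(path: str | Path) -> list:
    """Round-trip reader for :func:`write_intervals` output."""
    from .sweepscan import SweepInterval

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, name, score = line.split("\t")
            pop, stat = name.split(":")
            out.append(SweepInterval(
                chrom=chrom, start=int(start), end=int(end),
                population_id=pop, statistic=stat,
                min_value=float(score), n_windows=0))
    return out


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable scan/threshold parameters with their experiment defaults."""

    window_size: int = 200_000
    window_step: int = 100_000
    threshold_percentile: float = 1.0
    merge_gap: int = 400_000
    zscore_cutoff: float = -4.0
    afc_percentile: float = 99.0
    n_bootstrap: int = 1000
    n_null_loci: int = 1000
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.window_step <= self.window_size:
            raise ValidationError("require 0 < step <= size")
        for p in (self.threshold_percentile, self.afc_percentile):
            if not 0 < p < 100:
                raise ValidationError("percentiles must lie in (0, 100)")
        if self.merge_gap < 0:
            raise ValidationError("merge_gap must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def setup_logging(level: int = logging.INFO) -> None:
    """Structured-ish console logging shared by the CLI entry points."""
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
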