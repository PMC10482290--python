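"""Genome scans on haplotype-frequency windows.

Statistics: expected heterozygosity He = 1 - sum p_i^2 and its collapsed
top-k variants (He12, He123, He1234), which treat the k most frequent
haplotypes as a single allele -- sort frequencies descending and compute
1 - (sum of top k)^2 - sum of remaining squared frequencies -- gaining
sensitivity to soft sweeps where several haplotypes rise together.

Thresholds: the empirical rule takes a low percentile (default 1%) of each
directionally selected population's window values and combines them by the
median; the pedigree-null rule z-scales a track by a gene-drop null mean/SD
and flags windows below a z cutoff (default -4).  Below-threshold windows
are grouped into runs, runs within a merge gap (default 400 kb edge to
edge) are merged, and intervals overlapping the centromeric mask are
flagged (optionally dropped).  SNP scans summarise the absolute frequency
change |AFC| between the founder expectation (carrier-set size / 19) and
the observed pooled frequency, averaged per window, with outliers above a
high percentile (default 99%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (FOUNDERS, N_FOUNDERS, GenomeLayout,
                         HaplotypeFrequencyTable, SnpTable, ValidationError)

#: Map statistic name -> number of top haplotypes collapsed into one class.
STATISTICS = {"He": 1, "He12": 2, "He123": 3, "He1234": 4}


@dataclass
class ScanTrack:
    """One statistic value per genomic window for one population."""

    population_id: str
    statistic: str
    data: pd.DataFrame  # chrom, start, end, value, centromeric

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SweepInterval:
    """A merged run of below-threshold windows."""

    chrom: str
    start: int
    end: int
    population_id: str
    statistic: str
    min_value: float
    n_windows: int
    centromeric: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("interval end must exceed start")


@dataclass
class FrequencySpectrum:
    """Founder-haplotype frequencies averaged over a sweep interval,
    sorted descending."""

    interval: SweepInterval
    spectrum: pd.DataFrame  # founder, frequency


def _check_normalised(p: np.ndarray, tol: float = 1e-3) -> None:
    if np.any(p < -tol) or np.any(p > 1 + tol):
        raise ValidationError("frequencies outside [0, 1]")
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise ValidationError("frequency vector not normalised")


def expected_heterozygosity(frequency_vector) -> float:
    """He = 1 - sum p_i^2: probability two random draws differ."""
    p = np.asarray(frequency_vector, dtype=float)
    _check_normalised(p)
    return float(1.0 - (p ** 2).sum())


def collapsed_heterozygosity(frequency_vector, k: int) -> float:
    """He with the k most frequent haplotypes collapsed into one allele.

    k = 1 reduces to plain expected heterozygosity.
    """
    p = np.asarray(frequency_vector, dtype=float)
    if not 1 <= k <= p.shape[-1]:
        raise ValidationError(f"k must be in 1..{p.shape[-1]}")
    _check_normalised(p)
    q = np.sort(p)[::-1]
    return float(1.0 - q[:k].sum() ** 2 - (q[k:] ** 2).sum())


def _collapsed_matrix(freqs: np.ndarray, k: int) -> np.ndarray:
    """Vectorised collapsed-He over the rows of an (n, 19) matrix."""
    q = np.sort(freqs, axis=1)[:, ::-1]
    return 1.0 - q[:, :k].sum(axis=1) ** 2 - (q[:, k:] ** 2).sum(axis=1)


def scan_populations(tables: Sequence[HaplotypeFrequencyTable],
                     layout: GenomeLayout,
                     statistic: str = "He") -> list[ScanTrack]:
    """Compute one statistic per window per population, with centromere
    flags.  All tables must share one window grid."""
    if statistic not in STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}")
    k = STATISTICS[statistic]
    if not tables:
        raise ValidationError("no tables given")
    grid = tables[0].data[["chrom", "start", "end"]]
    tracks = []
    for table in tables:
        this_grid = table.data[["chrom", "start", "end"]]
        if not this_grid.equals(grid):
            raise ValidationError(
                f"window grid of {table.population_id} differs from "
                f"{tables[0].population_id}")
        values = _collapsed_matrix(table.frequencies, k)
        data = this_grid.copy()
        data["value"] = values
        data["centromeric"] = layout.is_centromeric(
            data["chrom"], data["start"], data["end"])
        tracks.append(ScanTrack(table.population_id, statistic, data))
    return tracks


def empirical_threshold(tracks: Sequence[ScanTrack],
                        percentile: float = 1.0) -> float:
    """Median across populations of each population's given percentile.

    Quantiles use linear interpolation between order statistics; missing
    windows are excluded.
    """
    if not tracks:
        raise ValidationError("no tracks given")
    if not 0 < percentile < 100:
        raise ValidationError("percentile must lie in (0, 100)")
    per_pop = [float(np.nanpercentile(t.data["value"].to_numpy(), percentile))
               for t in tracks]
    return float(np.median(per_pop))


def pooled_threshold(tracks: Sequence[ScanTrack],
                     percentile: float = 1.0) -> float:
    """Alternative: one percentile over all populations' windows pooled."""
    values = np.concatenate([t.data["value"].to_numpy() for t in tracks])
    return float(np.nanpercentile(values, percentile))


def zscore_track(track: ScanTrack, null_mean: float, null_sd: float) -> ScanTrack:
    """Scale a track by a gene-drop null: (value - mean) / SD per window."""
    if null_sd <= 0:
        raise ValidationError("null SD must be positive")
    data = track.data.copy()
    data["value"] = (data["value"] - null_mean) / null_sd
    return ScanTrack(track.population_id, "z" + track.statistic, data)


def merge_intervals(intervals: Sequence[SweepInterval],
                    merge_gap: int) -> list[SweepInterval]:
    """Merge same-chromosome intervals whose edge-to-edge distance is
    <= merge_gap.  Idempotent."""
    out: list[SweepInterval] = []
    by_chrom: dict[str, list[SweepInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: iv.start)
        current = ivs[0]
        for nxt in ivs[1:]:
            if nxt.start - current.end <= merge_gap:
                current = replace(
                    current, end=max(current.end, nxt.end),
                    min_value=min(current.min_value, nxt.min_value),
                    n_windows=current.n_windows + nxt.n_windows,
                    centromeric=current.centromeric or nxt.centromeric)
            else:
                out.append(current)
                current = nxt
        out.append(current)
    return out


def call_intervals(track: ScanTrack, threshold: float,
                   merge_gap: int = 400_000,
                   drop_centromeric: bool = False) -> list[SweepInterval]:
    """Group below-threshold windows into merged sweep intervals.

    Consecutive below-threshold windows form runs; runs on the same
    chromosome within ``merge_gap`` (edge to edge) are merged.  Intervals
    overlapping the centromeric mask are flagged, and removed when
    ``drop_centromeric``.
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    data = track.data
    below = data["value"].to_numpy() < threshold
    raw: list[SweepInterval] = []
    for chrom, grp in data.groupby("chrom", sort=False):
        mask = below[grp.index.to_numpy()]
        if not mask.any():
            continue
        idx = grp.index.to_numpy()[mask]
        # split into runs of consecutive window indices
        breaks = np.where(np.diff(idx) != 1)[0] + 1
        for run in np.split(idx, breaks):
            sub = data.loc[run]
            raw.append(SweepInterval(
                chrom=str(chrom), start=int(sub["start"].min()),
                end=int(sub["end"].max()),
                population_id=track.population_id,
                statistic=track.statistic,
                min_value=float(sub["value"].min()),
                n_windows=len(run),
                centromeric=bool(sub["centromeric"].any())))
    merged = merge_intervals(raw, merge_gap) if raw else []
    if drop_centromeric:
        merged = [iv for iv in merged if not iv.centromeric]
    return merged


def haplotype_spectrum(table: HaplotypeFrequencyTable,
                       interval: SweepInterval) -> FrequencySpectrum:
    """Mean founder frequencies over the windows overlapping an interval,
    sorted descending with labels."""
    data = table.data
    overlap = ((data["chrom"] == interval.chrom)
               & (data["start"] < interval.end)
               & (data["end"] > interval.start))
    if not overlap.any():
        raise ValidationError("interval overlaps no window of the table")
    means = data.loc[overlap, list(FOUNDERS)].mean(axis=0)
    spectrum = (means.rename("frequency").rename_axis("founder").reset_index()
                .sort_values("frequency", ascending=False, kind="stable")
                .reset_index(drop=True))
    return FrequencySpectrum(interval=interval, spectrum=spectrum)


def snp_afc_scan(snp_table: SnpTable, layout: GenomeLayout,
                 window_size: int = 200_000, window_step: int = 100_000,
                 afc_percentile: float = 99.0,
                 population_id: str = "") -> tuple[ScanTrack, pd.DataFrame]:
    """Windowed scan of absolute SNP allele-frequency change.

    Per SNP the founder (generation-1) frequency is carrier-set size / 19
    and |AFC| is its absolute difference from the observed pooled
    frequency.  Windows average the |AFC| of the SNPs they contain; empty
    windows are missing and excluded from the outlier percentile, which is
    computed within the supplied track (above = outlier).
    """
    grid = layout.windows(window_size, window_step)
    snps = snp_table.data
    founder_freq = snps["carriers"].map(len).to_numpy() / N_FOUNDERS
    afc = np.abs(snps["freq"].to_numpy() - founder_freq)

    values = np.full(len(grid), np.nan)
    for chrom, gidx in grid.groupby("chrom", sort=False).groups.items():
        sub = snps[snps["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        if pos.min() < 0 or pos.max() >= layout.length_of(str(chrom)):
            raise ValidationError(f"SNP outside chromosome {chrom}")
        a = afc[sub.index.to_numpy()]
        starts = grid.loc[gidx, "start"].to_numpy()
        ends = grid.loc[gidx, "end"].to_numpy()
        # each SNP falls in size/step consecutive windows
        lo = np.searchsorted(starts, pos - window_size, side="right")
        hi = np.searchsorted(starts, pos, side="right")
        sums = np.zeros(len(gidx))
        counts = np.zeros(len(gidx))
        for s, e, v in zip(lo, hi, a):
            sums[s:e] += v
            counts[s:e] += 1
        with np.errstate(invalid="ignore"):
            vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        values[np.asarray(gidx)] = vals

    data = grid.copy()
    data["value"] = values
    data["centromeric"] = layout.is_centromeric(
        data["chrom"], data["start"], data["end"])
    track = ScanTrack(population_id, "meanAFC", data)
    finite = data["value"].dropna()
    cutoff = float(np.percentile(finite, afc_percentile)) if len(finite) else np.nan
    outliers = data[data["value"] > cutoff].copy()
    return track, outliers
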