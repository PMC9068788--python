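"""Coverage normalization, meta-region matrices and multi-omics kinetics.

Coverage tracks are normalized so their wigsum (total per-base coverage)
equals 1e9, the scale of ten million 100-nt reads, making tracks from
libraries of different depth directly comparable. Meta-region matrices
average normalized coverage in 100-bp bins over +/-5 kb around anchoring
CpGs; bases beyond contig ends contribute zero while the bin denominator
stays at the full bin width (the "w0" convention). The kinetics table
summarizes, per uninherited-demethylated-region set, the time courses of
-dM, log2 coverage fold-changes per assay, and TF expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylome import UDRSet

TARGET_WIGSUM = 1e9


@dataclass
class CoverageTrack:
    """Dense per-base coverage arrays keyed by chromosome."""

    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}
        for chrom, arr in self.data.items():
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")

    @property
    def wigsum(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    @classmethod
    def from_bedgraph(cls, path: str | Path,
                      genome_bounds: Mapping[str, int]) -> "CoverageTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="t",
                         names=["Chromosome", "Start", "End", "Value"])
        return cls.from_intervals(df, genome_bounds)

    @classmethod
    def from_intervals(cls, df: pd.DataFrame,
                       genome_bounds: Mapping[str, int]) -> "CoverageTrack":
        """Build a dense track from (Chromosome, Start, End, Value) rows."""
        data = {c: np.zeros(n) for c, n in genome_bounds.items()}
        for row in df.itertuples(index=False):
            arr = data.get(row.Chromosome)
            if arr is None:
                continue
            start = max(0, int(row.Start))
            end = min(arr.size, int(row.End))
            if end > start:
                arr[start:end] += float(row.Value)
        return cls(data)

    @classmethod
    def from_reads(cls, reads: pd.DataFrame,
                   genome_bounds: Mapping[str, int]) -> "CoverageTrack":
        """Expand BED-style reads (unit weight each) to per-base coverage."""
        df = reads[["Chromosome", "Start", "End"]].copy()
        df["Value"] = 1.0
        return cls.from_intervals(df, genome_bounds)

    def to_bedgraph(self, path: str | Path) -> None:
        rows = []
        for chrom, arr in self.data.items():
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    rows.append((chrom, int(s), int(e), float(arr[s])))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def normalize_coverage(track: CoverageTrack,
                       target: float = TARGET_WIGSUM) -> CoverageTrack:
    """Scale a track uniformly so its wigsum equals ``target`` (default 1e9)."""
    total = track.wigsum
    if total <= 0:
        raise ValueError("cannot normalize an empty coverage track")
    factor = target / total
    return CoverageTrack({c: arr * factor for c, arr in track.data.items()})


def binned_coverage_matrix(
    track: CoverageTrack,
    centers: pd.DataFrame,
    half_width: int = 5000,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Mean coverage in ``bin_size``-bp bins over +/-half_width per center.

    ``centers`` has chrom/pos columns (pos 1-based). Each row spans
    [pos-1-half_width, pos-1+half_width) — 2*half_width bases, so 100 bins
    at the defaults. Out-of-contig bases count as zero coverage but the
    bin mean keeps the full ``bin_size`` denominator (w0 rule).
    """
    n_bins = (2 * half_width) // bin_size
    span = n_bins * bin_size
    rows = np.zeros((len(centers), n_bins))
    index = []
    for i, row in enumerate(centers.itertuples(index=False)):
        arr = track.data.get(row.chrom)
        index.append(getattr(row, "probe_id", i))
        if arr is None:
            continue
        start = int(row.pos) - 1 - half_width
        window = np.zeros(span)
        lo = max(0, start)
        hi = min(arr.size, start + span)
        if hi > lo:
            window[lo - start:hi - start] = arr[lo:hi]
        rows[i] = window.reshape(n_bins, bin_size).mean(axis=1)
    cols = np.arange(n_bins) * bin_size - half_width
    return pd.DataFrame(rows, index=index, columns=cols)


def mean_region_coverage(track: CoverageTrack, centers: pd.DataFrame,
                         half_width: int = 250) -> float:
    """Mean per-base coverage over closed +/-half_width windows (w0 rule)."""
    width = 2 * half_width + 1
    total = 0.0
    for row in centers.itertuples(index=False):
        arr = track.data.get(row.chrom)
        if arr is None:
            continue
        start = int(row.pos) - 1 - half_width
        lo = max(0, start)
        hi = min(arr.size, start + width)
        if hi > lo:
            total += arr[lo:hi].sum()
    return total / (len(centers) * width) if len(centers) else float("nan")


def region_tpm_profile(
    tag_tables: Mapping[str, pd.DataFrame],
    library_sizes: Mapping[str, float],
    centers: pd.DataFrame,
    half_width: int = 250,
    pseudo_tpm: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region TPM time courses around demethylated CpGs.

    ``tag_tables`` maps each time point to a table of tag 5' positions
    (columns chrom, pos 1-based, count); region TPM is the tag count within
    the closed +/-half_width window times 1e6 over the library size.
    Returns (per-region TPM matrix, summary) where the summary carries the
    across-region mean, s.d. and the mean relative to the first time point
    (pseudocount ``pseudo_tpm`` added to both sides of the ratio).
    """
    timepoints = list(tag_tables)
    values = np.zeros((len(centers), len(timepoints)))
    for j, t in enumerate(timepoints):
        lib = float(library_sizes[t])
        if lib <= 0:
            raise ValueError(f"non-positive library size for {t}")
        tags = tag_tables[t]
        count_col = tags["count"] if "count" in tags.columns else pd.Series(
            np.ones(len(tags)), index=tags.index)
        for i, row in enumerate(centers.itertuples(index=False)):
            sel = (tags["chrom"] == row.chrom) & (
                (tags["pos"] - row.pos).abs() <= half_width)
            values[i, j] = count_col[sel].sum() * 1e6 / lib
    ids = centers["probe_id"] if "probe_id" in centers.columns else range(len(centers))
    per_region = pd.DataFrame(values, index=list(ids), columns=timepoints)
    mean = per_region.mean(axis=0)
    sd = per_region.std(axis=0, ddof=1) if len(per_region) > 1 else mean * 0.0
    rel = (mean + pseudo_tpm) / (mean.iloc[0] + pseudo_tpm)
    summary = pd.DataFrame(
        {"mean_tpm": mean, "sd_tpm": sd, "relative_to_t0": rel})
    return per_region, summary


def kinetics_table(
    mvalues: pd.DataFrame,
    tracks: Mapping[str, Mapping[str, CoverageTrack]],
    udr_sets: Sequence[UDRSet],
    probes: pd.DataFrame,
    expression: pd.Series | None = None,
    half_width: int = 250,
    pseudo_coverage: float = 1.0,
) -> pd.DataFrame:
    """Multi-omics time courses per uninherited-demethylated-region set.

    For each UDR set and time point the table reports the mean -dM versus
    the first time point across member probes, and per assay in ``tracks``
    (time point -> normalized CoverageTrack) the log2 fold-change of mean
    region coverage versus the first time point with pseudo-coverage
    ``pseudo_coverage`` added to numerator and denominator. A TF expression
    series (TPM per time point) is appended as its own measure. Empty UDR
    sets are skipped with a warning. Long format: udr_timepoint, timepoint,
    measure, value.
    """
    timepoints = list(mvalues.columns)
    t0 = timepoints[0]
    rows = []
    for udr in udr_sets:
        if not udr.probe_ids:
            warnings.warn(f"empty UDR set at {udr.timepoint}; skipped", stacklevel=2)
            continue
        members = probes[probes["probe_id"].isin(udr.probe_ids)]
        sub_m = mvalues.loc[mvalues.index.isin(udr.probe_ids)]
        for t in timepoints:
            rows.append((udr.timepoint, t, "neg_delta_m",
                         float(-(sub_m[t] - sub_m[t0]).mean())))
        for assay, per_time in tracks.items():
            base = mean_region_coverage(per_time[t0], members, half_width)
            for t in timepoints:
                cov = mean_region_coverage(per_time[t], members, half_width)
                fc = np.log2((cov + pseudo_coverage) / (base + pseudo_coverage))
                rows.append((udr.timepoint, t, f"log2fc_{assay}", float(fc)))
        if expression is not None:
            for t in timepoints:
                rows.append((udr.timepoint, t, "tf_tpm", float(expression[t])))
    return pd.DataFrame(
        rows, columns=["udr_timepoint", "timepoint", "measure", "value"])
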