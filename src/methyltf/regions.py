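"""Genomic region sets: probe extension, overlap counting, permutation
testing and promoter/enhancer annotation.

Intervals are 0-based half-open throughout (BED convention). Probe CpGs,
given as 1-based base positions, extend to regions of width 2*half_width+1
centered on the cytosine. The permutation test relocates every query region
uniformly at random (length-preserving, chromosome chosen with probability
proportional to the number of valid start positions) and compares the
observed overlap count with the permuted distribution using the
(k + 1) / (n + 1) one-sided empirical tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pyranges as pr

from ._io import read_bed, write_bed


@dataclass
class RegionSet:
    """Named set of genomic intervals with per-chromosome bounds.

    ``df`` needs Chromosome/Start/End columns; Strand, Name and a 1-based
    ``Center`` column (the anchoring CpG for probe-derived regions) are
    optional. Intervals within a set may overlap each other.
    """

    name: str
    df: pd.DataFrame
    genome_bounds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        for col in ("Chromosome", "Start", "End"):
            if col not in df.columns:
                raise ValueError(f"RegionSet requires a {col} column")
        if len(df) and (df["Start"] >= df["End"]).any():
            raise ValueError("all intervals must satisfy Start < End")
        for chrom, grp in df.groupby("Chromosome", observed=True):
            bound = self.genome_bounds.get(chrom)
            if bound is not None and (grp["End"] > bound).any():
                raise ValueError(f"interval beyond bounds of {chrom}")
            if (grp["Start"] < 0).any():
                raise ValueError("negative interval start")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def to_pyranges(self) -> pr.PyRanges:
        return pr.PyRanges(self.df[["Chromosome", "Start", "End"]].copy())

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None,
                 genome_bounds: Mapping[str, int] | None = None) -> "RegionSet":
        return cls(name or Path(path).stem, read_bed(path),
                   dict(genome_bounds or {}))

    def to_bed(self, path: str | Path) -> None:
        write_bed(self.df, path)


def extend_probes_to_regions(
    probes: pd.DataFrame,
    half_width: int,
    genome_bounds: Mapping[str, int],
    name: str = "probe_regions",
) -> RegionSet:
    """Extend each CpG (1-based ``pos``) to [pos-1-hw, pos+hw), clamped.

    The unclamped width is 2*half_width + 1 bases, symmetric around the
    cytosine. Probes on chromosomes absent from ``genome_bounds`` are
    skipped with a warning.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    keep = probes["chrom"].isin(genome_bounds)
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} probes off-contig; skipped", stacklevel=2)
    sub = probes[keep]
    bounds = sub["chrom"].map(genome_bounds).to_numpy()
    center0 = sub["pos"].to_numpy() - 1
    df = pd.DataFrame(
        {
            "Chromosome": sub["chrom"].to_numpy(),
            "Start": np.maximum(0, center0 - half_width),
            "End": np.minimum(bounds, center0 + half_width + 1),
            "Name": sub["probe_id"].to_numpy(),
            "Center": sub["pos"].to_numpy(),
        }
    )
    return RegionSet(name, df, dict(genome_bounds))


def count_overlaps(a: RegionSet, b: RegionSet) -> tuple[int, float]:
    """Count intervals of ``a`` intersecting >= 1 base of ``b``.

    Returns (count, fraction of a overlapping). Each interval of ``a``
    counts at most once. Empty ``a`` yields fraction NaN with a warning.
    """
    if len(a) == 0:
        warnings.warn("empty query set: overlap fraction undefined", stacklevel=2)
        return 0, float("nan")
    if len(b) == 0:
        return 0, 0.0
    counts = a.to_pyranges().count_overlaps(b.to_pyranges())
    n = int((counts.df["NumberOverlaps"] > 0).sum())
    return n, n / len(a)


class _MergedIntervals:
    """Per-chromosome merged, sorted intervals supporting vectorized
    any-overlap queries (used inside the permutation loop)."""

    def __init__(self, region_set: RegionSet):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        merged = region_set.to_pyranges().merge() if len(region_set) else None
        if merged is None or merged.empty:
            return
        for chrom, grp in merged.df.groupby("Chromosome", observed=True):
            grp = grp.sort_values("Start")
            self.by_chrom[str(chrom)] = (
                grp["Start"].to_numpy(), grp["End"].to_numpy()
            )

    def count_any_overlap(self, chroms: np.ndarray, starts: np.ndarray,
                          ends: np.ndarray) -> int:
        total = 0
        for chrom in np.unique(chroms):
            iv = self.by_chrom.get(str(chrom))
            sel = chroms == chrom
            if iv is None or not sel.any():
                continue
            s, e = iv
            # first merged interval ending after the query start; overlap
            # iff that interval starts before the query end
            j = np.searchsorted(e, starts[sel], side="right")
            inside = j < len(s)
            hit = np.zeros(sel.sum(), dtype=bool)
            hit[inside] = s[j[inside]] < ends[sel][inside]
            total += int(hit.sum())
        return total


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the randomized region-overlap test."""

    observed: int
    permuted: np.ndarray
    p_value: float
    n_perms: int
    seed: int

    @property
    def z_score(self) -> float:
        sd = self.permuted.std(ddof=1)
        if sd == 0:
            return float("nan")
        return float((self.observed - self.permuted.mean()) / sd)


def randomize_placements(
    lengths: np.ndarray,
    bounds: Mapping[str, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One random relocation of intervals of the given lengths.

    Each interval is placed independently: the chromosome is drawn with
    probability proportional to its number of valid start positions for
    that length, the start uniformly among them — i.e. uniform over all
    length-preserving placements in the genome. Returns (chromosomes,
    starts).
    """
    chrom_names = np.array(list(bounds))
    chrom_lens = np.array([bounds[c] for c in chrom_names])
    slots = np.maximum(chrom_lens[None, :] - np.asarray(lengths)[:, None] + 1, 0)
    totals = slots.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("an interval is longer than every chromosome")
    cum = (slots / totals[:, None]).cumsum(axis=1)
    u = rng.random(len(lengths))
    ci = (u[:, None] > cum).sum(axis=1)
    starts = (rng.random(len(lengths))
              * slots[np.arange(len(lengths)), ci]).astype(np.int64)
    return chrom_names[ci], starts


def permutation_overlap_test(
    a: RegionSet,
    b: RegionSet,
    n_perms: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Randomization test for the overlap of region set ``a`` with ``b``.

    Each permutation relocates every interval of ``a`` independently and
    uniformly over all valid placements in the genome (lengths preserved,
    placed regions may overlap each other); the statistic is the number of
    relocated intervals intersecting ``b``. One-sided (greater) empirical
    p = (#{permuted >= observed} + 1) / (n_perms + 1).
    """
    bounds = dict(a.genome_bounds or b.genome_bounds)
    if not bounds:
        raise ValueError("genome bounds are required for randomization")
    rng = np.random.default_rng(seed)
    lengths = (a.df["End"] - a.df["Start"]).to_numpy()
    chrom_names = np.array(list(bounds))
    chrom_lens = np.array([bounds[c] for c in chrom_names])
    if lengths.size and lengths.max() > chrom_lens.max():
        raise ValueError("an interval is longer than every chromosome")

    merged_b = _MergedIntervals(b)
    observed = merged_b.count_any_overlap(
        a.df["Chromosome"].to_numpy(), a.df["Start"].to_numpy(),
        a.df["End"].to_numpy(),
    )
    permuted = np.empty(n_perms, dtype=int)
    for i in range(n_perms):
        chroms, starts = randomize_placements(lengths, bounds, rng)
        permuted[i] = merged_b.count_any_overlap(chroms, starts, starts + lengths)
    p = (int((permuted >= observed).sum()) + 1) / (n_perms + 1)
    return PermutationResult(
        observed=observed, permuted=permuted, p_value=p,
        n_perms=n_perms, seed=seed,
    )


def build_promoters(gene_models: pd.DataFrame, upstream: int = 1000,
                    downstream: int = 200) -> pd.DataFrame:
    """Strand-aware promoter intervals around each TSS.

    ``gene_models`` is BED-like (Chromosome, Start, End, Strand); the TSS is
    Start for + genes and End - 1 for - genes (0-based). The promoter covers
    ``upstream`` bases before and ``downstream`` bases after the TSS in the
    direction of transcription, inclusive of the TSS base.
    """
    if "Strand" not in gene_models.columns or gene_models["Strand"].isna().any():
        raise ValueError("gene models must carry a strand")
    plus = gene_models["Strand"] == "+"
    tss = np.where(plus, gene_models["Start"], gene_models["End"] - 1)
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream + 1, tss + upstream + 1)
    return pd.DataFrame(
        {
            "Chromosome": gene_models["Chromosome"].to_numpy(),
            "Start": np.maximum(0, start),
            "End": end,
            "Strand": gene_models["Strand"].to_numpy(),
        }
    )


def annotate_regions(
    regions: RegionSet,
    gene_models: pd.DataFrame,
    enhancers: RegionSet,
    upstream: int = 1000,
    downstream: int = 200,
) -> tuple[pd.Series, dict[str, int]]:
    """Classify each region as promoter, enhancer or unannotated.

    The predicate is containment of the region's anchoring CpG point (the
    ``Center`` column when present, else the interval midpoint) within a
    promoter ([TSS-1000, TSS+200] in the transcription direction) or an
    enhancer; promoter takes precedence. Returns per-region classes plus
    class counts (which always sum to the number of regions).
    """
    promoters = build_promoters(gene_models, upstream, downstream)
    if "Center" in regions.df.columns:
        points = regions.df["Center"].to_numpy() - 1  # 1-based -> 0-based
    else:
        points = ((regions.df["Start"] + regions.df["End"] - 1) // 2).to_numpy()
    chroms = regions.df["Chromosome"].to_numpy()

    def contained(intervals: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(points), dtype=bool)
        for chrom, grp in intervals.groupby("Chromosome", observed=True):
            sel = chroms == chrom
            if not sel.any():
                continue
            grp = grp.sort_values("Start")
            s = grp["Start"].to_numpy()
            e = grp["End"].to_numpy()
            p = points[sel]
            j = np.searchsorted(np.maximum.accumulate(e), p, side="right")
            hit = np.zeros(p.size, dtype=bool)
            ok = j < len(s)
            hit[ok] = s[j[ok]] <= p[ok]
            out[sel] = hit
        return out

    cls = np.where(
        contained(promoters),
        "promoter",
        np.where(contained(enhancers.df), "enhancer", "unannotated"),
    )
    series = pd.Series(cls, index=regions.df.index, name="class")
    counts = {k: int(v) for k, v in series.value_counts().items()}
    for k in ("promoter", "enhancer", "unannotated"):
        counts.setdefault(k, 0)
    return series, counts
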