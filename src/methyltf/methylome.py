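"""Differential methylation over a time course of Infinium-style M-values.

The substrate is a probes x time-points matrix of M-values (log2 ratio of
methylated to unmethylated signal). A probe is called differentially
methylated between two time points when the M-value difference exceeds a
fixed threshold (default 2 M-units, strict inequality): methylated when
dM = M(later) - M(earlier) > threshold, demethylated when dM < -threshold.

"Uninherited" demethylated CpGs partition the cumulative demethylated sets
versus time 0 by the first time point at which each probe crosses the
threshold, so that each later set measures only newly demethylated probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

DEFAULT_DELTA_M = 2.0
_EPS = 1e-6


def beta_to_m(beta, eps: float = _EPS):
    """Convert beta values (methylated fraction) to M-values.

    M = log2(beta / (1 - beta)). Values in [0, 1] but outside (eps, 1-eps)
    are clipped with a warning; values outside [0, 1] raise.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("beta values must lie in [0, 1]")
    if np.any(arr < eps) or np.any(arr > 1 - eps):
        warnings.warn(f"beta values clipped to [{eps}, {1 - eps}]", stacklevel=2)
        arr = np.clip(arr, eps, 1 - eps)
    m = np.log2(arr / (1.0 - arr))
    return m if arr.ndim else float(m)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + np.exp2(-arr))
    return beta if arr.ndim else float(beta)


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV with columns probe_id, chrom, pos (1-based)."""
    df = pd.read_csv(path, sep="\t")
    return validate_manifest(df)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    required = {"probe_id", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        raise ValueError("manifest probe ids must be unique")
    if (df["pos"] < 1).any():
        raise ValueError("manifest positions are 1-based and must be >= 1")
    return df


def read_mvalues(path) -> pd.DataFrame:
    """Read an M-value matrix TSV (index: probe id, columns: time points)."""
    return pd.read_csv(path, sep="\t", index_col=0)


@dataclass(frozen=True)
class DifferentialCallSet:
    """Probes crossing the dM threshold between two time points."""

    interval: tuple[str, str]
    methylated: frozenset[str]
    demethylated: frozenset[str]
    threshold: float = DEFAULT_DELTA_M
    n_excluded: int = 0  # probes with missing values in either column

    def __post_init__(self):
        if self.methylated & self.demethylated:
            raise ValueError("a probe cannot be both methylated and demethylated")


@dataclass(frozen=True)
class UDRSet:
    """Probes first called demethylated (vs t0) at this time point."""

    timepoint: str
    probe_ids: frozenset[str] = field(default_factory=frozenset)


def call_differential_probes(
    mvalues: pd.DataFrame,
    t_earlier: str,
    t_later: str,
    threshold: float = DEFAULT_DELTA_M,
) -> DifferentialCallSet:
    """Call probes with |dM| > threshold between two time points.

    dM = M(t_later) - M(t_earlier). Strict inequalities on both sides;
    probes with a missing value at either time point are excluded and
    counted in ``n_excluded``.
    """
    for t in (t_earlier, t_later):
        if t not in mvalues.columns:
            raise KeyError(f"time point {t!r} not in M-value matrix")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    delta = mvalues[t_later] - mvalues[t_earlier]
    ok = delta.notna()
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} probes with missing M-values excluded from "
            f"interval ({t_earlier}, {t_later})",
            stacklevel=2,
        )
    delta = delta[ok]
    return DifferentialCallSet(
        interval=(t_earlier, t_later),
        methylated=frozenset(delta.index[delta > threshold]),
        demethylated=frozenset(delta.index[delta < -threshold]),
        threshold=threshold,
        n_excluded=n_excluded,
    )


def compute_uninherited_demethylated(
    mvalues: pd.DataFrame,
    t0: str,
    later_timepoints: list[str],
    threshold: float = DEFAULT_DELTA_M,
) -> list[UDRSet]:
    """Partition cumulative demethylated-vs-t0 sets by first crossing time.

    UDR(t_k) = Demeth(t0 -> t_k) minus the union of Demeth(t0 -> t_j) for
    all earlier j, so the sets are pairwise disjoint and their union up to
    t_k equals the union of the cumulative sets up to t_k.
    """
    if not later_timepoints:
        raise ValueError("need at least one later time point")
    order = list(mvalues.columns)
    idx = [order.index(t) for t in [t0, *later_timepoints]]
    if idx != sorted(idx):
        raise ValueError("time points must be given in matrix column order")
    seen: set[str] = set()
    udrs = []
    for t in later_timepoints:
        demeth = call_differential_probes(mvalues, t0, t, threshold).demethylated
        udrs.append(UDRSet(timepoint=t, probe_ids=frozenset(demeth - seen)))
        seen |= demeth
    return udrs


def sample_correlation_matrix(mvalues: pd.DataFrame):
    """Pairwise Pearson correlation of samples plus a dendrogram leaf order.

    Hierarchical clustering uses complete linkage on Euclidean distances
    between the columns of the correlation matrix. Zero-variance samples are
    flagged with a warning and yield NaN correlations.
    """
    if mvalues.shape[1] < 2:
        raise ValueError("need at least two samples")
    flat = mvalues.std(ddof=0) == 0
    if flat.any():
        warnings.warn(
            f"zero-variance samples (R undefined): {list(mvalues.columns[flat])}",
            stacklevel=2,
        )
    corr = mvalues.corr(method="pearson")
    filled = corr.fillna(0.0).to_numpy()
    z = linkage(filled, method="complete", metric="euclidean")
    order = [corr.columns[i] for i in leaves_list(z)]
    return corr, order
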