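"""The regulator screen: motif over-representation gated by TF expression.

For every interval of adjacent time points and both directions of
methylation change, the screen calls differential probes, scans sequence
windows around them with every PWM, contrasts hit counts against windows
around an equal number of randomly sampled non-differential probes with a
one-sided exact Poisson test, corrects across the motif library
(Benjamini-Hochberg within each interval x direction), and finally keeps
only TFs expressed at >= 50 TPM at either flanking time point — the
expression gate that separates the binding family member actually present
from relatives sharing its motif.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .methylome import DEFAULT_DELTA_M, call_differential_probes
from .motifs import (
    DEFAULT_HALF_WIDTH,
    DEFAULT_THRESHOLD_FRACTION,
    EnrichmentRecord,
    PWM,
    extract_probe_windows,
    poisson_overrepresentation,
    scan_windows,
)

DEFAULT_TPM_THRESHOLD = 50.0
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class RegulatorCall:
    """One (TF, interval, direction) cell with its pass/fail verdict."""

    tf_name: str
    interval: tuple[str, str]
    direction: str
    p_value: float
    q_value: float | None
    expressed_at: tuple[str, ...]
    passed: bool


def filter_by_expression(
    enrichments: Sequence[EnrichmentRecord],
    expression: pd.DataFrame,
    interval: tuple[str, str],
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    q_values: Mapping[str, float] | None = None,
) -> list[RegulatorCall]:
    """Gate enrichment records on TPM >= threshold at either flank.

    A TF passes when its (adjusted) p-value is <= ``alpha`` AND its
    expression reaches ``tpm_threshold`` (inclusive) at the earlier or the
    later flanking time point. TFs absent from the expression table fail
    with a warning.
    """
    t_lo, t_hi = interval
    for t in interval:
        if t not in expression.columns:
            raise ValueError(f"time point {t!r} missing from expression table")
    calls = []
    for rec in enrichments:
        if rec.tf_name not in expression.index:
            warnings.warn(f"TF {rec.tf_name!r} absent from expression table; fails",
                          stacklevel=2)
            expressed: tuple[str, ...] = ()
        else:
            row = expression.loc[rec.tf_name]
            expressed = tuple(t for t in (t_lo, t_hi) if row[t] >= tpm_threshold)
        q = None if q_values is None else float(q_values[rec.tf_name])
        crit = rec.p_value if q is None else q
        calls.append(
            RegulatorCall(
                tf_name=rec.tf_name,
                interval=interval,
                direction=rec.direction or "",
                p_value=rec.p_value,
                q_value=q,
                expressed_at=expressed,
                passed=bool(crit <= alpha and expressed),
            )
        )
    return calls


def _bh(pvals: np.ndarray) -> np.ndarray:
    return multipletests(pvals, method="fdr_bh")[1]


@dataclass
class ScreenResult:
    """Long-format cell table plus the passing calls and a clustered row order."""

    table: pd.DataFrame
    calls: list[RegulatorCall] = field(default_factory=list)
    tf_order: list[str] = field(default_factory=list)

    @property
    def passing(self) -> list[RegulatorCall]:
        return [c for c in self.calls if c.passed]


def screen_regulators(
    mvalues: pd.DataFrame,
    probes: pd.DataFrame,
    genome: Mapping[str, str],
    pwms: Sequence[PWM],
    expression: pd.DataFrame,
    intervals: Sequence[tuple[str, str]] | None = None,
    threshold: float = DEFAULT_DELTA_M,
    half_width: int = DEFAULT_HALF_WIDTH,
    scan_threshold: float = DEFAULT_THRESHOLD_FRACTION,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    use_fdr: bool = True,
    bg_draws: int = 1,
    seed: int = 0,
) -> ScreenResult:
    """Run the full methylation-regulating-TF screen.

    ``intervals`` defaults to all adjacent time-point pairs of the M-value
    matrix. For each interval and direction with a non-empty differential
    set, hit counts in +/-half_width windows around the differential CpGs
    are tested against windows around an equal-size seeded random sample of
    non-differential probes (averaged over ``bg_draws`` draws). Cells with
    an empty differential set are recorded as not testable (p = NaN), not
    as p = 1. With ``use_fdr`` the pass criterion applies BH-adjusted
    q-values across the motif library within each interval x direction.
    """
    timepoints = list(mvalues.columns)
    if intervals is None:
        intervals = list(zip(timepoints[:-1], timepoints[1:]))
    rng = np.random.default_rng(seed)
    rows = []
    all_calls: list[RegulatorCall] = []
    for interval in intervals:
        callset = call_differential_probes(mvalues, *interval, threshold)
        for direction in ("methylated", "demethylated"):
            target_ids = getattr(callset, direction)
            if not target_ids:
                for pwm in pwms:
                    rows.append((pwm.tf_name, interval[0], interval[1], direction,
                                 np.nan, np.nan, np.nan, False, False))
                continue
            target_probes = probes[probes["probe_id"].isin(target_ids)]
            target_windows = extract_probe_windows(target_probes, genome, half_width)
            pool = probes[~probes["probe_id"].isin(
                callset.methylated | callset.demethylated)]
            n_bg = min(len(target_probes), len(pool))
            if n_bg == 0:
                warnings.warn(
                    f"no background probes for {interval} {direction}", stacklevel=2)
                continue
            bg_window_sets = []
            for _ in range(max(1, bg_draws)):
                bg_probes = pool.sample(
                    n=n_bg, random_state=int(rng.integers(0, 2**31)))
                bg_window_sets.append(
                    extract_probe_windows(bg_probes, genome, half_width))
            records = []
            for pwm in pwms:
                observed = len(scan_windows(target_windows, pwm, scan_threshold))
                bg_mean = float(np.mean(
                    [len(scan_windows(ws, pwm, scan_threshold))
                     for ws in bg_window_sets]))
                records.append(
                    poisson_overrepresentation(
                        observed, bg_mean, len(target_windows), n_bg,
                        tf_name=pwm.tf_name, interval=tuple(interval),
                        direction=direction,
                    )
                )
            qvals = dict(zip(
                [r.tf_name for r in records],
                _bh(np.array([r.p_value for r in records])),
            )) if use_fdr else None
            calls = filter_by_expression(
                records, expression, tuple(interval), tpm_threshold,
                alpha=alpha, q_values=qvals,
            )
            all_calls.extend(calls)
            for rec, call in zip(records, calls):
                rows.append((rec.tf_name, interval[0], interval[1], direction,
                             rec.observed, rec.lam, rec.p_value,
                             bool(call.expressed_at), call.passed))
    table = pd.DataFrame(
        rows,
        columns=["tf_name", "t_earlier", "t_later", "direction",
                 "observed", "lambda", "p_value", "expressed", "passed"],
    )
    return ScreenResult(table=table, calls=all_calls,
                        tf_order=_cluster_tfs(table))


def _cluster_tfs(table: pd.DataFrame) -> list[str]:
    """Order TFs by complete-linkage clustering of -log10 p profiles."""
    wide = table.pivot_table(
        index="tf_name", columns=["t_earlier", "t_later", "direction"],
        values="p_value", sort=False,
    )
    if wide.shape[0] < 3:
        return list(wide.index)
    profiles = -np.log10(wide.clip(lower=1e-300)).fillna(0.0).to_numpy()
    z = linkage(profiles, method="complete", metric="euclidean")
    return [wide.index[i] for i in leaves_list(z)]
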