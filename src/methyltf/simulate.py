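"""Synthetic multi-omics data with planted ground truth.

The generator emulates the statistical structure of a differentiation
time course in which one "driver" transcription factor switches on
mid-course and demethylates the DNA around its binding sites: a random
genome carries planted consensus instances of the driver motif; CpG probes
sit either near a planted site (these start hypermethylated and lose more
than two M-units across the course, beginning at the driver's onset) or in
background (constant mean plus Gaussian noise); the driver's expression
steps from ``tpm_off`` to ``tpm_on`` at onset while decoy TFs stay below
the screening threshold. Every output is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .motifs import PWM

DEFAULT_TIMEPOINT_PREFIX = "t"
_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the regime the screen is designed for: a driver
    whose adjacent probes drop 4 M-units from a +3 baseline across a
    six-point course with 0.3 M-unit noise, and a 0 -> 300 TPM expression
    step at the onset time point.
    """

    genome_length: int = 1_000_000
    gc_content: float = 0.41  # human-like base composition
    n_probes: int = 120
    n_timepoints: int = 6
    driver_motif: str = "GATA6"
    n_planted_sites: int = 25
    demeth_effect: float = 4.0  # M-units lost over the full course
    noise_sd: float = 0.3
    driver_onset: int = 2  # time-point index at which the driver switches on
    tpm_on: float = 300.0
    tpm_off: float = 0.0
    seed: int = 0
    chrom: str = "chr1"
    near_fraction: float = 0.5  # fraction of probes placed near planted sites
    near_distance: int = 500
    baseline_m: float = 3.0

    def __post_init__(self):
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if not 0 < self.gc_content <= 1:
            raise ValueError("gc_content must be in (0, 1]")
        if self.demeth_effect <= 0:
            raise ValueError("demeth_effect must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("n_probes", "n_timepoints", "n_planted_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.driver_onset < self.n_timepoints - 1:
            raise ValueError("driver_onset must leave at least one later time point")
        if not 0 < self.near_fraction <= 1:
            raise ValueError("near_fraction must be in (0, 1]")

    @property
    def timepoints(self) -> list[str]:
        return [f"{DEFAULT_TIMEPOINT_PREFIX}{i}" for i in range(self.n_timepoints)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def default_pwms(driver: str = "GATA6") -> list[PWM]:
    """The driver motif plus non-planted decoy motifs.

    Each PWM puts probability 0.85 on the consensus base and 0.05
    elsewhere, a sharp but not degenerate motif. The decoys (AP-1-, E-box-
    and NF-Y-like consensi) are never planted, so their window hits arise
    only from the random genome background.
    """
    consensi = {
        "GATA6": "AGATAAGATC",
        "AP1": "ATGACTCATC",
        "EBOX": "GACACGTGTC",
        "NFY": "TAGCCAATCA",
    }
    if driver not in consensi:
        consensi = {driver: consensi["GATA6"], **{k: v for k, v in consensi.items() if k != "GATA6"}}
    pwms = []
    for name, cons in consensi.items():
        mat = np.full((len(cons), 4), 0.05)
        for i, base in enumerate(cons):
            mat[i, "ACGT".index(base)] = 0.85
        pwms.append(PWM(name, mat, pseudocount=0.0))
    return pwms


def generate_genome(config: SimConfig) -> dict[str, str]:
    """I.i.d. random genome with expected GC fraction ``gc_content``."""
    rng = np.random.default_rng(config.seed)
    at = (1.0 - config.gc_content) / 2.0
    gc = config.gc_content / 2.0
    draws = rng.choice(4, size=config.genome_length, p=[at, gc, gc, at])
    return {config.chrom: "".join(_BASES[draws])}


def plant_motif_instances(
    genome: dict[str, str],
    pwm: PWM,
    n_sites: int,
    seed: int = 0,
    max_tries: int = 10_000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Overwrite ``n_sites`` non-overlapping loci with the PWM consensus.

    Half the sites (on average) receive the reverse complement and are
    recorded as minus-strand. Returns the modified genome and a BED6-style
    site table (0-based half-open coordinates).
    """
    (chrom, seq), = genome.items()
    length = pwm.length
    if n_sites * length > len(seq) / 10:
        raise ValueError("requested sites would occupy >10% of the genome")
    rng = np.random.default_rng(seed)
    if n_sites == 0:
        return dict(genome), pd.DataFrame(
            columns=["Chromosome", "Start", "End", "Name", "Score", "Strand"])
    starts: list[int] = []
    for _ in range(max_tries):
        cand = int(rng.integers(0, len(seq) - length + 1))
        if all(abs(cand - s) >= length for s in starts):
            starts.append(cand)
            if len(starts) == n_sites:
                break
    else:
        raise RuntimeError("could not place non-overlapping motif sites")
    starts.sort()
    strands = np.where(rng.random(n_sites) < 0.5, "+", "-")
    consensus = pwm.consensus
    rc = consensus.translate(_COMP)[::-1]
    arr = list(seq)
    for start, strand in zip(starts, strands):
        arr[start:start + length] = consensus if strand == "+" else rc
    sites = pd.DataFrame(
        {
            "Chromosome": chrom,
            "Start": starts,
            "End": [s + length for s in starts],
            "Name": [f"site_{i}" for i in range(n_sites)],
            "Score": 0,
            "Strand": strands,
        }
    )
    return {chrom: "".join(arr)}, sites


def make_probe_manifest(config: SimConfig, sites: pd.DataFrame) -> pd.DataFrame:
    """CpG probe positions: ``near_fraction`` near planted sites, rest background.

    Near probes land within ``near_distance`` of a planted site's midpoint;
    background probes are resampled until they are farther than that from
    every site, guaranteeing two clean populations.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_near = int(round(config.n_probes * config.near_fraction))
    n_far = config.n_probes - n_near
    mids = ((sites["Start"] + sites["End"]) // 2).to_numpy()
    positions = []
    for i in range(n_near):
        mid = mids[i % len(mids)]
        offset = int(rng.integers(-config.near_distance, config.near_distance + 1))
        positions.append(int(np.clip(mid + offset, 0, config.genome_length - 1)) + 1)
    placed = 0
    while placed < n_far:
        pos0 = int(rng.integers(0, config.genome_length))
        if len(mids) == 0 or np.abs(mids - pos0).min() > config.near_distance:
            positions.append(pos0 + 1)
            placed += 1
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:06d}" for i in range(config.n_probes)],
            "chrom": config.chrom,
            "pos": positions,
        }
    )


def probe_site_distance(probes: pd.DataFrame, sites: pd.DataFrame) -> np.ndarray:
    """Distance from each CpG to the nearest planted-site midpoint."""
    if len(sites) == 0:
        return np.full(len(probes), np.inf)
    mids = ((sites["Start"] + sites["End"]) // 2).to_numpy()
    pos0 = probes["pos"].to_numpy() - 1
    return np.abs(pos0[:, None] - mids[None, :]).min(axis=1)


def simulate_methylome_timecourse(
    config: SimConfig,
    probes: pd.DataFrame,
    sites: pd.DataFrame,
) -> pd.DataFrame:
    """M-value trajectories: driver-adjacent probes demethylate, rest drift.

    Probes within ``near_distance`` of a planted site start at
    ``baseline_m`` and decline linearly by ``demeth_effect`` between the
    onset time point and the course end; all other probes keep a constant
    per-probe mean. I.i.d. Gaussian noise (sd ``noise_sd``) is added to
    every probe and time point.
    """
    if (probes["pos"] > config.genome_length).any() or (probes["pos"] < 1).any():
        raise ValueError("probes outside genome bounds")
    rng = np.random.default_rng(config.seed + 2)
    n, t = len(probes), config.n_timepoints
    near = probe_site_distance(probes, sites) <= config.near_distance
    means = np.empty((n, t))
    background_level = rng.normal(0.0, 2.0, size=n)
    ramp = np.clip(
        (np.arange(t) - config.driver_onset) / (t - 1 - config.driver_onset),
        0.0, 1.0,
    )
    means[near] = config.baseline_m - config.demeth_effect * ramp
    means[~near] = background_level[~near, None]
    noise = rng.normal(0.0, config.noise_sd, size=(n, t)) if config.noise_sd else 0.0
    return pd.DataFrame(
        means + noise, index=probes["probe_id"], columns=config.timepoints
    )


def simulate_expression_table(config: SimConfig, tf_names: list[str]) -> pd.DataFrame:
    """TPM table: the driver steps from tpm_off to tpm_on at onset.

    Decoy TFs get a constant expression drawn once per TF below the
    screening threshold of 50 TPM.
    """
    if config.driver_motif not in tf_names:
        raise ValueError("driver TF must be among tf_names")
    rng = np.random.default_rng(config.seed + 3)
    rows = []
    for name in tf_names:
        if name == config.driver_motif:
            row = np.where(np.arange(config.n_timepoints) >= config.driver_onset,
                           config.tpm_on, config.tpm_off)
        else:
            row = np.full(config.n_timepoints, float(rng.uniform(0.0, 40.0)))
        rows.append(row)
    return pd.DataFrame(rows, index=tf_names, columns=config.timepoints)


def simulate_read_coverage(
    sites: pd.DataFrame,
    genome_bounds: dict[str, int],
    background_rate: float = 0.0,
    reads_per_site: int = 0,
    read_length: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """BED-style reads piling on planted sites over uniform background.

    ``background_rate`` is the expected number of background reads per
    base of genome. Site reads start uniformly within one read length of
    the site midpoint, clamped to contig bounds.
    """
    if background_rate < 0 or reads_per_site < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for row in sites.itertuples(index=False):
        bound = genome_bounds[row.Chromosome]
        mid = (row.Start + row.End) // 2
        for _ in range(reads_per_site):
            start = int(mid - read_length + rng.integers(0, read_length + 1))
            start = int(np.clip(start, 0, bound - read_length))
            rows.append((row.Chromosome, start, start + read_length))
    for chrom, bound in genome_bounds.items():
        n_bg = rng.poisson(background_rate * bound)
        for start in rng.integers(0, max(1, bound - read_length), size=n_bg):
            rows.append((chrom, int(start), int(start) + read_length))
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])


def simulate_study(config: SimConfig):
    """Generate the full linked dataset: genome with planted driver sites,
    probe manifest, M-value course, and TF expression table.

    Returns a dict with keys genome, sites, probes, mvalues, expression,
    pwms — the inputs the regulator screen consumes.
    """
    pwms = default_pwms(config.driver_motif)
    driver = next(p for p in pwms if p.tf_name == config.driver_motif)
    genome = generate_genome(config)
    genome, sites = plant_motif_instances(
        genome, driver, config.n_planted_sites, seed=config.seed)
    probes = make_probe_manifest(config, sites)
    mvalues = simulate_methylome_timecourse(config, probes, sites)
    expression = simulate_expression_table(config, [p.tf_name for p in pwms])
    return {
        "genome": genome,
        "sites": sites,
        "probes": probes,
        "mvalues": mvalues,
        "expression": expression,
        "pwms": pwms,
    }
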