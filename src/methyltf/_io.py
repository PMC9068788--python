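"""Small readers/writers for the plain-text formats used across the package.

FASTA goes through Biopython; tabular formats (BED, TSV matrices,
chromosome sizes) through pandas. All genomic intervals on disk are BED-style
0-based half-open; probe positions in manifests are 1-based base coordinates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["Chromosome", "Start", "End", "Name", "Score", "Strand"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a dict of uppercase sequences keyed by contig."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED6 file; returns a DataFrame with BED6-style column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bases."""
    df = pd.read_csv(path, sep="\t", header=None, names=["Chromosome", "Length"])
    return dict(zip(df["Chromosome"], df["Length"].astype(int)))


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
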