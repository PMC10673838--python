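"""Plain-text I/O helpers: FASTA, bedGraph, TSV, YAML configs.

All genomic coordinates are 0-based, half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "read_tsv",
    "write_tsv",
    "load_config",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Expand a 4-column bedGraph into dense per-base arrays."""
    track = {c: np.zeros(int(n), dtype=float) for c, n in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
                     comment="#", dtype={"chrom": str})
    for row in df.itertuples(index=False):
        if row.chrom not in track:
            raise ValueError(f"bedGraph chrom {row.chrom!r} absent from chrom_sizes")
        track[row.chrom][int(row.start):int(row.end)] += float(row.value)
    return track


def write_bedgraph(track: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Run-length encode dense per-base arrays to bedGraph; zero runs are skipped."""
    with open(path, "w") as fh:
        for chrom in track:
            arr = np.asarray(track[chrom], dtype=float)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for a, b in zip(starts, ends):
                v = arr[a]
                if v != 0:
                    fh.write(f"{chrom}\t{a}\t{b}\t{v:g}\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
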