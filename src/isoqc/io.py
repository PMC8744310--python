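"""Flat-file helpers shared by the CLI pipeline."""

from __future__ import annotations

import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
]


def read_fasta(path) -> dict[str, str]:
    with Fasta(str(path), rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_design(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_design(design: pd.Series, path) -> None:
    design.rename("condition").to_frame().rename_axis("sample").to_csv(
        path, sep="\t"
    )
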