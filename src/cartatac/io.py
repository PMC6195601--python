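"""Readers and writers for the plain-text formats the pipeline exchanges.

BED files are tab-separated, headerless, 0-based half-open; ``track`` and
``browser`` lines and ``#`` comments are skipped.  Genome files are two-column
chrom/size TSV.  Everything else is headered TSV read through pandas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import GenomeModel, as_intervals

_BED_SKIP = ("track", "browser", "#")


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6; returns chrom/start/end (+ id when a name column exists)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(_BED_SKIP):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line: {line!r}")
            rows.append(parts[:4] if len(parts) >= 4 else parts[:3])
    if not rows:
        return as_intervals([])
    ncol = max(len(r) for r in rows)
    cols = ["chrom", "start", "end", "id"][:ncol]
    df = pd.DataFrame([r + [None] * (ncol - len(r)) for r in rows], columns=cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["id"] if "id" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_genome(sizes_path, gaps_path=None, autosomes=None) -> GenomeModel:
    sizes = pd.read_csv(sizes_path, sep="\t", header=None, names=["chrom", "size"],
                        dtype={"chrom": str})
    gaps = read_bed(gaps_path) if gaps_path else as_intervals([])
    return GenomeModel(chromosomes=tuple(zip(sizes["chrom"], sizes["size"])),
                       gaps=gaps, autosomes=tuple(autosomes or ()))


def write_genome(genome: GenomeModel, sizes_path, gaps_path=None) -> None:
    pd.DataFrame(genome.chromosomes).to_csv(sizes_path, sep="\t", header=False, index=False)
    if gaps_path is not None:
        write_bed(genome.gaps, gaps_path)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    """Count matrix TSV: first column feature id, remaining columns = samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise ValueError(f"{path}: non-numeric count columns")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=True, index_label="feature")
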