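"""Readers and writers for the plain-text formats used by the pipeline.

Coordinate convention: everything in memory is 0-based half-open.  Reads are
BED6-style TSV (chrom, start, end, read_id, score, strand); call and gene
tables are headered TSV; density tracks are written as bedGraph or two-column
TSV.  Tables exported from 1-based inclusive spreadsheets can be converted on
ingestion with ``one_based=True``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .density import DensityMap

__all__ = [
    "read_reads",
    "read_calls",
    "read_genes",
    "read_chrom_sizes",
    "write_table",
    "write_bedgraph",
    "write_density_tsv",
    "write_profile",
]

READ_COLUMNS = ["chrom", "start", "end", "read_id", "score", "strand"]


def read_reads(path, one_based: bool = False) -> pd.DataFrame:
    """Strand-resolved reads from BED6-style TSV (no header).

    Also accepts the 5-column layout (chrom, start, end, strand, read_id).
    ``one_based=True`` converts 1-based inclusive coordinates to 0-based
    half-open.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 6:
        df.columns = READ_COLUMNS
    elif df.shape[1] == 5:
        df.columns = ["chrom", "start", "end", "strand", "read_id"]
        df["score"] = 1
        df = df[READ_COLUMNS]
    else:
        raise ValueError(f"expected 5 or 6 columns in read table, got {df.shape[1]}")
    if one_based:
        df["start"] = df["start"] - 1
    return df


def read_calls(path, one_based: bool = False) -> pd.DataFrame:
    """Nucleosome calls: headered TSV with chrom, dyad, fuzziness."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"chrom", "dyad", "fuzziness"} - set(df.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    if one_based:
        df["dyad"] = df["dyad"] - 1
    return df


def read_genes(path, one_based: bool = False) -> pd.DataFrame:
    """Gene table: headered TSV with feature_id, chrom, strand, tss, orf_end."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"feature_id", "chrom", "strand", "tss", "orf_end"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    if one_based:
        df["tss"] = df["tss"] - 1
        df["orf_end"] = df["orf_end"] - 1
    return df


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column chromosome-sizes file (chrom, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], comment="#")
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_table(df: pd.DataFrame, path, header: bool = True, comment: str | None = None):
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, header=header)


def write_bedgraph(density: DensityMap, path, comment: str | None = None):
    """Density as bedGraph (0-based half-open runs of equal value; zeros skipped)."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for chrom in sorted(density.tracks):
            t = density.tracks[chrom]
            # run-length encode
            change = np.flatnonzero(np.diff(t) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(t)]])
            for s, e in zip(starts, ends):
                v = t[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def write_density_tsv(density: DensityMap, path, comment: str | None = None):
    """Density as TSV (chrom, coordinate, weight), nonzero sites only."""
    frames = []
    for chrom in sorted(density.tracks):
        t = density.tracks[chrom]
        nz = np.flatnonzero(t)
        frames.append(pd.DataFrame({"chrom": chrom, "coord": nz, "weight": t[nz]}))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "coord", "weight"]
    )
    write_table(out, path, comment=comment)


def write_profile(profile, path, comment: str | None = None):
    """AlignedProfile as TSV (offset, mean_weight, n_genes)."""
    df = pd.DataFrame(
        {
            "offset": profile.offsets,
            "mean_weight": profile.mean_weight,
            "n_genes": profile.n_genes,
        }
    )
    write_table(df, path, comment=comment)
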