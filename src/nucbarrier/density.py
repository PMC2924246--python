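"""Per-bp proxies for nucleosome density.

Two proxies are built from the two kinds of experimental table:

* the *read density* map -- each aligned read contributes weight at the
  putative midpoint of its nucleosomal fragment, with multi-mapping reads
  down-weighted by the reciprocal of their alignment count, so every
  sequenced molecule carries total weight 1;
* the *call density* map -- each called nucleosome contributes a unit-mass
  discretized Gaussian centered at its dyad, with sigma equal to its
  "fuzziness" (the positional standard deviation across cells).

Coordinates are 0-based half-open internally; 1-based inclusive tables are
converted on ingestion by the readers in :mod:`nucbarrier.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["DensityMap", "reads_to_density", "calls_to_density", "cross_normalize"]


@dataclass
class DensityMap:
    """Per-chromosome nonnegative weight per bp."""

    tracks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_weight(self) -> float:
        return float(sum(t.sum() for t in self.tracks.values()))

    def scaled(self, factor: float) -> "DensityMap":
        return DensityMap({c: t * factor for c, t in self.tracks.items()})

    def __add__(self, other: "DensityMap") -> "DensityMap":
        out = {c: t.copy() for c, t in self.tracks.items()}
        for c, t in other.tracks.items():
            if c in out:
                n = max(len(out[c]), len(t))
                merged = np.zeros(n)
                merged[: len(out[c])] += out[c]
                merged[: len(t)] += t
                out[c] = merged
            else:
                out[c] = t.copy()
        return DensityMap(out)


def _track_sizes(chrom_sizes, frame: pd.DataFrame, end_col: str, pad: int) -> dict[str, int]:
    if chrom_sizes is not None:
        return dict(chrom_sizes)
    sizes: dict[str, int] = {}
    for chrom, sub in frame.groupby("chrom", sort=False):
        sizes[chrom] = int(sub[end_col].max()) + pad
    return sizes


def reads_to_density(
    reads: pd.DataFrame, b: int = 147, chrom_sizes: dict[str, int] | None = None
) -> DensityMap:
    """Weighted read-midpoint density from a strand-resolved read table.

    The fragment midpoint is ``start + (b-1)/2`` for Watson ('+') reads and
    ``end - 1 - (b-1)/2`` for Crick ('-') reads (0-based coordinates); each
    alignment adds ``1 / n_alignments`` there, where ``n_alignments`` counts
    rows sharing the read identifier.  The total weight equals the number of
    distinct reads.  Rows with an unknown strand are dropped with a warning.
    """
    if b % 2 == 0:
        raise ValueError(f"b must be odd for a well-defined midpoint, got {b}")
    h = (b - 1) // 2
    known = reads["strand"].isin(["+", "-"])
    if not known.all():
        logger.warning("dropping %d reads with unknown strand", (~known).sum())
        reads = reads[known]
    sizes = _track_sizes(chrom_sizes, reads, "end", pad=b)
    weights = 1.0 / reads.groupby("read_id")["read_id"].transform("size").to_numpy()
    mid = np.where(
        reads["strand"].to_numpy() == "+",
        reads["start"].to_numpy() + h,
        reads["end"].to_numpy() - 1 - h,
    )
    tracks = {c: np.zeros(n) for c, n in sizes.items()}
    chroms = reads["chrom"].to_numpy()
    for c in tracks:
        sel = chroms == c
        np.add.at(tracks[c], mid[sel].astype(np.int64), weights[sel])
    return DensityMap(tracks)


def calls_to_density(
    calls: pd.DataFrame,
    sd_floor: float = 1.0,
    chrom_sizes: dict[str, int] | None = None,
) -> DensityMap:
    """Density from called nucleosomes: one unit-mass Gaussian per call.

    Each call contributes a discretized Gaussian at its dyad with
    ``sigma = max(fuzziness, sd_floor)``, truncated at +/- 6 sigma and
    renormalized to unit mass (truncation loses < 1e-8 before
    renormalization).  Mass clipped at a chromosome edge is renormalized
    onto the remaining sites with a warning.  Total weight equals the number
    of calls.
    """
    if sd_floor < 0:
        raise ValueError("sd_floor must be >= 0")
    sizes = _track_sizes(chrom_sizes, calls.assign(end=calls["dyad"]), "end", pad=1000)
    tracks = {c: np.zeros(n) for c, n in sizes.items()}
    clipped = 0
    for chrom, dyad, fuzz in zip(calls["chrom"], calls["dyad"], calls["fuzziness"]):
        track = tracks[chrom]
        sigma = max(float(fuzz), sd_floor, 1e-12)
        w = int(np.ceil(6 * sigma))
        lo, hi = int(dyad) - w, int(dyad) + w
        if lo < 0 or hi >= len(track):
            clipped += 1
        lo_c, hi_c = max(lo, 0), min(hi, len(track) - 1)
        grid = np.arange(lo_c, hi_c + 1)
        mass = np.exp(-0.5 * ((grid - float(dyad)) / sigma) ** 2)
        track[lo_c : hi_c + 1] += mass / mass.sum()
    if clipped:
        logger.warning(
            "%d calls near chromosome edges: clipped Gaussians renormalized", clipped
        )
    return DensityMap(tracks)


def cross_normalize(read_map: DensityMap, call_map: DensityMap) -> float:
    """Scale factor making the read map's genome-wide total equal the call map's.

    Multiplying the read map by the returned factor matches total read
    weight to the total number of called nucleosomes, putting both proxies
    on a common scale.
    """
    rt, ct = read_map.total_weight, call_map.total_weight
    if rt <= 0 or ct <= 0:
        raise ValueError("both maps must have positive total weight")
    return ct / rt
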