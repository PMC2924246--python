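"""Anchor finding, strand-oriented metagene alignment, and gene subsets.

The quantitative signature fitted by :mod:`nucbarrier.fitting` is the
average density around the nucleosomes flanking promoter NFRs: per gene the
+1 nucleosome is the first call at or downstream from the TSS and the -1
nucleosome the first call strictly upstream (both in transcription
coordinates); the density map is then extracted around each anchor,
oriented with transcription left to right, and averaged with equal weight
per gene.  Analogous anchors at the ORF end probe the 3' NFR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import DensityMap

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedProfile",
    "find_flanking",
    "align_average",
    "position_distributions",
    "subset_genes",
]


@dataclass
class AlignedProfile:
    """Gene-averaged density vs. signed offset from an anchor.

    ``offsets`` run over [-window, window], oriented with transcription left
    to right; ``mean_weight[i]`` averages only the ``n_genes[i]`` genes whose
    chromosome covers that offset.
    """

    offsets: np.ndarray
    mean_weight: np.ndarray
    n_genes: np.ndarray
    anchor_kind: str = "plus1"

    def value_at(self, x) -> np.ndarray:
        """Mean weight at signed offset(s) x (must lie within the window)."""
        idx = np.asarray(x) - self.offsets[0]
        return self.mean_weight[np.asarray(idx, dtype=int)]

    def mirrored(self) -> "AlignedProfile":
        return AlignedProfile(
            offsets=self.offsets.copy(),
            mean_weight=self.mean_weight[::-1].copy(),
            n_genes=self.n_genes[::-1].copy(),
            anchor_kind=self.anchor_kind,
        )


def find_flanking(
    genes: pd.DataFrame, calls: pd.DataFrame, at: str = "tss"
) -> pd.DataFrame:
    """Per-gene +1/-1 anchor dyads relative to the TSS (or the ORF end).

    ``at="tss"``: +1 = first call at or downstream from the TSS, -1 = first
    call strictly upstream, in transcription coordinates.  ``at="orf_end"``
    mirrors the definitions at the 3' end: -1 = call at or upstream of the
    ORF end, +1 = first call strictly downstream.  Missing anchors are NaN
    (the gene is excluded from that alignment, logged), not errors.
    """
    if at not in ("tss", "orf_end"):
        raise ValueError(f"at must be 'tss' or 'orf_end', got {at!r}")
    dyads_by_chrom = {
        c: np.sort(sub["dyad"].to_numpy(dtype=float))
        for c, sub in calls.groupby("chrom", sort=False)
    }
    plus1 = np.full(len(genes), np.nan)
    minus1 = np.full(len(genes), np.nan)
    anchor_col = "tss" if at == "tss" else "orf_end"
    for i, (chrom, strand, a) in enumerate(
        zip(genes["chrom"], genes["strand"], genes[anchor_col])
    ):
        dy = dyads_by_chrom.get(chrom)
        if dy is None or len(dy) == 0:
            continue
        if strand == "+":
            # downstream = larger coordinates
            j = np.searchsorted(dy, a, side="left")  # first dyad >= a
            down_incl = dy[j] if j < len(dy) else np.nan
            j2 = np.searchsorted(dy, a, side="right")
            down_excl = dy[j2] if j2 < len(dy) else np.nan
            k = np.searchsorted(dy, a, side="left") - 1  # last dyad < a
            up_excl = dy[k] if k >= 0 else np.nan
            k2 = np.searchsorted(dy, a, side="right") - 1  # last dyad <= a
            up_incl = dy[k2] if k2 >= 0 else np.nan
        else:
            # downstream = smaller coordinates
            j = np.searchsorted(dy, a, side="right") - 1  # last dyad <= a
            down_incl = dy[j] if j >= 0 else np.nan
            j2 = np.searchsorted(dy, a, side="left") - 1
            down_excl = dy[j2] if j2 >= 0 else np.nan
            k = np.searchsorted(dy, a, side="right")  # first dyad > a
            up_excl = dy[k] if k < len(dy) else np.nan
            k2 = np.searchsorted(dy, a, side="left")
            up_incl = dy[k2] if k2 < len(dy) else np.nan
        if at == "tss":
            plus1[i], minus1[i] = down_incl, up_excl
        else:  # 3' end: the inclusive side is upstream
            plus1[i], minus1[i] = down_excl, up_incl
    missing = int(np.isnan(plus1).sum() + np.isnan(minus1).sum())
    if missing:
        logger.info("%d missing flanking anchors across %d genes", missing, len(genes))
    out = genes[["feature_id", "chrom", "strand"]].copy()
    out["plus1"] = plus1
    out["minus1"] = minus1
    return out


def align_average(
    density: DensityMap,
    anchors: pd.DataFrame,
    window: int = 2000,
    anchor_col: str = "plus1",
    anchor_kind: str | None = None,
) -> AlignedProfile:
    """Equal-per-gene average of the density around strand-oriented anchors.

    For each gene the density at ``anchor + offset`` (Watson) or
    ``anchor - offset`` (Crick) is collected for offsets in
    [-window, window]; offsets outside the chromosome are excluded from that
    offset's denominator.  Genes with a missing anchor contribute nothing.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    offsets = np.arange(-window, window + 1)
    total = np.zeros(len(offsets))
    count = np.zeros(len(offsets), dtype=int)
    used = 0
    for chrom, strand, a in zip(
        anchors["chrom"], anchors["strand"], anchors[anchor_col]
    ):
        if not np.isfinite(a):
            continue
        track = density.tracks.get(chrom)
        if track is None:
            continue
        a = int(a)
        coords = a + offsets if strand == "+" else a - offsets
        valid = (coords >= 0) & (coords < len(track))
        total[valid] += track[coords[valid]]
        count[valid] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable anchors")
    mean = np.divide(total, count, out=np.zeros_like(total), where=count > 0)
    return AlignedProfile(
        offsets=offsets,
        mean_weight=mean,
        n_genes=count,
        anchor_kind=anchor_kind or anchor_col,
    )


def position_distributions(
    genes: pd.DataFrame, calls: pd.DataFrame, b: int = 147
) -> dict[str, np.ndarray]:
    """Signed +1/-1-to-TSS distances and the -1/+1 edge-to-edge gap, per gene.

    Distances are in transcription coordinates (positive = downstream); the
    gap is the dyad separation minus one footprint, so touching nucleosomes
    have gap 0.  NaNs mark genes with a missing anchor.  Histograms can be
    formed with :func:`numpy.histogram(..., density=True)`.
    """
    fl = find_flanking(genes, calls)
    s = np.where(genes["strand"].to_numpy() == "+", 1, -1)
    tss = genes["tss"].to_numpy(dtype=float)
    d_plus = s * (fl["plus1"].to_numpy() - tss)
    d_minus = s * (fl["minus1"].to_numpy() - tss)
    gap = s * (fl["plus1"].to_numpy() - fl["minus1"].to_numpy()) - b
    return {"plus1_to_tss": d_plus, "minus1_to_tss": d_minus, "gap": gap}


def subset_genes(
    genes: pd.DataFrame, mode: str, calls: pd.DataFrame | None = None
):
    """Gene subsets used for robustness checks of the averaged profiles.

    mode:
        ``"all"`` -- unchanged;
        ``"long2000"`` -- genes strictly longer than 2000 bp;
        ``"clean_upstream1000"`` -- genes with no other gene's TSS or ORF end
        within 1000 bp upstream of the TSS (transcription coordinates);
        ``"three_prime"`` -- anchors re-derived at the ORF end (requires
        ``calls``); returns the anchor table instead of a gene subset.
    """
    if mode == "all":
        return genes
    if mode == "long2000":
        length = (genes["orf_end"] - genes["tss"]).abs()
        return genes[length > 2000]
    if mode == "clean_upstream1000":
        keep = np.ones(len(genes), dtype=bool)
        pts_by_chrom = {}
        for c, sub in genes.groupby("chrom", sort=False):
            pts_by_chrom[c] = np.sort(
                np.concatenate(
                    [sub["tss"].to_numpy(dtype=float), sub["orf_end"].to_numpy(dtype=float)]
                )
            )
        for i, (fid, chrom, strand, tss) in enumerate(
            zip(genes["feature_id"], genes["chrom"], genes["strand"], genes["tss"])
        ):
            pts = pts_by_chrom[chrom]
            lo, hi = (tss - 1000, tss) if strand == "+" else (tss, tss + 1000)
            inside = pts[(pts >= lo) & (pts <= hi)]
            # discount this gene's own TSS
            n_own = int(np.sum(inside == tss))
            if len(inside) - n_own > 0:
                keep[i] = False
        return genes[keep]
    if mode == "three_prime":
        if calls is None:
            raise ValueError("mode 'three_prime' requires the call table")
        return find_flanking(genes, calls, at="orf_end")
    raise ValueError(f"unknown subset mode {mode!r}")
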