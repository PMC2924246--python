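"""Synthetic nucleosome cohorts with the statistical structure the analysis assumes.

Generates, on a synthetic chromosome:

* exact canonical hard-rod ("Tonks") configurations (:func:`sample_tonks`),
  including the pinned-origin variant that serves as the Monte-Carlo oracle
  for the analytic barrier density;
* a gene cohort in which every gene has a nucleosome-free region flanked by
  a +1 nucleosome (~50 bp downstream of the TSS) and a -1 nucleosome, each
  side governed by a configurable boundary scenario -- ``direct`` (a pinned
  boundary nucleosome) or ``indirect`` (a repelling edge with the first
  nucleosome free);
* MNase-seq-like paired-strand reads with Poisson coverage, positional
  jitter and a controlled fraction of multi-mapping reads;
* nucleosome-call and gene tables matching the reader schemas of the
  analysis modules, plus a truth table for blind parameter-recovery tests.

Away from a boundary the realized arrays are a renewal process with
exponential gaps (mean ``dbar - b``), which is the exact thermodynamic-limit
Tonks gas, so gene-averaged profiles converge to the analytic density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .lattice import continuum_fugacity

__all__ = [
    "SyntheticConfig",
    "Configuration",
    "AnnotationSet",
    "SyntheticCohort",
    "sample_tonks",
    "sample_tonks_batch",
    "generate_annotations",
    "generate_reads",
    "simulate_cohort",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the conditions of the analysis this package quantifies:
    2000 genes, 147-bp nucleosomes at 177-bp mean spacing, a +1 nucleosome
    about 50 bp downstream of the TSS, an NFR gap of ~140 bp, about 6 reads
    per nucleosome, and a log-normal gene-length law with roughly a third of
    genes longer than 2000 bp.
    """

    seed: int = 0
    n_genes: int = 2000
    b: int = 147
    dbar: float = 177.0
    dbar_genic: float | None = None  # defaults to dbar
    dbar_intergenic: float | None = None  # defaults to dbar
    chrom: str = "chrSim"
    chrom_length: int | None = None  # derived from gene territories if None
    n_cells: int = 8  # independent configurations pooled per cohort
    flank_bp: int = 3000
    plus1_offset_mean: float = 50.0
    plus1_offset_sd: float = 20.0
    minus1_dispersion: float = 25.0
    gap_mean: float = 140.0
    reads_per_nucleosome_mean: float = 6.0
    read_jitter_sd: float = 10.0
    multimap_fraction: float = 0.05
    multimap_copies: int = 3
    gene_length_mu: float = 7.24  # log of bp; ~third of genes > 2000 bp
    gene_length_sigma: float = 0.85
    gene_length_min: int = 400
    scenario_plus: str = "direct"
    scenario_minus: str = "indirect"

    def __post_init__(self) -> None:
        if self.b % 2 == 0 or self.b <= 0:
            raise ValueError("b must be a positive odd integer")
        for name in ("dbar", "flank_bp", "gap_mean", "reads_per_nucleosome_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dbar <= self.b:
            raise ValueError("dbar must exceed b")
        if not 0.0 <= self.multimap_fraction <= 1.0:
            raise ValueError("multimap_fraction must lie in [0, 1]")
        if self.multimap_fraction > 0 and self.multimap_copies < 2:
            raise ValueError("multimap_copies must be >= 2 when multimapping is on")
        if self.read_jitter_sd < 0:
            raise ValueError("read_jitter_sd must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("scenario_plus", "scenario_minus"):
            if getattr(self, name) not in ("direct", "indirect"):
                raise ValueError(f"{name} must be 'direct' or 'indirect'")

    @property
    def ell_genic(self) -> float:
        return (self.dbar_genic or self.dbar) - self.b

    @property
    def ell_intergenic(self) -> float:
        return (self.dbar_intergenic or self.dbar) - self.b

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class Configuration:
    """One realized hard-rod configuration: sorted midpoints on a chromosome."""

    chrom: str
    dyads: np.ndarray
    b: float

    def __post_init__(self) -> None:
        self.dyads = np.sort(np.asarray(self.dyads, dtype=float))

    def min_gap(self) -> float:
        """Smallest center-to-center spacing; >= b iff no rods overlap."""
        if len(self.dyads) < 2:
            return np.inf
        return float(np.min(np.diff(self.dyads)))


@dataclass
class AnnotationSet:
    genes: pd.DataFrame
    calls: pd.DataFrame
    truth: pd.DataFrame
    configurations: list[Configuration]

    @property
    def configuration(self) -> Configuration:
        """First cell's configuration (each cell is a valid configuration)."""
        return self.configurations[0]


@dataclass
class SyntheticCohort:
    genes: pd.DataFrame
    calls: pd.DataFrame
    truth: pd.DataFrame
    configurations: list[Configuration]
    reads: pd.DataFrame
    config: SyntheticConfig

    @property
    def configuration(self) -> Configuration:
        return self.configurations[0]


# ---------------------------------------------------------------------------
# exact canonical sampling


def sample_tonks(
    L: float,
    N: int,
    b: float,
    fixed_origin: bool = False,
    rng: np.random.Generator | None = None,
    chrom: str = "chrSim",
) -> Configuration:
    """Exact canonical sample of N hard rods of width b in a length-L interval.

    Rods map to a point gas on an interval of length ``L - N b``: N sorted
    uniform points plus ``k*b`` shifts give the rod left edges, making every
    admissible configuration equally likely.  With ``fixed_origin`` one rod's
    midpoint is pinned at 0 and the remaining N-1 rods are sampled to its
    right -- the pinned-barrier ensemble whose binned midpoint histogram is
    the Monte-Carlo oracle for the analytic barrier density.
    """
    rng = rng or np.random.default_rng()
    if N * b > L:
        raise ValueError(f"infeasible packing: N*b = {N * b} exceeds L = {L}")
    free = L - N * b
    if fixed_origin:
        if N < 1:
            raise ValueError("fixed_origin requires N >= 1")
        u = np.sort(rng.uniform(0.0, free, size=N - 1))
        rest = b + u + np.arange(N - 1) * b
        dyads = np.concatenate([[0.0], rest])
    else:
        u = np.sort(rng.uniform(0.0, free, size=N))
        left = u + np.arange(N) * b
        dyads = left + b / 2.0
    return Configuration(chrom=chrom, dyads=dyads, b=b)


def sample_tonks_batch(
    L: float,
    N: int,
    b: float,
    n_configs: int,
    rng: np.random.Generator | None = None,
    chunk: int = 20000,
) -> np.ndarray:
    """Distances of the N-1 free rods from a pinned origin rod, for many replicates.

    Vectorized version of ``sample_tonks(..., fixed_origin=True)`` returning
    an (n_configs, N-1) array of midpoint distances; used to histogram the
    density next to a perfect barrier at Monte-Carlo scale.
    """
    rng = rng or np.random.default_rng()
    if N * b > L:
        raise ValueError(f"infeasible packing: N*b = {N * b} exceeds L = {L}")
    free = L - N * b
    shifts = b + np.arange(N - 1) * b
    out = np.empty((n_configs, N - 1))
    for start in range(0, n_configs, chunk):
        stop = min(start + chunk, n_configs)
        u = rng.uniform(0.0, free, size=(stop - start, N - 1))
        u.sort(axis=1)
        out[start:stop] = u + shifts
    return out


# ---------------------------------------------------------------------------
# cohort construction


def _sample_segment(
    mid_left: float,
    mid_right: float,
    b: float,
    z: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact grand-canonical hard-rod sample between two boundary rods.

    Boundary rods have midpoints at ``mid_left`` and ``mid_right``; interior
    rods map to a point gas with free length F_N = D - (N+1) b, so the
    particle number follows P(N) proportional to z^N F_N^N / N! and, given
    N, positions are sorted uniforms.  This is the exact equilibrium of the
    gas at fugacity z conditioned on the two boundaries -- no truncation or
    censoring artifacts.
    """
    D = mid_right - mid_left
    n_max = int(np.floor(D / b)) - 1
    if n_max < 1:
        return np.empty(0)
    n_arr = np.arange(0, n_max + 1)
    F = D - (n_arr + 1) * b
    with np.errstate(divide="ignore"):
        logw = n_arr * np.log(z) + n_arr * np.where(F > 0, np.log(F), -np.inf) - gammaln(n_arr + 1)
    logw[0] = 0.0
    p = np.exp(logw - logw.max())
    p /= p.sum()
    N = int(rng.choice(n_arr, p=p))
    if N == 0:
        return np.empty(0)
    u = np.sort(rng.uniform(0.0, F[N], size=N))
    return mid_left + b + u + np.arange(N) * b


def generate_annotations(
    sc: SyntheticConfig, rng: np.random.Generator | None = None
) -> AnnotationSet:
    """Gene table, nucleosome-call table, truth record and realized configuration.

    Genes are laid head-to-tail on one synthetic chromosome, each in its own
    territory of ``flank + gene length + flank`` bp, alternating strands.
    Per gene the +1 call is drawn near TSS + plus1_offset_mean and the -1
    call one footprint plus an NFR gap upstream; gene bodies and flanks are
    then filled with hard-rod arrays against these boundaries according to
    the per-side scenario.  Calls are emitted at the modal position of each
    nucleosome slot (what an idealized peak detector recovers); fuzziness is
    filled in from reads by :func:`simulate_cohort` (placeholder here).
    """
    rng = rng or sc.rng()
    b = float(sc.b)
    dbar_g = sc.dbar_genic or sc.dbar
    dbar_i = sc.dbar_intergenic or sc.dbar
    inhomogeneous = dbar_g != dbar_i
    z_g = continuum_fugacity(b, dbar_g)
    z_i = continuum_fugacity(b, dbar_i)

    gene_rows, call_rows, truth_rows = [], [], []
    genic_intervals: list[tuple[float, float]] = []
    territories: list[tuple[float, float]] = []
    # boundary rods along the chromosome: (midpoint, realized, nfr_on_right)
    rods: list[tuple[float, bool, bool]] = [(-b, False, False)]
    cursor = 0.0
    for g in range(sc.n_genes):
        glen = max(
            sc.gene_length_min,
            int(round(float(rng.lognormal(sc.gene_length_mu, sc.gene_length_sigma)))),
        )
        territory = 2 * sc.flank_bp + glen
        t0, t1 = cursor, cursor + territory
        cursor = t1
        territories.append((t0, t1))
        strand = "+" if g % 2 == 0 else "-"
        s = 1 if strand == "+" else -1
        if s > 0:
            tss, orf_end = t0 + sc.flank_bp, t0 + sc.flank_bp + glen
        else:
            tss, orf_end = t1 - sc.flank_bp, t1 - sc.flank_bp - glen
        lo_g, hi_g = min(tss, orf_end), max(tss, orf_end)
        genic_intervals.append((lo_g, hi_g))

        # the +1 nucleosome is by definition at or downstream of the TSS
        plus1 = tss + s * max(
            0.0, round(rng.normal(sc.plus1_offset_mean, sc.plus1_offset_sd))
        )
        gap = max(0.0, round(rng.normal(sc.gap_mean, sc.minus1_dispersion)))
        minus1 = plus1 - s * (b + gap)

        # lower/upper anchors in chromosome coordinates; an indirect anchor
        # is a repelling edge, represented by a virtual rod displaced one
        # footprint into the NFR (it bounds the outer array exactly like a
        # wall at the anchor, with the modal first dyad at the anchor)
        if s > 0:
            lower, lower_scen = minus1, sc.scenario_minus
            upper, upper_scen = plus1, sc.scenario_plus
        else:
            lower, lower_scen = plus1, sc.scenario_plus
            upper, upper_scen = minus1, sc.scenario_minus
        lower_rod = lower if lower_scen == "direct" else lower + b
        upper_rod = upper if upper_scen == "direct" else upper - b
        if inhomogeneous:
            # a positioned nucleosome at the ORF end demarcates the genic
            # and intergenic spacing regimes (a 3'-boundary rod)
            if s > 0:
                rods.append((lower_rod, lower_scen == "direct", True))
                rods.append((upper_rod, upper_scen == "direct", False))
                rods.append((float(orf_end), True, False))
            else:
                rods.append((float(orf_end), True, False))
                rods.append((lower_rod, lower_scen == "direct", True))
                rods.append((upper_rod, upper_scen == "direct", False))
        else:
            rods.append((lower_rod, lower_scen == "direct", True))
            rods.append((upper_rod, upper_scen == "direct", False))

        # calls: anchors at the modal boundary positions, then one call per
        # expected downstream/upstream peak of the average pattern
        gene_calls = [plus1, minus1]
        limit_down = t1 - b / 2 if s > 0 else t0 + b / 2
        limit_up = t0 + b / 2 if s > 0 else t1 - b / 2
        pos = plus1
        while True:
            step = dbar_g if lo_g <= pos + s * b <= hi_g else dbar_i
            pos = pos + s * step
            if s * (limit_down - pos) <= 0:
                break
            gene_calls.append(round(pos))
        pos = minus1
        while True:
            pos = pos - s * dbar_i
            if s * (pos - limit_up) <= 0:
                break
            gene_calls.append(round(pos))

        fid = f"SYN{g:05d}"
        gene_rows.append((fid, sc.chrom, strand, int(tss), int(orf_end)))
        for dyad in gene_calls:
            call_rows.append((sc.chrom, int(dyad), float(sc.read_jitter_sd)))
        truth_rows.append(
            [
                fid, strand, sc.scenario_plus, sc.scenario_minus,
                int(plus1), int(minus1), float(gap), int(glen),
                float(dbar_g), float(dbar_i), 0,
            ]
        )

    chrom_length = int(np.ceil(cursor)) + sc.b
    rods.append((chrom_length + b, False, False))

    # exact grand-canonical sample of every inter-boundary segment, once per
    # cell (boundaries are fixed on the genome; the arrays between them vary
    # from cell to cell); NFR segments between a gene's two anchors stay empty
    genic_starts = np.array([iv[0] for iv in genic_intervals])
    genic_ends = np.array([iv[1] for iv in genic_intervals])

    def _is_genic(pos: float) -> bool:
        j = int(np.searchsorted(genic_starts, pos, side="right")) - 1
        return j >= 0 and pos <= genic_ends[j]

    realized_rods = [m for m, realized, _ in rods if realized]
    segment_z = []
    for (m_l, _, nfr_right), (m_r, _, _) in zip(rods[:-1], rods[1:]):
        if nfr_right:
            segment_z.append(None)
        else:
            segment_z.append(z_g if _is_genic(0.5 * (m_l + m_r)) else z_i)

    configurations: list[Configuration] = []
    for _cell in range(sc.n_cells):
        cell_dyads = list(realized_rods)
        if sc.n_genes:
            for (m_l, _, _), (m_r, _, _), z in zip(rods[:-1], rods[1:], segment_z):
                if z is None:
                    continue
                cell_dyads.extend(_sample_segment(m_l, m_r, b, z, rng).tolist())
        configurations.append(
            Configuration(chrom=sc.chrom, dyads=np.array(cell_dyads), b=b)
        )

    if sc.n_genes:
        dy_sorted = configurations[0].dyads
        for row, (t0, t1) in zip(truth_rows, territories):
            row[10] = int(
                np.searchsorted(dy_sorted, t1) - np.searchsorted(dy_sorted, t0)
            )
    if sc.chrom_length is not None:
        if sc.chrom_length < chrom_length:
            raise ValueError(
                f"chrom_length={sc.chrom_length} cannot hold the cohort "
                f"(needs >= {chrom_length})"
            )
        chrom_length = sc.chrom_length

    genes = pd.DataFrame(
        gene_rows, columns=["feature_id", "chrom", "strand", "tss", "orf_end"]
    )
    calls = (
        pd.DataFrame(call_rows, columns=["chrom", "dyad", "fuzziness"])
        .sort_values(["chrom", "dyad"], kind="stable")
        .reset_index(drop=True)
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "feature_id", "strand", "scenario_plus", "scenario_minus",
            "plus1_dyad", "minus1_dyad", "gap", "gene_length",
            "dbar_genic", "dbar_intergenic", "n_nucleosomes",
        ],
    )
    truth.attrs["chrom_length"] = chrom_length
    return AnnotationSet(
        genes=genes, calls=calls, truth=truth, configurations=configurations
    )


def generate_reads(
    config: Configuration, sc: SyntheticConfig, rng: np.random.Generator | None = None,
    chrom_length: int | None = None,
    rate: float | None = None,
    read_prefix: str = "r",
) -> pd.DataFrame:
    """MNase-seq-like reads from a realized configuration (BED6-style table).

    Per nucleosome the read count is Poisson with mean ``rate`` (defaulting
    to the config's reads_per_nucleosome_mean); each read's midpoint is the
    true dyad plus rounded Gaussian jitter, the strand is a fair coin, and
    the read spans exactly one footprint (b bp, 0-based half-open), so the
    midpoint arithmetic of the density module is exact.  A configured
    fraction of reads is emitted as several rows sharing one read identifier
    at displaced positions, emulating multi-mapping.  ``read_prefix`` keeps
    identifiers unique when reads from several configurations are pooled.
    """
    rng = rng or sc.rng()
    b = int(sc.b)
    h = (b - 1) // 2
    dyads = np.asarray(config.dyads)
    if chrom_length is None:
        chrom_length = int(np.max(dyads)) + b if len(dyads) else b
    if rate is None:
        rate = sc.reads_per_nucleosome_mean
    counts = rng.poisson(rate, size=len(dyads))
    src = np.repeat(np.round(dyads).astype(np.int64), counts)
    n = len(src)
    jitter = np.round(rng.normal(0.0, sc.read_jitter_sd, size=n)).astype(np.int64)
    mid = np.clip(src + jitter, h, chrom_length - h - 1)
    strands = np.where(rng.integers(0, 2, size=n) == 0, "+", "-")
    read_id = np.array([f"{read_prefix}{i:08d}" for i in range(n)])

    starts = mid - h
    ends = mid + h + 1
    frames = [
        pd.DataFrame(
            {
                "chrom": config.chrom,
                "start": starts,
                "end": ends,
                "read_id": read_id,
                "score": 1,
                "strand": strands,
            }
        )
    ]
    if sc.multimap_fraction > 0 and n > 0:
        n_multi = int(round(sc.multimap_fraction * n))
        idx = rng.choice(n, size=n_multi, replace=False)
        extra = sc.multimap_copies - 1
        # secondary alignments of nucleosomal fragments fall at other
        # nucleosome-protected loci (repeated DNA is packaged too), not
        # uniformly on the genome
        decoy_src = np.round(
            dyads[rng.integers(0, len(dyads), size=n_multi * extra)]
        ).astype(np.int64)
        decoy_jit = np.round(
            rng.normal(0.0, sc.read_jitter_sd, size=n_multi * extra)
        ).astype(np.int64)
        decoy_mid = np.clip(decoy_src + decoy_jit, h, chrom_length - h - 1)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": config.chrom,
                    "start": decoy_mid - h,
                    "end": decoy_mid + h + 1,
                    "read_id": np.repeat(read_id[idx], extra),
                    "score": 1,
                    "strand": np.where(
                        rng.integers(0, 2, size=n_multi * extra) == 0, "+", "-"
                    ),
                }
            )
        )
    reads = pd.concat(frames, ignore_index=True)
    return reads


def simulate_cohort(
    sc: SyntheticConfig, rng: np.random.Generator | None = None
) -> SyntheticCohort:
    """Full synthetic cohort: annotations, reads, and empirical call fuzziness.

    Reads are pooled over the cohort's ``n_cells`` configurations (boundary
    anchors fixed on the genome, arrays resampled per cell), each cell
    contributing Poisson reads at 1/n_cells of the per-nucleosome rate --
    the cell-population averaging of an MNase-seq experiment.  Fuzziness of
    each call is the standard deviation of the pooled read midpoints within
    half a footprint of it (what a caller would measure); calls with fewer
    than two nearby reads keep the configured jitter sd.
    """
    rng = rng or sc.rng()
    ann = generate_annotations(sc, rng)
    chrom_length = ann.truth.attrs["chrom_length"]
    per_cell_rate = sc.reads_per_nucleosome_mean / sc.n_cells
    reads = pd.concat(
        [
            generate_reads(
                cfg_cell, sc, rng, chrom_length=chrom_length,
                rate=per_cell_rate, read_prefix=f"c{i}_",
            )
            for i, cfg_cell in enumerate(ann.configurations)
        ],
        ignore_index=True,
    )

    h = (sc.b - 1) // 2
    mids = np.sort((reads["start"] + h).to_numpy())
    calls = ann.calls.copy()
    fuzz = np.full(len(calls), float(sc.read_jitter_sd))
    half = sc.b // 2
    dy = calls["dyad"].to_numpy()
    lo = np.searchsorted(mids, dy - half, side="left")
    hi = np.searchsorted(mids, dy + half, side="right")
    for i in range(len(calls)):
        if hi[i] - lo[i] >= 2:
            fuzz[i] = float(np.std(mids[lo[i] : hi[i]], ddof=1))
    calls["fuzziness"] = np.maximum(fuzz, 0.0)

    return SyntheticCohort(
        genes=ann.genes,
        calls=calls,
        truth=ann.truth,
        configurations=ann.configurations,
        reads=reads,
        config=sc,
    )
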