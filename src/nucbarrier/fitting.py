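"""Least-squares fitting of the hard-rod barrier model to aligned profiles.

The fitted function is ``f(x) = A * rho(x - x0)`` with ``rho`` the analytic
density next to a perfect barrier (footprint b fixed at 147 bp), free
parameters the normalization A, the horizontal offset x0 and the mean
spacing dbar, and the squared deviation per data point as the score.  The
offset's basin classifies the boundary condition: |x0| < b/2 means the
boundary nucleosome is itself the barrier ("direct" positioning), an offset
near -b means the array is positioned against a repelling region with the
first nucleosome free ("indirect" statistical positioning).

Each fit is restarted many times (default 300) from randomized starting
points, since the score has one deep basin per boundary scenario; -1-side
profiles are mirrored at the origin before fitting so the same model form
applies to both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .density import DensityMap
from .profiles import AlignedProfile, find_flanking
from .tonks import FitModelParams, TonksParams, fit_model, normalize_kernel

__all__ = [
    "FitConfig",
    "FitResult",
    "ScenarioFit",
    "SCENARIO_PAIRS",
    "fit_profile",
    "fit_convolved",
    "fit_minus_fixed",
    "simultaneous_fit",
    "compare_scenarios",
    "density_ratio",
]

#: The four boundary-condition pairs for simultaneous +1/-1 fits.
SCENARIO_PAIRS = {
    "A": ("direct", "direct"),
    "B": ("indirect", "direct"),
    "C": ("direct", "indirect"),
    "D": ("indirect", "indirect"),
}


@dataclass(frozen=True)
class FitConfig:
    """Fitting protocol parameters."""

    fit_range: tuple[int, int] = (200, 2000)
    n_starts: int = 300
    seed: int = 0
    b: float = 147.0
    a_factor_range: tuple[float, float] = (0.2, 5.0)  # times data-matched A
    x0_range: tuple[float, float] = (-220.0, 220.0)
    dbar_range: tuple[float, float] = (150.0, 250.0)
    basin_halfwidth: float = 30.0  # spread of x0 starts around a basin center
    conv_window: int = 80

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not self.fit_range[0] < self.fit_range[1]:
            raise ValueError("fit_range must be increasing")


@dataclass
class FitResult:
    A: float
    x0: float
    dbar: float
    chi2: float  # mean squared deviation per data point
    scenario: str  # "direct" | "indirect"
    converged: bool
    n_restarts: int = 0
    basin: str = "free"


@dataclass
class ScenarioFit:
    A: float
    dbar: float
    x0_plus: float
    x0_minus: float
    chi2: float  # joint mean squared deviation per data point
    scenario_pair: str
    converged: bool


def _classify(x0: float, b: float) -> str:
    return "direct" if abs(x0) < b / 2 else "indirect"


def _extract(profile: AlignedProfile, fit_range, mirror: bool):
    """Data (x, y) on the fit range; mirrored profiles read negative offsets."""
    x = np.arange(fit_range[0], fit_range[1] + 1)
    src = -x if mirror else x
    idx = src - profile.offsets[0]
    if idx.min() < 0 or idx.max() >= len(profile.offsets):
        raise ValueError("profile window does not cover the fit range")
    return x.astype(float), profile.mean_weight[idx]


def _model_grid(x, A, x0, dbar, b):
    p = FitModelParams(A=A, x0=x0, tonks=TonksParams(b=b, dbar=dbar))
    return fit_model(x, p)


def _x0_starts(basin: str, n: int, cfg: FitConfig, rng) -> np.ndarray:
    hw = cfg.basin_halfwidth
    if basin == "direct":
        return rng.uniform(-hw, hw, n)
    if basin == "indirect":
        return rng.uniform(-cfg.b - hw, -cfg.b + hw, n)
    if basin == "free":
        return rng.uniform(*cfg.x0_range, n)
    raise ValueError(f"unknown basin {basin!r}")


def _x0_bounds(basin: str, cfg: FitConfig) -> tuple[float, float]:
    """Offset bounds imposing a boundary scenario (basins split at |x0| = b/2)."""
    if basin == "direct":
        return (-cfg.b / 2, cfg.b / 2)
    if basin == "indirect":
        return (-1.5 * cfg.b, -cfg.b / 2)
    return (min(cfg.x0_range[0], -cfg.b - 80.0), cfg.x0_range[1] + 80.0)


def _is_degenerate(y: np.ndarray) -> bool:
    m = float(np.mean(y))
    return m <= 0 or float(np.std(y)) < 1e-6 * max(m, 1.0)


def fit_profile(
    profile: AlignedProfile,
    cfg: FitConfig = FitConfig(),
    basin: str = "free",
    mirror: bool = False,
) -> FitResult:
    """Multi-start least-squares fit of ``A * rho(x - x0)`` to a profile.

    ``basin`` seeds the offset starts near 0 ("direct"), near -b
    ("indirect"), or across the whole range ("free").  ``mirror`` fits a
    -1-side profile after mirroring it at the origin.  Flat profiles are
    returned as non-converged (dbar is unidentifiable there).
    """
    x, y = _extract(profile, cfg.fit_range, mirror)
    if _is_degenerate(y):
        return FitResult(np.nan, np.nan, np.nan, np.nan, "direct", False, 0, basin)
    rng = np.random.default_rng(cfg.seed)
    n = len(x)
    data_mean = float(np.mean(y))

    def resid(theta):
        return _model_grid(x, theta[0], theta[1], theta[2], cfg.b) - y

    best = None
    x0s = _x0_starts(basin, cfg.n_starts, cfg, rng)
    x0_lo, x0_hi = _x0_bounds(basin, cfg)
    x0s = np.clip(x0s, x0_lo, x0_hi)
    dbars = rng.uniform(*cfg.dbar_range, cfg.n_starts)
    afacs = rng.uniform(*cfg.a_factor_range, cfg.n_starts)
    lb = [1e-12, x0_lo, cfg.b + 2.0]
    ub = [np.inf, x0_hi, max(400.0, cfg.dbar_range[1] + 50)]
    for i in range(cfg.n_starts):
        a0 = afacs[i] * data_mean * dbars[i]  # A matching the data asymptote
        theta0 = [max(a0, 1e-9), x0s[i], dbars[i]]
        try:
            sol = least_squares(resid, theta0, bounds=(lb, ub), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all restarts failed to converge")
    A, x0, dbar = best.x
    chi2 = float(np.mean(resid(best.x) ** 2))
    return FitResult(
        A=float(A), x0=float(x0), dbar=float(dbar), chi2=chi2,
        scenario=_classify(x0, cfg.b), converged=bool(best.success),
        n_restarts=cfg.n_starts, basin=basin,
    )


def empirical_kernel(profile: AlignedProfile, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-mass kernel from the profile in a +/-w window around the anchor.

    Captures the residual positional spread of the boundary nucleosome
    (e.g. the finite width of the +1 peak) for the convolved model.
    """
    offs = np.arange(-w, w + 1)
    idx = offs - profile.offsets[0]
    if idx.min() < 0 or idx.max() >= len(profile.offsets):
        raise ValueError("profile window does not cover the kernel window")
    masses = profile.mean_weight[idx]
    if masses.sum() <= 0:
        raise ValueError("empty kernel region")
    return normalize_kernel((offs, masses))


def fit_convolved(
    profile: AlignedProfile,
    cfg: FitConfig = FitConfig(),
    mirror: bool = False,
) -> FitResult:
    """Fit of the model convolved with the empirical boundary-peak shape.

    The kernel is the profile itself in [-w, +w] around offset 0, rescaled
    to unit mass; the offset x0 is fixed at 0 because the kernel already
    carries the peak location, leaving (A, dbar) free.
    """
    if not 0 <= cfg.conv_window <= cfg.fit_range[0]:
        raise ValueError("conv_window must lie within [0, fit_range start]")
    offs, masses = empirical_kernel(profile, cfg.conv_window)
    x, y = _extract(profile, cfg.fit_range, mirror)
    if _is_degenerate(y):
        return FitResult(np.nan, 0.0, np.nan, np.nan, "direct", False, 0, "direct")
    rng = np.random.default_rng(cfg.seed)
    data_mean = float(np.mean(y))

    # evaluate the model once on an extended grid, then convolve:
    # (f * k)(x) = sum_j k(j) f(x - j) with j in [offs[0], offs[-1]]
    x_ext = np.arange(x[0] - offs[-1], x[-1] - offs[0] + 1, dtype=float)

    def model(theta):
        f = _model_grid(x_ext, theta[0], 0.0, theta[1], cfg.b)
        # convolve's built-in flip makes this exactly sum_j masses(j) f(x - j)
        return np.convolve(f, masses, mode="valid")

    def resid(theta):
        return model(theta) - y

    best = None
    dbars = rng.uniform(*cfg.dbar_range, cfg.n_starts)
    afacs = rng.uniform(*cfg.a_factor_range, cfg.n_starts)
    for i in range(cfg.n_starts):
        theta0 = [max(afacs[i] * data_mean * dbars[i], 1e-9), dbars[i]]
        try:
            sol = least_squares(
                resid, theta0,
                bounds=([1e-12, cfg.b + 2.0], [np.inf, max(400.0, cfg.dbar_range[1] + 50)]),
                method="trf",
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all restarts failed to converge")
    chi2 = float(np.mean(resid(best.x) ** 2))
    return FitResult(
        A=float(best.x[0]), x0=0.0, dbar=float(best.x[1]), chi2=chi2,
        scenario="direct", converged=bool(best.success),
        n_restarts=cfg.n_starts, basin="direct",
    )


def fit_minus_fixed(
    profile_minus: AlignedProfile,
    A_fixed: float,
    dbar_fixed: float,
    cfg: FitConfig = FitConfig(),
) -> FitResult:
    """Offset-only fit to the mirrored -1 alignment.

    Normalization and spacing are carried over from the +1 fit; only x0 is
    optimized, multi-start from both boundary basins (centers 0 and -b).
    """
    x, y = _extract(profile_minus, cfg.fit_range, mirror=True)
    if _is_degenerate(y):
        return FitResult(A_fixed, np.nan, dbar_fixed, np.nan, "direct", False, 0, "free")
    rng = np.random.default_rng(cfg.seed)

    def resid(theta):
        return _model_grid(x, A_fixed, theta[0], dbar_fixed, cfg.b) - y

    n_half = max(cfg.n_starts // 2, 1)
    starts = np.concatenate(
        [_x0_starts("direct", n_half, cfg, rng), _x0_starts("indirect", n_half, cfg, rng)]
    )
    best = None
    for x00 in starts:
        sol = least_squares(
            resid, [x00],
            bounds=([-cfg.b - 80.0], [cfg.b + 80.0]),
            method="trf",
        )
        if best is None or sol.cost < best.cost:
            best = sol
    x0 = float(best.x[0])
    return FitResult(
        A=A_fixed, x0=x0, dbar=dbar_fixed, chi2=float(np.mean(resid(best.x) ** 2)),
        scenario=_classify(x0, cfg.b), converged=bool(best.success),
        n_restarts=len(starts), basin="free",
    )


def simultaneous_fit(
    profile_plus: AlignedProfile,
    profile_minus: AlignedProfile,
    scenario_pair: str,
    cfg: FitConfig = FitConfig(),
) -> ScenarioFit:
    """Joint fit to the +1 and mirrored -1 alignments under one boundary pair.

    A and dbar are shared between the two sides; x0_plus and x0_minus are
    free but seeded in the basins named by ``scenario_pair`` (see
    :data:`SCENARIO_PAIRS`).  chi2 is the joint mean squared deviation per
    data point over both sides.
    """
    if scenario_pair not in SCENARIO_PAIRS:
        raise ValueError(f"scenario_pair must be one of {sorted(SCENARIO_PAIRS)}")
    basin_p, basin_m = SCENARIO_PAIRS[scenario_pair]
    xp, yp = _extract(profile_plus, cfg.fit_range, mirror=False)
    xm, ym = _extract(profile_minus, cfg.fit_range, mirror=True)
    if _is_degenerate(yp) or _is_degenerate(ym):
        return ScenarioFit(np.nan, np.nan, np.nan, np.nan, np.nan, scenario_pair, False)
    rng = np.random.default_rng(cfg.seed)
    data_mean = float(np.mean(np.concatenate([yp, ym])))

    def resid(theta):
        A, dbar, x0p, x0m = theta
        return np.concatenate(
            [
                _model_grid(xp, A, x0p, dbar, cfg.b) - yp,
                _model_grid(xm, A, x0m, dbar, cfg.b) - ym,
            ]
        )

    best = None
    dbars = rng.uniform(*cfg.dbar_range, cfg.n_starts)
    afacs = rng.uniform(*cfg.a_factor_range, cfg.n_starts)
    bp_lo, bp_hi = _x0_bounds(basin_p, cfg)
    bm_lo, bm_hi = _x0_bounds(basin_m, cfg)
    x0ps = np.clip(_x0_starts(basin_p, cfg.n_starts, cfg, rng), bp_lo, bp_hi)
    x0ms = np.clip(_x0_starts(basin_m, cfg.n_starts, cfg, rng), bm_lo, bm_hi)
    lb = [1e-12, cfg.b + 2.0, bp_lo, bm_lo]
    ub = [np.inf, max(400.0, cfg.dbar_range[1] + 50), bp_hi, bm_hi]
    for i in range(cfg.n_starts):
        theta0 = [
            max(afacs[i] * data_mean * dbars[i], 1e-9), dbars[i], x0ps[i], x0ms[i],
        ]
        try:
            sol = least_squares(resid, theta0, bounds=(lb, ub), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all restarts failed to converge")
    A, dbar, x0p, x0m = best.x
    chi2 = float(np.mean(resid(best.x) ** 2))
    return ScenarioFit(
        A=float(A), dbar=float(dbar), x0_plus=float(x0p), x0_minus=float(x0m),
        chi2=chi2, scenario_pair=scenario_pair, converged=bool(best.success),
    )


def compare_scenarios(
    profile_plus: AlignedProfile,
    profile_minus: AlignedProfile,
    cfg: FitConfig = FitConfig(),
) -> dict[str, ScenarioFit]:
    """All four simultaneous boundary-pair fits, keyed by scenario letter."""
    return {
        pair: simultaneous_fit(profile_plus, profile_minus, pair, cfg)
        for pair in SCENARIO_PAIRS
    }


def density_ratio(
    density: DensityMap,
    genes: pd.DataFrame,
    calls: pd.DataFrame,
) -> float:
    """Mean intergenic over mean genic density per bp, NFRs excluded.

    Genic bp are the union of [TSS, ORF end] intervals; intergenic bp the
    complement on each chromosome; the interval between each gene's -1 and
    +1 dyads (the NFR and its flanking rods' inner edges) is excluded from
    the intergenic average so promoter depletion does not bias the ratio.
    """
    fl = find_flanking(genes, calls)
    ratios_num = 0.0
    num_bp = 0
    ratios_den = 0.0
    den_bp = 0
    for chrom, track in density.tracks.items():
        n = len(track)
        genic = np.zeros(n, dtype=bool)
        nfr = np.zeros(n, dtype=bool)
        sub = genes[genes["chrom"] == chrom]
        if sub.empty:
            continue
        for tss, orf_end in zip(sub["tss"], sub["orf_end"]):
            lo, hi = int(min(tss, orf_end)), int(max(tss, orf_end))
            genic[max(lo, 0) : min(hi + 1, n)] = True
        fsub = fl[fl["chrom"] == chrom]
        for p1, m1 in zip(fsub["plus1"], fsub["minus1"]):
            if np.isfinite(p1) and np.isfinite(m1):
                lo, hi = int(min(p1, m1)), int(max(p1, m1))
                nfr[max(lo, 0) : min(hi + 1, n)] = True
        inter = ~genic & ~nfr
        ratios_num += float(track[inter].sum())
        num_bp += int(inter.sum())
        gen_only = genic & ~nfr
        ratios_den += float(track[gen_only].sum())
        den_bp += int(gen_only.sum())
    if num_bp == 0 or den_bp == 0:
        raise ValueError("empty genic or intergenic partition")
    return (ratios_num / num_bp) / (ratios_den / den_bp)
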