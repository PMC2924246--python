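"""Grand-canonical hard rods on a 1-bp lattice in an external energy landscape.

Transfer-matrix style recursion for the exact equilibrium midpoint density of
hard rods (width ``b`` bp, odd, so the midpoint is a lattice site) at fugacity
``z``, with an arbitrary per-midpoint binding energy ``E(m)`` in units of
k_B T (beta = 1).  This generalizes the perfect-barrier solution of
:mod:`nucbarrier.tonks` to soft boundaries: repellent regions of finite
strength and attractive wells of finite depth/width, spanning the continuum
between "direct" positioning (a pinned boundary nucleosome) and "indirect"
statistical positioning against a repelling stretch of DNA.

Forward/backward partition values are kept in log space, so arbitrarily long
lattices and deep wells cannot overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnergyProfile",
    "LatticeGas",
    "GCResult",
    "solve_density",
    "tune_fugacity",
    "boundary_family",
    "continuum_fugacity",
]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class EnergyProfile:
    """External energy landscape acting on rod midpoints.

    shape:
        ``"repellent_halfline"`` -- +eps on a long stretch ending at
        ``region[1]`` (a half-line for all practical purposes),
        ``"attractive_well"`` -- -|eps| on a narrow interval,
        ``"custom"`` -- explicit per-midpoint energy ``table``.
    eps:
        Energy amplitude in k_B T.  ``math.inf`` is allowed for a hard wall.
    region:
        Closed interval of midpoint coordinates (1-based lattice sites) over
        which the energy applies; energy is 0 outside.
    """

    shape: str = "custom"
    eps: float = 0.0
    region: tuple[int, int] | None = None
    table: dict[int, float] | None = None

    def energies(self, L: int) -> np.ndarray:
        """Energy at each midpoint site, index 0 unused, sites 1..L."""
        E = np.zeros(L + 1)
        if self.shape == "custom":
            if self.table:
                for m, e in self.table.items():
                    if 1 <= m <= L:
                        E[m] = e
        elif self.shape in ("repellent_halfline", "attractive_well"):
            if self.region is None:
                raise ValueError(f"shape {self.shape!r} requires a region")
            lo, hi = self.region
            lo, hi = max(1, lo), min(L, hi)
            E[lo : hi + 1] = self.eps
        else:
            raise ValueError(f"unknown energy shape {self.shape!r}")
        bad = ~np.isfinite(E) & ~(E == np.inf)
        if np.any(bad):
            raise ValueError("energies must be finite or +inf (hard exclusion)")
        return E


@dataclass(frozen=True)
class LatticeGas:
    """Lattice, rod width and fugacity of the grand-canonical gas."""

    L: int = 20000
    b: int = 147
    z: float = 1.0

    def __post_init__(self) -> None:
        if self.b % 2 == 0:
            raise ValueError(
                f"rod width b must be odd so the midpoint is a lattice site, got {self.b}"
            )
        if self.L <= 10 * self.b:
            raise ValueError(f"lattice too short: L={self.L} must exceed 10*b={10 * self.b}")
        if not (self.z > 0 and np.isfinite(self.z)):
            raise ValueError(f"fugacity must be positive and finite, got {self.z}")

    @property
    def h(self) -> int:
        """Rod half-width, (b-1)/2."""
        return (self.b - 1) // 2

    @property
    def mu(self) -> float:
        """Chemical potential ln(z), k_B T units."""
        return math.log(self.z)


@dataclass
class GCResult:
    """Midpoint density track and bookkeeping from :func:`solve_density`."""

    midpoint_density: np.ndarray  # index m = 1..L, index 0 unused (zero)
    z_used: float
    bulk_spacing: float  # 1 / mean density over the central 50% window
    eps: float | None = None

    @property
    def mean_particle_number(self) -> float:
        return float(self.midpoint_density.sum())


def _logaddexp(a: float, b: float) -> float:
    if a == _NEG_INF:
        return b
    if b == _NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))


def solve_density(profile: EnergyProfile, gas: LatticeGas) -> GCResult:
    """Exact grand-canonical midpoint density for rods in an energy landscape.

    Forward partition values F(i) over prefixes and backward values B(i) over
    suffixes satisfy

        F(i) = F(i-1) + w(i-h) F(i-b),   w(m) = z exp(-E(m)),  F(i<=0) = 1
        B(i) = B(i+1) + w(i+h) B(i+b),                         B(i>L)  = 1

    and the density of a rod midpoint at site m is

        n(m) = w(m) F(m-h-1) B(m+h+1) / F(L).

    Sites where the rod would overhang the lattice have n(m) = 0.
    """
    L, b, h, z = gas.L, gas.b, gas.h, gas.z
    E = profile.energies(L)
    lnz = math.log(z)
    # log statistical weight of a rod with midpoint m; -inf where invalid
    logw = np.full(L + 1, _NEG_INF)
    for m in range(h + 1, L - h + 1):
        e = E[m]
        logw[m] = _NEG_INF if e == np.inf else lnz - e

    logF = np.zeros(L + 1)  # logF[i], i = 0..L; F(i<=0) = 1
    lw = logw  # local alias for speed
    for i in range(1, L + 1):
        a = logF[i - 1]
        if i >= b:
            w = lw[i - h]
            if w != _NEG_INF:
                a = _logaddexp(a, w + logF[i - b])
        logF[i] = a

    logB = np.zeros(L + 2)  # logB[i], i = 1..L+1; B(i>L) = 1
    for i in range(L, 0, -1):
        a = logB[i + 1]
        m = i + h
        if m <= L - h:
            w = lw[m]
            if w != _NEG_INF:
                tail = logB[i + b] if i + b <= L + 1 else 0.0
                a = _logaddexp(a, w + tail)
        logB[i] = a

    n = np.zeros(L + 1)
    logZ = logF[L]
    for m in range(h + 1, L - h + 1):
        w = lw[m]
        if w != _NEG_INF:
            n[m] = math.exp(w + logF[m - h - 1] + logB[m + h + 1] - logZ)

    lo, hi = L // 4, 3 * L // 4
    bulk = float(n[lo : hi + 1].mean())
    spacing = math.inf if bulk == 0 else 1.0 / bulk
    return GCResult(midpoint_density=n, z_used=z, bulk_spacing=spacing)


def continuum_fugacity(b: float, dbar: float) -> float:
    """Closed-form continuum Tonks equation of state: fugacity at density 1/dbar.

    z = rho/(1 - rho b) * exp(rho b / (1 - rho b)), rho = 1/dbar.
    """
    rho = 1.0 / dbar
    eta = rho * b / (1.0 - rho * b)
    return rho / (1.0 - rho * b) * math.exp(eta)


def tune_fugacity(
    gas: LatticeGas,
    target_dbar: float,
    tol: float = 0.1,
    max_iter: int = 200,
) -> float:
    """Fugacity at which the free (E=0) gas has bulk spacing ``target_dbar``.

    Bisection on ln z; the bulk density is monotone increasing in z, so the
    bulk spacing is monotone decreasing and bisection converges.  The initial
    bracket is seeded from the continuum equation of state and widened
    automatically if needed.
    """
    if not target_dbar > gas.b:
        raise ValueError(f"target_dbar={target_dbar} must exceed b={gas.b}")
    if not tol > 0:
        raise ValueError("tol must be positive")
    free = EnergyProfile(shape="custom", table=None)

    def spacing_at(lnz: float) -> float:
        g = LatticeGas(L=gas.L, b=gas.b, z=math.exp(lnz))
        return solve_density(free, g).bulk_spacing

    lnz0 = math.log(continuum_fugacity(gas.b, target_dbar))
    lo, hi = lnz0 - 1.0, lnz0 + 1.0
    # widen until the bracket straddles the target (spacing decreasing in z)
    for _ in range(60):
        if spacing_at(lo) >= target_dbar:
            break
        lo -= 2.0
    else:
        raise RuntimeError("could not bracket target spacing from below in z")
    for _ in range(60):
        if spacing_at(hi) <= target_dbar:
            break
        hi += 2.0
    else:
        raise RuntimeError("could not bracket target spacing from above in z")

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        s = spacing_at(mid)
        if abs(s - target_dbar) <= tol:
            return math.exp(mid)
        if s > target_dbar:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"fugacity bisection did not reach |spacing-{target_dbar}| <= {tol}"
    )


def boundary_family(
    eps_values,
    gas: LatticeGas,
    well_width: int = 20,
    anchor: int | None = None,
    repellent_span_rods: int = 20,
) -> list[GCResult]:
    """Density patterns for a family of boundary conditions of varying strength.

    For each energy amplitude eps (k_B T): eps >= 0 builds a repellent
    stretch of length ``repellent_span_rods * b`` ending at the anchor site
    (eps = +inf is a hard wall, eps = 0 the free gas); eps < 0 builds an
    attractive well of width ``well_width`` ending at the anchor.  All family
    members share the fugacity of ``gas`` (tune it once on the free gas), so
    differences between members reflect the boundary alone.
    """
    if well_width < 1:
        raise ValueError("well_width must be >= 1")
    if anchor is None:
        anchor = gas.L // 4
    results = []
    for eps in eps_values:
        if eps >= 0:
            prof = EnergyProfile(
                shape="repellent_halfline",
                eps=eps,
                region=(anchor - repellent_span_rods * gas.b + 1, anchor),
            )
        else:
            prof = EnergyProfile(
                shape="attractive_well",
                eps=eps,
                region=(anchor - well_width + 1, anchor),
            )
        res = solve_density(prof, gas)
        res.eps = float(eps)
        results.append(res)
    return results
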