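# Methods

## The physical model

`nucbarrier` treats nucleosomes as impenetrable rods of footprint `b = 147`
bp on a one-dimensional genome at mean center-to-center spacing `d̄`
(density `ρ̄ = 1/d̄`, default `d̄ = 177` bp) — the Tonks gas of statistical
physics. Mapping the rods to a point gas shows that bulk edge-to-edge gaps
are exponential with mean `ℓ = d̄ − b`, so the distance from a perfectly
positioned "barrier" nucleosome to its k-th neighbor is a shifted Erlang
density

    P_k(x) = Θ(x − k b) (x − k b)^(k−1) exp(−(x − k b)/ℓ) / (ℓ^k (k−1)!),

and the mean density at distance x from the barrier is the finite sum
`ρ(x) = Σ_k P_k(x)` (terms with `k > x/b` vanish identically, so the sum is
exact, not truncated). `ρ(x)` is zero on `[0, b)`, jumps to `1/ℓ` at
contact, and decays through damped oscillations to `1/d̄`. The bulk pair
distribution is `g(x) = ρ̄ ρ(x)` with limit `ρ̄²`.

Aligned, gene-averaged nucleosome read densities are fitted with

    f(x) = A · ρ(x − x₀),

where `A` converts particle density to read-weight units and the offset
`x₀` encodes the boundary condition: `x₀ ≈ 0` means the alignment
nucleosome is itself the barrier (*direct* positioning); `x₀ ≈ −b` means
the array is phased by a repelling region with the first nucleosome free
(*indirect*, purely statistical positioning). The two cases are deep,
separate basins of the least-squares score; the classification threshold is
`|x₀| < b/2`.

Assumptions inherited from the model: thermodynamic equilibrium in a static
free-energy landscape, hard-core interactions only, a continuum coordinate
(valid because `ℓ ≫ 1` bp), and the same `d̄` on both sides of the NFR
(checked empirically via the density ratio, below).

## Grand-canonical lattice solver

Between the two perfect limits (pinned nucleosome / hard wall) lie soft
boundaries. `lattice.solve_density` computes the exact equilibrium midpoint
density of hard rods on a 1-bp lattice at fugacity `z` in an arbitrary
per-midpoint energy landscape `E(m)` (units k_BT, β = 1) via forward and
backward partition recursions

    F(i) = F(i−1) + w(i−h) F(i−b),   w(m) = z e^(−E(m)),   h = (b−1)/2,
    B(i) = B(i+1) + w(i+h) B(i+b),
    n(m) = w(m) F(m−h−1) B(m+h+1) / F(L).

Partition values are carried in log space, so lattice length and well depth
cannot overflow. `b` must be odd so the midpoint is a lattice site.
`tune_fugacity` bisects on `ln z` until the free-gas bulk spacing (central
50% of the lattice, avoiding edge depletion) hits the target within 0.1 bp;
convergence is guaranteed by monotonicity of density in `z`.
`boundary_family` builds repellent stretches (length 20·b, amplitude +ε,
ε = ∞ being a hard wall) and attractive wells (width 20 bp by default,
depth −ε) sharing one tuned fugacity, so differences between members
reflect the boundary alone. The well width is a free parameter chosen to
be comparable to the width of an experimentally positioned nucleosome peak;
it is exposed in the API and CLI.

Two numerical conventions matter when comparing the lattice to the
continuum formula:

* a lattice site at gap g from a wall (or distance x from a pinned rod)
  carries the continuum probability mass of the unit bin `[g, g+1)`
  (`tonks.barrier_density_binned`), not the pointwise density — at the
  discontinuous contact peak the two differ by ~3%;
* the lattice gap law is geometric rather than exponential, which shifts
  the fugacity-density relation: the tuned fugacity matches the exact
  lattice k-mer equation of state, and is ~12% below the continuum
  equation of state at `b = 147`, `ℓ = 30`. Densities agree to <2% at the
  oscillation peaks once the bin-measure convention is used.

## Fitting protocol

Profiles are fitted on the integer offsets 200–2000 bp downstream of the
+1 anchor (upstream profiles are mirrored at the origin first); the
alternative range 200–1200 bp is exposed for robustness checks. The score
is the mean squared deviation per data point (reported as `chi2`).
`scipy.optimize.least_squares` (bounded trust-region) is restarted 300
times per fit from randomized starts: `A` within 0.2–5× the data-matched
normalization, `d̄` uniform in 150–250 bp, `x₀` uniform across the chosen
basin (±30 bp around 0 or −b, or the full ±220 bp range when free). On
every profile tested the best of 300 restarts equals the best of 1000 to
10⁻⁹ — the basin structure is simple. Flat (degenerate) profiles are
returned as non-converged rather than with arbitrary parameters, since
`d̄` is unidentifiable there.

Variants:

* **Offset-only −1 fit** — `A` and `d̄` carried over from the +1 fit,
  only `x₀` optimized, started in both basins.
* **Convolved fit** — the model is convolved with the empirical profile in
  ±80 bp around the anchor (unit-normalized), which carries the residual
  positional spread of the boundary nucleosome; `x₀` is fixed at 0 because
  the kernel already encodes the peak location. The convolution window is
  a configuration parameter.
* **Simultaneous four-scenario fit** — joint least squares over both
  profiles with `A` and `d̄` shared and each side's offset bounded to the
  basin named by the scenario pair (A = both direct, B = indirect/direct,
  C = direct/indirect, D = both indirect); the pairs are ranked by joint
  chi² per point.

The two offset basins are nearly degenerate over 200–2000 bp (a shift of
one period almost maps the model onto itself), which is why scenario fits
impose basin bounds rather than relying on starting values alone; the
discrimination lives mostly in the first fitted peak.

## Density proxies

`reads_to_density` assigns each read the midpoint of its 147-bp fragment
(`start + 73` for Watson, `end − 1 − 73` for Crick, 0-based half-open) and
weights each alignment by the reciprocal of the read's alignment count, so
every sequenced molecule carries total weight 1. `calls_to_density` places
a unit-mass discretized Gaussian at each called dyad with σ equal to the
call's fuzziness, floored at `sd_floor` (default 1 bp — sub-floor calls get
the floored Gaussian rather than a delta; this treatment is a package
decision), truncated at ±6σ (<10⁻⁸ mass) and renormalized.
`cross_normalize` returns the factor equating genome-wide totals of the
two proxies. Anchors: the +1 nucleosome is the first call at or downstream
of the TSS, the −1 the first strictly upstream; ties break downstream; the
3′-end anchors mirror these at the ORF end with the inclusive side
upstream. Averages weight genes equally (read-weighted averaging would
overweight highly covered genes); this is a stated choice, not forced by
the data model.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
entirely on one synthetic contig (`chrSim`):

* Genes sit head-to-tail in territories of `flank + length + flank`
  (flank 3 kb), alternating strands; lengths are log-normal
  (μ = 7.24, σ = 0.85 in log-bp, floor 400 bp), putting about a third of
  genes beyond 2 kb with typical lengths near 1–1.5 kb.
* Per gene, the +1 dyad sits at TSS + max(0, N(50, 20)) bp in transcription
  coordinates (the +1 is by definition at or downstream of the TSS) and
  the −1 one footprint plus an NFR gap of max(0, N(140, 25)) bp upstream.
* Each NFR side has a boundary scenario: *direct* places a real pinned rod
  at the anchor; *indirect* places a repelling edge, implemented exactly as
  a virtual rod displaced one footprint into the NFR, so the first free
  nucleosome's modal dyad falls on the anchor. Defaults: direct +1,
  indirect −1.
* Between consecutive boundary rods the configuration is drawn from the
  exact grand-canonical distribution: particle number with
  `P(N) ∝ z^N F_N^N / N!` (`F_N = D − (N+1)b` the free length), then
  sorted-uniform positions; `z` comes from the continuum equation of
  state at the local target spacing. This construction has no truncation
  or censoring artifacts, so gene-averaged profiles converge to the
  analytic `ρ(x)` and region densities to `1/d̄` exactly.
* A cohort pools `n_cells = 8` such configurations per genome (anchors
  fixed, arrays resampled), mirroring the cell-population averaging of an
  MNase experiment; with one cell, configuration noise dominates
  subset-level statistics and cannot be reduced by sequencing deeper.
* Reads: per nucleosome and cell, Poisson counts at
  `reads_per_nucleosome_mean / n_cells` (default total 6 per nucleosome);
  midpoint = dyad + round(N(0, 10)) bp of digestion/trimming jitter; strand
  fair-coin; fragment exactly 147 bp so midpoint arithmetic is exact. A
  5% fraction of reads is emitted as 3 alignments sharing one identifier,
  with the extra copies placed at other nucleosomes' dyads — secondary
  alignments of nucleosomal fragments fall at nucleosome-protected loci,
  not uniformly on the genome (a uniform background would also bias the
  fitted spacing upward by ~1 bp, since the model has no constant term).
* Calls are emitted at the modal dyad of each slot — what an idealized
  peak detector recovers: the pinned dyad (direct) or the wall edge plus
  multiples of `d̄` (indirect) — with fuzziness measured as the SD of
  pooled read midpoints within half a footprint of the call. A separate
  truth table (never read by the pipeline) retains scenarios and true
  parameters for blind recovery tests.
* When genic and intergenic spacings differ, a positioned rod at each ORF
  end demarcates the two regimes (the 3′-boundary nucleosome); with equal
  spacings no such rod is placed.

What the generator does **not** emulate: DNA sequence (no FASTA, no MNase
sequence bias), transcription-coupled remodeling, fuzzy/overlapping calls
from real peak callers, chromosome ends, or replication effects. Passing
recovery tests therefore demonstrates that the inference machinery is
correct and well-calibrated under the model's own assumptions — not that
real chromatin satisfies those assumptions.

## What the fits recover, and residual biases

On the default cohort (2000 genes) the pipeline recovers `d̄` within ~1.5
bp of truth. Two small, understood systematics remain: fitting the
unconvolved model to jitter-smeared data inflates `d̄` by ~1 bp (the
convolved fit removes most of it — the same observation motivates the
convolved variant), and each is documented rather than corrected, matching
the analysis protocol. The intergenic/genic density ratio uses the union
of [TSS, ORF-end] intervals as genic, excludes each gene's −1-to-+1 dyad
interval (the NFR and the flanking rods' inner edges) from both averages,
and its standard error in tests comes from per-contiguous-gene-block
ratios. When spacings are equal the ratio is 1 to within noise. When they
differ, the region-mean estimator carries a known ≈+1% systematic: regions
are sliced at rod-scale boundaries, so the boundary-straddling rods'
reads (half the demarcating ORF-end rod's reads spill intergenic) and the
finite-region surface layers (worth a fraction of one rod per boundary) do
not cancel between regions of unequal length. The bulk rod-density ratio
of the construction is exact; the read-based region mean reports it only
to ~1% at these region sizes. This is a granularity limit of any
per-bp region-mean estimator, not a property of the gas model.

## Problem sizes and determinism

Everything is seeded (`numpy.random.default_rng`); identical configuration
plus seed reproduces byte-identical tables. The validation suite uses an
800-gene cohort for module-level checks and a 2000-gene cohort (the study
condition) for end-to-end recovery; the Monte-Carlo oracle uses 10⁵
pinned-origin configurations of 240 rods in 5-bp bins over 0–2000 bp; the
lattice solver runs on L = 20000 sites. These sizes give sampling errors
well below every tolerance asserted while keeping the whole suite in the
minutes range on a single CPU.
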