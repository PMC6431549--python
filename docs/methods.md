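# Methods

This note documents the models implemented in `lulcsim`, the defaults and
their rationale, the numerical choices, and what the synthetic studies do
and do not demonstrate.

## Data model and accounting

A landscape is a 2-D integer raster of class codes with a boolean nodata
mask and a square cell size in meters (default 30 m, the Landsat ground
resolution). Grids are row-major and 0-based; no reprojection or resampling
is performed — inputs must be co-registered, which is the normal situation
for a single-footprint satellite time series. Change computations use the
union of the epochs' nodata masks so that all totals refer to one fixed
footprint; only then do per-class net changes sum to zero.

Areas are `cells × cell_size²/10,000` ha. Percentage shares are recomputed
from hectares, so a table built from published hectare totals reproduces
published share columns to their printed precision. Annualized percent rates
`((A₂/A₁)^{1/Δt} − 1)·100` are provided as a convenience only: published
LULC tables often carry "rate of change" columns whose formulas are not
stated and cannot be assumed to match.

Change typing defaults to: primary forest (PF) to cleared or built classes
(AWV, HS) = deforestation; PF to secondary forest (SF) = degradation; SF to
PF = recovery; any other change = other. The mapping is a configurable
argument because no single convention is universal.

## Transition matrices and annualization

The maximum-likelihood period matrix is the row-normalized crosstab. A class
absent at the period start gets an identity row with a warning rather than
an error: rare classes (water bodies, settlements) can be absent from an
epoch without invalidating the matrix.

Yearly stepping requires the matrix `T`-th root. We take the principal
eigendecomposition root `A = V D^{1/T} V⁻¹`. Two failure modes raise
errors: eigenvalues on the negative real axis (no principal real root) and
numerically non-diagonalizable matrices. Complex conjugate eigenvalue pairs
are accepted — the principal branch keeps `A` real.

Empirical period matrices are frequently *non-embeddable*: the exact root
carries small negative entries, and **no** nonnegative stochastic yearly
matrix powers back to the period matrix. (Structural reason: a period-matrix
zero between classes that are connected through intermediaries cannot be
reproduced by any nonnegative root whose diagonal is positive; we confirmed
by bounded least-squares over all nonnegative stochastic roots that the
error floor for a typical printed 27-year forest matrix is ~2×10⁻², four
orders of magnitude above the exact root's round-trip error.) `annualize`
therefore returns the exact root by default, flagged quasi-stochastic, with
the total negative mass reported in `cleanup_magnitude` (typically ~10⁻³ of
rate mass); `enforce_stochastic=True` gives the truncate-and-renormalize
variant when a proper probability matrix matters more than round-trip
fidelity. Restricting to a transition whitelist folds all off-whitelist
mass — including the negative artifacts — into the diagonal, so the matrix
the simulator consumes is always properly stochastic.

Matrices loaded from printed tables are row-renormalized within an explicit
tolerance of 5×10⁻⁴ (4-decimal rounding routinely makes printed rows sum to
0.9999 or 1.0001); larger deviations are rejected as data errors.

## Driver screening and Weights of Evidence

Continuous drivers are discretized into equal-width bins (default 20) over
their observed range; the bin count is configurable because the weight
noise floor scales with it (see below). Cramér's V is computed without
continuity correction, dropping zero-marginal rows/columns with a warning.
Screening is iterative: while any retained pair has V strictly above the
0.5 threshold, the pair with the largest V loses its member with the weaker
association to the transition indicator. A tie at exactly 0.5 is retained,
reading "above 0.5" as the association criterion.

W⁺ uses additive smoothing of +0.5 on all four counts of a bin's 2×2 table
only when one of them is zero, so well-populated bins are exact (a bin
holding 80% of changed and 20% of unchanged cells scores exactly ln 4).
The probability map multiplies prior odds by `exp(ΣW⁺)` across drivers —
the usual conditional-independence assumption, taken as given after
screening, with no further Bayesian correction.

Sampling noise: the standard error of a bin's W⁺ is roughly
`√(1/a+1/b+1/c+1/d)`. On 10⁴ cells with a 30% change rate this stays below
~0.05 per bin at 5 bins, but reaches ~0.1 at 20 bins; the no-effect
invariant test therefore uses 5 bins, where a |W⁺| < 0.15 bound is a
meaningful null band rather than a coin flip.

## Cellular automata

Demand per transition per year is `round(n(i)·A[i,j])` with a fractional
carry (largest-remainder): a rate worth 1.55 cells/year alternates demands
of 1 and 2 and stays unbiased over any horizon. Unmet expander demand
cascades to the patcher within the year; unmet patcher demand carries to
the next year through the same accumulator.

Adjacency is 8-neighbor throughout (the standard for landscape CA). The
expander recomputes the frontier after each probability-weighted sampling
round, so patches can snowball within a year. The patcher draws seeds
proportionally to the probability map and grows each patch cell-by-cell,
scoring candidates by `p(cell) · isometry^(adjacent patch cells − 1)`; new
patch sizes are lognormal, parameterized by mean/variance in hectares and
truncated at the remaining demand. Patch-geometry defaults (0.5 ha mean,
isometry 1.5, expander fraction 0.5) are exposed in the config and recorded
in every run manifest — they are modeling choices, not estimates, and no
published values exist for them.

A single seeded `numpy` generator is threaded through the run; identical
seeds give bitwise-identical landscapes. Dynamic drivers are recomputed
each year as exact Euclidean distance transforms (`+inf` when the target
class is absent, documented sentinel).

Because allocation only redistributes a demand that is itself computed from
the current class counts, aggregate shares track the Markov projection by
construction; deviations are integer-rounding level (sub-cell), which is
exactly what the convergence study measures.

## Scenarios

Scenario specs scale off-diagonal annual rates multiplicatively and refit
the diagonal; a row whose scaled off-diagonal mass reaches 1 raises an
infeasibility error naming the row. Frozen classes get identity rows *and*
have incoming mass returned to the senders' diagonals, so their share is
held constant — matching the convention of holding settlements and water
bodies fixed in forest-change projections. The magnitudes of "optimistic"
and "pessimistic" (suggested 0.5× and 1.5×) are mandatory configuration:
every manifest and report records them.

## Validation

κ uses the confusion-matrix marginals; the degenerate case of two constant
identical maps is defined as κ = 1. The fuzzy similarity index uses
constant fuzziness within the window and two-way minimum aggregation, the
variant standard in the multi-resolution validation lineage; an
exponential-decay variant (credit halving per Chebyshev cell) is selectable
since published descriptions often leave the decay unstated. Windows are
clipped at map edges so the index is defined on small grids. Distance
reporting supports both the full-width convention (`w × cell_size`; 7×7 at
30 m ↔ 210 m, the default) and the half-width convention
(`(w−1)/2 × cell_size`; 7×7 ↔ 90 m).

## Synthetic data

The landscape generator thresholds Gaussian-smoothed white noise at
share-matching quantiles: simple, deterministic per seed, with realized
shares within ±0.02 of the request on grids ≥ 200×200 and patch scale set
by the smoothing length (default 5 cells). Cluster-growth generators were
rejected as harder to parameterize. Default class shares (PF 0.55, SF 0.40,
AWV 0.04, HS and WB 0.005) mirror a forest-dominated footprint.

Drivers cover the three families used in deforestation modeling: proximity
(exact distance transform to random point/line features), density
(Gaussian-kernel feature counts per km²), and topographic (multi-octave
smoothed-noise elevation mapped to a 1,000–2,500 m range, slope from
central differences in degrees, TPI as deviation from the mean in a
square window of radius 5 cells).

`simulate_history` moves each cell of class i to j with probability
`A[i,j]·m_c/mean(m)`, where `m_c` is the cell's planted WoE odds multiplier;
the empirical renormalization keeps aggregate demand equal to the matrix
regardless of the planted spatial structure. Planted effect profiles are
constructed with ~unit mean odds (e.g. +0.5 below the driver median and
ln(2−e^0.5) ≈ −1.05 above it), so measured W⁺ centers on the planted values
and recovery within ±0.3 is a genuine recovery check rather than an offset
estimate.

What the synthetic studies show: that estimation inverts generation
(matrix within 3 SE, WoE sign and ±0.3), that the CA conserves quantity
while allocating space, and that the validation metrics behave as their
definitions demand. What they do not show: performance on real imagery —
real landscapes have classification noise, aligned linear infrastructure,
and driver collinearity far richer than the generator's, so published
real-map accuracy figures are out of reach by construction (the source
rasters of the worked example were never deposited).

## Problem sizes

The test suite and acceptance script use 200×200 grids over 10 years for
recovery, 100×100 over 10 years × 20 seeds for CA convergence, and 80×80
over 33 years × 10 seeds × 3 scenarios for ordering — sizes at which the
sampling-error bounds above are already tight while a full run stays within
a few minutes on one core.
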