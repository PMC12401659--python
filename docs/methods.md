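# Methods

This note documents the models and procedures implemented in `xericfish`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical choices that matter.

## Spatial binning

The hex grid lives in longitude/latitude degree space (not a projection):
pointy-top cells, centroid-to-vertex radius 0.1° by default, cell (0, 0)
anchored at (0°, 0°). Cells are identified by integer axial indices
(q, r). Because the grid is angular, metric cell area varies with
latitude; `hex_area` reports the planar closed form (3√3/2)·R², which at
the nominal 11 km conversion of 0.1° gives ~314 km². Assignment is
nearest-centroid (computed by cube rounding and verified against an
explicit neighbourhood search); points exactly on shared edges or vertices
break ties toward the lexicographically smallest (q, r), making assignment
deterministic.

Coordinate-precision screening counts digit characters in the *original*
coordinate strings (sign and decimal point excluded, leading zeros
counted): at least three latitude digits keeps a record, and two-digit
latitudes are kept when the longitude has exactly five or nine digits —
the trailing-zero rescue rule. We read "three digits" as total digits, not
decimal places, because the canonical example pair (46.1, −99.4) has three
total digits each. The freshwater rule is applied per sampling point: a
site is kept when at least half of its distinct species are flagged
freshwater, after which marine/brackish-specific records are removed.
Polygon filters count boundary points as inside (deterministic and
inclusion-biased, matching the coarse intent of a habitat mask).

## Climate metrics

Calendar-year precipitation metrics: total, anomaly (total minus the
site's long-term mean), zero-precipitation days (daily total < 1 mm;
1.0 mm is a rain day), and intensity (total / rain days, undefined for a
rainless year). Seasonal temperature metrics use daily means
(tmin + tmax)/2 averaged over meteorological quarters; the hemisphere
flips the labels (December–February is northern winter, southern summer).
December is assigned to the quarter labelled by the following January's
year so blocks stay contiguous. Long-term means are **self-inclusive**
(the focal year is part of its own reference), the plain reading of
"subtracting the long-term average"; hence anomalies sum to ~0 over the
record, a tested invariant. Years or seasons with more than 10% of days
missing yield undefined metrics and are excluded from long-term means.
All computation is unit-agnostic; slopes are in whatever unit the input
uses per year.

## Flow metrics

Water years are configurable and label by the ending calendar year:
1 October–30 September (USA convention) and 1 July–30 June (Australia)
are provided. A gauge-day is dry iff discharge is zero and stage is
missing or ≤ `stage_threshold` (default 0.02 in the stage's native unit —
a numeric cut is needed to separate flow reversals, where water stands but
does not flow, from dry channels; the default is small relative to any
realistic stage scale and is exposed in config). A cell is dry when any
member gauge is dry. Per water year with ≥ 90% coverage we report the
zero-flow-day count, the longest dry run, and the 1-based day of the first
occurrence of the annual minimum discharge (first-occurrence rule for
ties).

The anomaly transform is z(t) = log₁₀(q(t)/q̄ + c) with c = 0.01: bounded
at q = 0 while perturbing wet-day values by < 1%. The seasonal expectation
is rebuilt from the DFT's zero frequency, the annual fundamental (the bin
nearest n/365.25 cycles, always retained), and harmonics k = 2..6 that
pass a periodogram screen: a harmonic is kept when its ordinate exceeds
−m·ln(α) with α = 0.05, where m is the background ordinate estimated from
the median of non-candidate bins (median-based so the annual peak cannot
inflate it; the median of an exponential is m·ln 2). NAA is the residual
summed per water year. Note the spectral caveat: a pure 365.25-day
sinusoid is captured exactly only when the record length is an integer
number of cycles; otherwise leakage leaves a small residual, which the
NAA largely cancels because any pure harmonic sums to ~0 over a full year.
NAA is invariant to rescaling all discharge (mean normalization) and, by
construction, sums to ~0 over the record when no trend is present.

## Trend tests

Implemented from the formulas (no statistics-package calls):
S = Σ_{i<j} sign(x_j − x_i); tie-corrected Var(S); Z with the continuity
correction (S ∓ 1)/√Var(S); two-sided normal p. The Sen slope is the
median of pairwise slopes; its CI takes the M1-th and (M2+1)-th sorted
slopes with M1,2 = (N′ ∓ z₀.₉₇₅√Var S)/2 (Gilbert's method, verified
identical to scipy's independent implementation). Seasonal and regional
tests sum S and Var(S) over blocks (months or stations) and pool
within-block pairwise slopes for the slope estimate; blocks with fewer
than two observations contribute nothing and are warned about. No
serial-correlation variance inflation is applied (block independence is
assumed, as in the basic form of the cited tests); the continuity
correction makes the test slightly conservative at small block sizes —
the measured type-I error at 10 stations × 20 years is ~0.04 at nominal
0.05. Monthly aggregation sums precipitation and averages temperature;
annualization for the regional test likewise (the reducer is exposed to
the caller, since published usage does not pin it down).

## Richness models

The mixed model is log λ_it = β₀ + Σ β_k x_kit + u_i with
u_i ~ N(0, σ²) and Poisson observations. The marginal likelihood is a
product of one-dimensional integrals (one per hex), evaluated by
**adaptive** Gauss–Hermite quadrature: each group's integrand is centred
on its posterior mode (found by Newton) and scaled by the local curvature,
with 15 nodes (Laplace is the 1-node special case). The total is maximised
over (β, log σ) by BFGS with a Nelder–Mead polish, started from an IRLS
Poisson GLM fit. Wald intervals come from the numerically differentiated
Hessian at the optimum. Parameter count is fixed effects + intercept + σ.
Predictors are centered and scaled by default; this changes coefficient
scale only, not the likelihood (tested). A single group collapses to an
ordinary Poisson regression with σ = 0 and a warning.

AIC bookkeeping: Δᵢ, weights, cumulative weights, the smallest
weight-ordered prefix reaching 0.95 (confidence set), evidence ratios, and
a Δ ≤ 7 equal-plausibility flag.

CCA follows the classical algorithm: divide the site-by-species matrix by
its grand total, form Q = (P − rcᵀ)/√(rcᵀ), weight rows of the centred
constraints by √r, project Q onto them, and take the SVD of the fitted
matrix; canonical eigenvalues are squared singular values, total inertia
is ΣQ². Presence/absence (not abundance) is the intended response, since
multi-source occurrence data lack effort standardization. Axis
significance permutes rows of the constraint matrix jointly (default 999
permutations, seeded) and compares the k-th eigenvalue; this is a simple
unconditioned per-axis test. The implementation is cross-checked against
scikit-bio's CCA in the test suite.

## Trait tests and listing reasons

The Fisher–Pitman statistic is the group-A sum; its exact permutation
moments give Z = (T − E T)/√Var T with Var T = n_a n_b Σ(x−x̄)²/(n(n−1)),
an asymptotic two-sided normal p, and a permutation p defined on |T − E T|.
All C(n, n_a) relabelings are enumerated when there are at most 100,000 of
them (no add-one correction; the 2-vs-2 example gives exactly 2/6);
otherwise the Monte-Carlo p is (b + 1)/(n_perm + 1) over seeded random
relabelings (default 10,000). Missing trait values must be dropped
pairwise per trait before testing.

"Of concern" means IUCN category NT, VU, EN, CR or EX; DD is tallied
separately. Reason percentages are round(100·k/n_listed) over species with
at least one recorded reason; flagged species with none are counted as
unrecorded, excluded from percentages, and warned about. Venn-region
counts partition the listed species (one region per distinct reason set).
`example_concern_table` is a deterministic 42-species configuration
consistent with the published marginal counts (the sources publish only
marginals, so one consistent assignment is constructed).

## Ancestral states

Equal-rates two-state Mk only, with the (0.5, 0.5) root prior; this is the
minimal model consistent with a "reversible" binary-trait analysis with
equal root priors (an all-rates-different variant would need asymmetric
evidence the data here cannot support). Likelihood is Felsenstein pruning
with per-node rescaling; q̂ by bounded golden-section search on log q in
[10⁻⁸, 100]. Polytomies are resolved with zero-length branches
(likelihood-neutral). Stochastic maps draw joint node states exactly —
root from prior × partial likelihoods, then preorder conditional draws —
so node frequencies are unbiased for the pruning marginals (tested at
3× Monte-Carlo SE). Branch histories use rejection sampling of forward
trajectories conditioned on endpoints (≤ 50 tries), falling back to
uniformization, where for this chain every virtual jump is a real flip and
the jump count distribution is Poisson weighted by endpoint parity.

## Synthetic generators

The generators emulate the *structure* of the real archives, not their
content: daily calendar dates with leap years, seasonal hydrographs with
AR(1) log-noise, contiguous dry spells placed in the low-flow season,
stage generated jointly with discharge (so flow-reversal days exist),
zero-inflated precipitation, seasonal temperature with linear trends,
occurrence tables drawn from the richness model run forward, and
pure-birth trees with Mk-evolved tip states. One seeded
`numpy.random.Generator` drives each call; identical seeds give identical
output.

Two deliberate semantics: `dry_spell_trend` adds days/yr to the *expected
total* annual zero-flow days (split over a Poisson number of spells), so
the injected value equals the recoverable Theil–Sen slope of annual
zero-flow days whatever the spell rate; and `precip_trend` scales wet-day
amounts so the expected annual total changes by that many mm/yr.
Injected-parameter defaults mirror the magnitudes relevant to dryland
gauges and richness series (e.g. warming of ~0.05°/yr, drying of
~0.5 d/yr, richness decline of −0.02 log/yr over 23 hexes × 30 years).

What passing tests show — and what they do not: recovery succeeds under
the generators' idealizations (no detection error, no observer effort
gradients, no spatial autocorrelation beyond the hex random intercept, no
serial correlation in annual metrics beyond what AR(1) daily noise
induces, dry spells that never interact with the seasonal amplitude).
Real archives violate several of these; in particular, effort-driven
richness trends and gauge relocation artefacts are outside what these
tests can exclude. Small recovery biases are expected and measured: spell
overlap clips ~5% off injected drying slopes, and a single inflated-flow
year loses ~1/n_years of its NAA response to the self-inclusive seasonal
mean (~356 of 365 log₁₀-day units at 40 years).

## Problem sizes and degenerate inputs

Simulation-based checks use 100–1,000 replicates at the scale of the
motivating datasets (50 stations × 42 years for climate trends, 200
gauges × 40 years for drying trends, 23 hexes × 30 years for richness);
these sizes give Monte-Carlo error comfortably inside the stated
tolerances. Degenerate inputs are defined, not fatal: all-tied series give
S = 0 and p = 1; a rainless year has undefined intensity; a monomorphic
tip-state vector pins q̂ at the lower bound with a warning; a single hex
collapses the mixed model to a GLM; empty CCA rows/columns are removed and
reported.
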