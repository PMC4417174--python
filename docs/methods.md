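# Methods

This note records the models implemented in etsdyn, the assumptions
behind them, the defaults that matter, and the choices made where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Fragment geometry and flexure displacement

Fragments use 1-based, fully closed coordinates in which base pair *i*
occupies the continuous interval [*i* − 1, *i*] (centre *i* − 0.5). The
flexure displacement of a site of length *s* starting at base *b* in a
fragment of length *L* is

    x = (b + (s - 1)/2 - 0.5) / L,

which makes a site centred at the fragment midpoint give *x* = 0.5
exactly, for any site length. `make_series` slides the site in evenly
spaced steps from flush with one end to flush with the other, which
yields flexure displacements exactly mirror-symmetric about 0.5
(*x*<sub>i</sub> + *x*<sub>n+1−i</sub> = 1). Exact even spacing can
require fractional start coordinates (for the default 143-bp/10-bp/11
panel the centred fragment needs start 67.5); the package allows them,
since a physical panel's rounding to restriction sites perturbs *x* by
< 0.5/L and only *x* matters downstream. Default panel: 11 fragments of
143 bp with a 10-bp site — the site then spans 7% of the fragment, small
enough to treat the bend as a point.

## Point-kink mobility model

Reptation theory for gel electrophoresis predicts that mobility scales
with the squared end-to-end distance of the migrating duplex, in units
of its contour length. For a rigid rod of unit length with a point kink
of angle *θ* (deflection from linearity) at fractional position *x*,
planar vector geometry gives end-to-end² = 1 − 2*x*(1 − *x*)(1 − cos *θ*),
hence the relative mobility of the bound fragment

    Rf(x) = K [1 - 2 x (1 - x) (1 - cos theta)].

This functional form is fixed by the constraints the analysis relies
on: it is quadratic in *x*, minimised at *x* = 0.5 with value
*K*(1 + cos *θ*)/2, and equal to *K* at *x* ∈ {0, 1} for every *θ*. The
two limits of interest are: equal *θ*, different *K* → a uniform
vertical shift between two profiles; equal *K*, different *θ* → a
position-dependent gap that is maximal for centred sites and vanishes
at terminal ones. *K* is interpreted as the ratio of non-bend
charge/friction factors of the bound versus unbound fragment
(approximately the friction ratio ξ_u/ξ_b for fixed-length fragments,
whose total charge barely changes on protein binding); the individual
charge and friction constants are not identifiable from mobility data
and are not represented in the API.

Convention: *θ* is reported in degrees as the deflection from linearity
(180° minus the included angle), and the angle-to-curvature mapping
(1 − cos *θ*) is isolated in `bend.kink_curvature_factor`. An
alternative convention using cos(*θ*/2) would rescale fitted angles but
leave *K*, the fitted curves, all F tests and all verdicts unchanged;
every report embeds the convention string so the *θ* scale cannot be
misread.

### Fitting

Weighted nonlinear least squares (weights 1/SE²; unweighted when any SE
is zero) via a trust-region reflective descent with analytic Jacobian,
bounds *K* > 0, *θ* ∈ [0°, 180°). Initialisation is closed-form and
deterministic: *K*₀ is the mean mobility of the two most terminal
placements, *θ*₀ inverts the midpoint value through
arccos(2·Rf(x≈0.5)/K₀ − 1), clamped to [0°, 179°]. No random restarts by
default; `fit(random_restarts=n, seed=...)` adds seeded extra starts
for pathological data. A flat profile legitimately converges to the
*θ* = 0 boundary, where the *θ* gradient vanishes; the covariance is
then computed by pseudo-inverse and the confidence band refuses to
report rather than fabricate a *θ* uncertainty.

Parameter covariance is the linearised (Gauss–Newton) estimate
s²(JᵀJ)⁻¹ with s² = RSS/df, so confidence limits self-scale with fit
quality. Default 95% limits are delta-method t-intervals;
`conf_int(method="profile")` profiles the weighted RSS against the
F(1, df) threshold, preferable near the *θ* = 0 boundary. Pointwise
confidence bands use the delta method; at *x* = 0 and 1 the band width
depends only on var(*K*), mirroring the model's end-anchoring.

### Model comparison

`compare_profiles` fits each profile separately (4 parameters) and both
jointly with one shared (*K*, *θ*) pair (2 parameters), then forms

    F = [(RSS_global - RSS_separate)/2] / [RSS_separate / df_sep],

df_sep = n_a + n_b − 4, with the p-value from the upper tail of
F(2, df_sep). Verdicts use α = 0.05 by default; p-values are kept at
floating precision but printed with a 1e−5 floor ("<0.00001"). The
statistic is exact when both profiles carry equal weights and residuals
are normal — the situation the replicate design produces (below).

## Replicate statistics

Relative mobility of one lane pair is the migration (from the trace
origin) of the largest-area bound band over that of the unbound band,
making Rf invariant to intensity rescaling and to a common shift of the
migration axis. Band detection thresholds at median + 3 MAD and splits
multi-band regions at interior local minima; the centroid is
intensity-weighted after baseline removal. This densitometry stand-in is
deliberately simple, and the statistical tests are designed not to
depend on its minutiae.

Position-wise high/low comparisons use Welch's t from group means,
standard errors and replicate counts, with Welch–Satterthwaite degrees
of freedom, followed by Benjamini–Hochberg step-up adjustment
(via statsmodels) across the panel; significance is adjusted p < α.
Welch is preferred over a pooled test because per-condition variances
from quadruplicates cannot be verified equal.

When the synthetic generator summarises replicates into a profile it
pools the replicate variance across positions before forming the SE.
The replicate noise is homoscedastic by construction (one gel batch,
uniform SE), and per-position SEs from 3 degrees of freedom are so
noisy that weighting by them makes the downstream F test anticonservative
(empirically ~4-fold inflation of the type-I rate); pooling restores
exact calibration, which the test suite verifies over 500 null
simulations. Per-position SEs still drive the Welch tests, where the
Welch–Satterthwaite df accounts for their uncertainty.

## DLS size summaries

Hydrodynamic diameters come from Stokes–Einstein,
D_H = k_B·T/(3πη·D_t), with defaults T = 298.15 K and
η = 0.8872 mPa·s (water at 25 °C, a standard stand-in for dilute PBS —
overridable in `DLSConfig`). The module starts from intensity-vs-size
distributions; inversion of raw autocorrelation functions is instrument
firmware and out of scope.

A distribution is summarised by least-squares fitting a Gaussian in
ln D_H with free amplitude — parameters μ_g = exp(location) (geometric
mean = median, nm) and σ_g = exp(scale) ≥ 1 (dimensionless geometric
SD). The free amplitude makes the fit invariant to uniform rescaling of
the weights. Standard errors are delta-method transforms of the
linearised covariance of (ln μ_g, ln σ_g). Distribution statistics are
taken from the fitted log-normal law: mode = μ_g·exp(−ln²σ_g) <
median = μ_g < mean = μ_g·exp(ln²σ_g/2), all converging as σ_g → 1. The
conventional size range is μ_g/σ_g to μ_g·σ_g. Comparisons report the
median shift and the σ_g ratio (tightening < 1 < broadening) with
z-scores from propagated SEs, the σ_g comparison done on the log scale.

## Footprint quantitation

Peak areas are trapezoidal integrals of the baseline-subtracted signal
over per-base windows supplied by an index map (emulating sizing-derived
peak indexing); automatic baseline handling is a rolling minimum with a
configurable window, appropriate for slow capillary drift. Every area is
normalised to a single control peak outside the binding interface, which
cancels sample-recovery differences; protection is
100·(1 − bound/unbound) on the summed normalised core-guanine areas,
reported at 0.1 granularity, with negative values reported as
hypersensitivity. Bases (other than the control and the core) whose
normalised area changes by more than 20% of the unbound value are
flagged; a base with zero unbound but nonzero bound signal counts as an
infinite change. DNase traces yield a site-specific verdict when any
base in the probed window shows a bound/unbound ratio strictly above a
configurable factor (default 2). Binary sequencer formats are out of
scope; traces enter as CSV.

## Motif information and discrimination energetics

Positional IC is 2 + Σ p log₂ p bits (0·log 0 = 0) under a fixed
equiprobable background; GC-adjusted backgrounds are intentionally
excluded so totals remain comparable with the energetics bound. No
small-sample correction is applied by default; a Miller–Madow flag
(−3/(2n ln 2) per column, clipped to [0, 2]) exists but is off. Total IC
sums positions; logo stack heights are IC × base probability.

The information a protein can extract in moving from nonspecific to
specific binding is ε_r·log₂(K_sp/K_ns) bits, with conversion
efficiency at most ε_r = ln 2 ≈ 0.7 under isothermal conditions (the
default). Binding constants are accepted as **dissociation** constants
(the form affinities are quoted in) and inverted internally, so each
term is ε_r·log₂(Kd_ns/Kd_sp); the convention is embedded in every
result object. The A−B difference is antisymmetric and linear in ε_r.

## Synthetic scenarios

The generators emulate the statistical structure the analyses assume —
not the instruments' physics. Defaults mirror the study conditions:
11 × 143-bp panel, 10-bp site, quadruplicate mobilities with SE 0.005,
log-normal DLS intensity curves with 5% multiplicative noise, guanine
electropherogram ladders with a distal control peak, tenfold core
suppression when bound, 3-fold DNase enhancement in the core window, and
multinomial motif counts from a consensus-weighted PWM. Three shipped
scenarios encode the qualitative contrasts: `pu1-like` with high
(K = 0.95, θ = 60°) vs low (K = 0.88, θ = 52°) — chosen so the two
curves nearly coincide at x ≈ 0.5 and diverge toward terminal sites —
and the two `ets1-*-like` scenarios with identical high/low parameters
(the autoinhibited variant with larger hydrodynamic size). These values
are realistic-pattern choices, not estimates of any measured quantity.
The synthetic motif strengths (0.85 vs 0.72 per-position consensus
probability) were picked so the motif-pair total-IC difference lands
near the energetics bound computed from the default binding constants.

What passing tests do and do not show: the generators produce Gaussian,
independent replicate noise, single log-normal size modes, drift-free
baselines and exactly indexed peaks. Real gels, scattering records and
electropherograms violate all of these to some degree (band smiling,
multimodal aggregates, sizing errors), so green tests demonstrate
correctness of the estimators and calibration of the inference under
the stated noise model — not robustness to instrument artefacts.

## Problem sizes and determinism

Simulation-based checks use 200 replicates for CI-coverage and DLS
recovery studies and 500 for F-test calibration, sizes at which binomial
noise on the checked rates is a few percent. Every stochastic generator
is a pure function of (parameters, seed) using numpy's PCG64; reports
contain no timestamps, making repeat runs with one seed byte-identical
in their results, with provenance (input hashes, seed, version) in a
separate metadata object.

## Known limitations

- The point-kink model ignores field strength, gel concentration and
  junction-bend mixtures; θ is comparable only within one convention.
- Single log-normal DLS summaries cannot represent genuinely multimodal
  distributions (no CONTIN/cumulant inversion).
- Band and peak quantitation assume well-separated features; crowded
  electropherograms need externally curated index maps.
- Motif-pair IC differences on published matrices depend on which
  database versions are used; the package demonstrates the calculation
  on synthetic and fixture matrices only.
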