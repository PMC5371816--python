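# Methods

## The experimental design being modelled

The package analyses two-timepoint cross-infectivity experiments: each host
strain is grown in triplicate control wells and in triplicate wells
inoculated with each virus strain (virus:host ratio 10, 1 × 10⁵ cells/mL and
1 × 10⁶ particles/mL at t = 0), and cells and virions are enumerated at 0 h
and 72 h.  All concentrations are per mL; time enters the growth-rate
formula in days (72 h → 3.0 d).

## Phenotype metrics

**Growth rate.** µ = ln(N₂/N₁)/t per control replicate, then mean and sd
across replicates.  A noise-free exponential series is recovered exactly;
negative µ (declining controls) is retained.

**Resistance R₁.** For each host–virus pair, the ratio of mean final cells
in the infected wells to mean final cells in the controls, clipped to
[0, 1]; the per-host R₁ is the unweighted mean over all viruses (sd across
viruses is reported for error bars).  The clipped ratio was chosen over a
raw difference because it is bounded, unitless, and reads directly as a
surviving-cell percentage.

**Viral production Vp.** Final minus initial virion concentration per pair,
using the measured t = 0 virion count of that well (nominal 1 × 10⁶/mL as a
fallback when t0 virion counts are absent).  Negative values (passive viral
decay without replication) are retained in all averages, because Vp is
defined as a plain difference.  Per-virus mean and maximum over hosts and
per-host mean and maximum over viruses are derived from the same pair
matrix.

**Binary calls.** The assay itself does not define a lysis threshold, so the
calls are explicit, configurable rules on replicate means:

- lysis(host, virus) = 1 iff mean infected final cells < θ × mean control
  final cells, default θ = 0.75.  The ratio rule is robust for n = 3 and
  makes no distributional assumption; a one-sided Welch t-test variant is
  available (`method="welch"`).
- progeny(host, virus) = 1 iff mean final virions ≥ ρ × mean initial
  virions, default ρ = 1.5 — above plausible counting noise, far below a
  real burst (tens-fold).

Raising θ can only add lysis calls; raising ρ can only remove progeny
calls (tested as a monotonicity property).  R₂ is the row sum of the
progeny matrix; host range is the column sum of the lysis matrix.  Both
matrices are produced; the network analysis defaults to the lysis matrix,
since the infection network is defined by lysis.  Generalist/specialist
splits take the top-k and bottom-k viruses by host range (k = 5 by
default), ties broken lexicographically so the split is deterministic.

## Statistical screens

Pearson r with the two-sided p from t = r√((n−2)/(1−r²)) on n−2 df, and
one-way fixed-effects ANOVA with F = MS_between/MS_within on (k−1, n−k)
df, are computed from the defining formulas; scipy supplies only the t and
F tail areas.  This keeps scipy.stats.pearsonr / f_oneway available as
genuinely independent cross-checks (agreement to 1e-10 in the tests, and
the ANOVA holds its nominal 5% size over 2000 null simulations).  No
multiple-testing correction is applied — the screen battery is reported as
is.  The isolation-year ("domestication") grouping places the boundary year
2009 in the younger group; strains without a year are excluded and
reported.

## Network structure

**NODF.** For an ordered row pair (i, j) with marginal sums k_i > k_j > 0,
the paired term is |shared 1-columns|/k_j; ties in marginal sums and empty
rows contribute zero (strict decreasing fill, the canonical convention).
Column pairs are treated symmetrically, and the total is divided by
n(n−1)/2 + m(m−1)/2, a pure function of shape, giving the 0–1 scale
(a `scale="percent"` flag gives the older 0–100 convention).  Consequences
worth knowing: a perfectly nested matrix with tied marginals scores below
1, and at low fill the untouched-host pairs pull the score down.  NODF is
invariant to row/column permutation and to transposition.

**Barber modularity.** Q_b = (1/m) Σ_ij (A_ij − k_i d_j/m) δ(g_i, h_j).
The one-module partition scores exactly 0 for every matrix, which is the
detector's floor.  The detector recursively bipartitions modules by the
sign pattern of the dominant singular vectors of the modularity matrix
B = A − k dᵀ/m restricted to the module (the bipartite analogue of the
leading-eigenvector method; the sign of the vector pair is fixed by its
largest-magnitude component so results do not depend on the BLAS), accepts
a split only when Q_b strictly increases (tolerance 1e-12), and polishes
candidates with BRIM-style alternating label updates plus a greedy
single-row/column reassignment pass (rows first, label order, with one
fresh module always on offer).  Twelve seeded random restarts are added to
the spectral initialisation because pure recursive bisection can stall at
local optima on small sparse matrices; the whole procedure is deterministic
for a fixed rng seed (default 0).  On every ≤ 12-node matrix in the test
corpus the detector reaches at least 95% of the global optimum found by
`brute_force_modules`.

**Brute-force oracle.** Q_b separates over rows once column labels are
fixed, so the exhaustive search enumerates set partitions of the smaller
side only (restricted-growth strings, at most min(n, m) + 1 modules — more
cannot raise Q_b because single-side modules contribute zero) and assigns
each node of the other side its best module, with one shared spare module
for nodes whose best contribution is negative.  This is exact and makes the
≤ 12-node search effectively instant.  Tie-break: first optimum in
enumeration order; free-side ties go to the lowest label.

**Null model and significance.** The equiprobable null scatters the
observed fill uniformly over all cells; marginals are deliberately not
preserved.  Significance is one-tailed (structure above null) for both
metrics since the hypotheses are directional, with p = (r+1)/(n+1) so 100
nulls bottom out at p = 1/101; a two-tailed flag exists.  For Q_b every
null matrix is scored with its own detector run.  Child rngs are spawned
from the master seed by counter, so a fixed seed reproduces the null vector
bit for bit.  When the null ensemble is degenerate (sd = 0, e.g. the full
matrix), z is reported as NaN while the empirical p remains valid.

## Synthetic data generator

The generator emulates the plate design, not infection kinetics: no latent
period, no multi-cycle growth, no MOI dependence — one infection outcome
per well over 72 h.

- Controls grow as N₀e^{µt} with per-host µ ~ Uniform(0.12, 1.11)/d, the
  span observed across laboratory strains of this alga.
- A successful infection leaves `lysis_survival` (default 0.1) of the
  control's final cells and multiplies the inoculum by a per-pair burst
  factor, lognormal around `burst_fold` = 50 (log-sd 0.5) so that
  production varies across pairs; a failed infection tracks the control and
  decays the inoculum by `decay_fold` = 0.9.
- Every observation carries independent multiplicative lognormal noise with
  CV = `meas_cv` (default 0.10), mean-corrected to 1 — strictly positive,
  the natural error model for cytometry counts.
- Isolation years are uniform on 1990–2015 so both sides of the 2009
  boundary are populated; an optional `year_effect` multiplies burst sizes
  of post-boundary hosts to plant a detectable domestication signal.

**Planted structures.** `make_nested_matrix` draws a random host
susceptibility ranking and virus range sizes, and virus v infects exactly
the r_v most susceptible hosts — perfect nestedness by construction (every
pair of row supports is ordered by inclusion).  Range sizes are spread
evenly over the feasible span at the requested fill, with one
full-coverage generalist when the budget allows, light sum-preserving
jitter, and a tie-breaking pass: tied ranges mean tied marginals, which
strict decreasing fill scores as zero, and untouched hosts likewise score
zero against every partner, so without these steps a "perfectly nested"
draw can score no better than a random one.  `make_modular_matrix` splits
both sides into balanced groups and fills cells Bernoulli(within_p) inside
matched groups and Bernoulli(between_p) elsewhere.  `make_random_matrix`
is a draw from the equiprobable null itself.  The default structure is
nested at fill 0.35 — an intermediate fill consistent with a panel that
contains both fully susceptible and fully resistant hosts and host ranges
from 1 to most of the panel.

`flip_noise` flips each ground-truth cell independently before simulation;
the stored ground truth is the flipped (realised) matrix, so recovery is
scored against what was actually simulated.

**What passing tests show, and what they do not.** With the default noise
(CV 10%) the pipeline recovers the planted matrix essentially exactly,
because the simulated lysed/unlysed outcomes are far apart relative to the
noise.  Real cultures show partial lysis, delayed lysis, and
replicate-scale biological variance that this generator does not emulate;
recovery rates on synthetic data are therefore an upper bound, and the
value of the tests is in checking the estimators' logic, determinism, and
calibration, not in forecasting wet-lab error rates.

## Pipeline determinism and sizes

Every stochastic step takes the run seed; rerunning a config reproduces
every output byte for byte (no timestamps in results; logs go to stderr).
The default full-scale run (49 × 13 × 3 × 2 = 4116 count rows, 100 nulls
for each metric) completes in well under a minute; the test suite uses a
mixture of full-scale fixtures and smaller designs (8–20 hosts) chosen so
each property is exercised at the smallest size where it is informative.

## Known limitations

- The lysis/progeny thresholds are declared defaults, not inferred from
  data; sensitivity to θ and ρ should be checked on real data (the
  monotonicity properties bound the direction of the change).
- NODF significance uses only the equiprobable null, for parity with the
  rest of the analysis; degree-preserving (fixed-fixed, curveball) nulls
  are a noted extension point and typically give more conservative
  verdicts.
- The module detector is a heuristic; its near-optimality is verified
  exhaustively only up to 12 nodes.
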