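# Methods

This note documents the models implemented in `chromaburst`, the defaults
and numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Data model and conventions

Coordinates are nm, genomic positions bp, locus indices 0-based with
0-based half-open 50-kb bins.  Missing observations (hybridization
dropout, uncalled states) are NaN everywhere; all statistics are
pairwise-complete — a chromosome copy contributes to a locus pair only
when both loci were localized on that copy.  On-disk formats are
header-row TSV with a configurable column mapping (`TraceDialect`), so
deposited tables with other schemas can be mapped without touching the
parser.

## Spatial statistics

* MPD/STD matrices use the population STD convention (`ddof=0`,
  configurable) and suppress pairs with fewer than 20 contributing copies
  by default (configurable); the deposited-data schema does not fix these
  choices, so they are package defaults.
* Metagene maps average per-gene promoter-centered matrices with weight
  one per gene (not pooled chromosomes); offsets that leave the
  chromosome are truncated with count bookkeeping.
* The local-centroid window is a total genomic size (half on each side of
  the promoter segment) and includes the promoter's own segment by
  default; both are configurable since the definition is ambiguous at the
  margin.
* Expected MPD is the mean MPD over all locus pairs at each genomic
  separation; its inverse returns the separation with the closest mean,
  breaking ties toward the smaller separation and clamping out-of-range
  queries to the nearest endpoint.
* Contact frequency uses a strict r < 200 nm threshold over copies with
  both loci observed.
* Bootstrap SEMs resample the contributing units (chromosome copies or
  gene pairs) with replacement, 1,000 replicates, seeded; significance
  tests are Welch's two-sample t-test at p < 0.01.
* Gene-activity partitions split at the median fractional occupancy with
  ties going to the low group; locus-density partitions are quartile
  labels, degenerating gracefully to a single group for constant vectors.

## ϕ co-expression

ϕ is computed from the 2×2 contingency table and equals the Pearson
correlation of the binary vectors; cells with a zero marginal are
undefined and reported as NaN, never imputed.  Binned curves use 200-nm
physical-distance bins, 0.5-Mb genomic bins and data-decile
contact-frequency bins (the latter two are package defaults).  The
single-chromosome-distance estimator computes, per gene pair and bin, ϕ
from only the chromosome copies whose distance falls in the bin, and
drops (pair, bin) combinations with fewer than 100 copies.  2D grids
report cell means only when more than 40 observations contribute, and
test each row/column for a trend by a two-sided Pearson correlation of
cell means against bin index (≥3 populated cells required), starred at
p < 0.01.  The trend-test choice is a package default; the underlying
procedure is modular.

## Live-cell dynamics

Relative allele positions R(t) are formed for every unordered allele pair
at shared timestamps, which cancels rigid cell motion exactly.  The MSD
pools squared displacements over all tracks and time origins per lag;
CIs are a bootstrap over tracks.  The diffusion fit is weighted least
squares through the origin with per-lag inverse-variance weights (no
localization-error intercept).  The slope equals 2·d·D_eff; because the
relative motion of two independent alleles doubles the diffusion
coefficient, the reported single-allele D is D_eff/2.  Defaults: 2D
tracks, D = 2.5×10⁻⁴ μm²/s, 3,000-s horizon at 10-s sampling.

## Distance process

The inter-gene distance follows an overdamped Langevin equation whose
drift is empirical: μ(r) = D·d ln Pₛ(r)/dr from the stationary
Fokker–Planck balance, with D the *relative* diffusion coefficient of the
pair (2× the single-locus D, in nm²/s).  Pₛ is estimated on 25-nm
histograms by Richardson–Lucy-type unfolding of the observed histogram
against the analytic localization-error kernel: with per-locus per-axis
error σ, the displacement picks up per-axis variance 2σ² and
r_obs²/(2σ²) is noncentral chi-square with 3 dof — the blur is not
Gaussian in r.  Unfolding runs a fixed 200 iterations (enough to converge
on these smooth, low-dimensional problems) and logs the forward
round-trip residual.  Before differencing, the histogram is floored at
10⁻⁶ of its maximum and ln Pₛ is smoothed with a 5-bin moving average;
boundary drift extrapolates as a constant.  The SDE is integrated by
Euler–Maruyama with dt = 1 s, reflecting boundaries at 0 and r_max
(1.5×–top-of-grid), and the 1D noise amplitude √(2D·dt) exactly as the
distance equation is written.  On smooth targets the integrator's
long-run law matches the target to KS < 0.01; on rough empirical
histograms deconvolved from a few thousand samples, KS distances of
0.03–0.07 are typical because the smoothing in the drift is itself a mild
regularization of the target.

## Co-bursting model

For an ordered pair (P_i ≤ P_j), bursts arrive through three channels
with propensities ω(r)·P_i (co-burst, producing one nascent RNA at each
gene), P_i − ω(r)·P_i and P_j − ω(r)·P_i (individual bursts); each
molecule decays independently at Pd = 1/800 s⁻¹.  Because ω ≤ 1 and the
pair is ordered, all propensities are non-negative at every instant.  A
gene is on at the observation time T = 15,000 s iff its nascent-RNA count
is positive.

**Engines.**  The burst propensities do not depend on the molecular
state, and lifetimes are i.i.d.; the reaction system is therefore exactly
equivalent to three independent inhomogeneous Poisson birth streams with
an independent lifetime per molecule.  The production engine samples that
representation directly: candidate events from homogeneous Poisson
streams at the constant bounds, thinning by ω(r(t)) evaluated on the
1-s distance grid, and survival tests per molecule.  This is an exact
sampler of the same law as a Gillespie simulation with piecewise-constant
propensities, it vectorizes over thousands of trajectories, and it lets
the ω search reuse one set of random draws across all candidate functions
(common random numbers).  A literal event-driven Gillespie implementation
(next-reaction draws, advancing to the next distance-grid boundary when
the draw crosses it) is retained and cross-checked against the vectorized
engine in the tests.

**Calibration.**  The lookup table of on-fraction vs burst propensity is
built by simulating the single-gene birth–death process on a propensity
grid in [0, 0.05] s⁻¹ (2,000 trajectories × 15,000 s by default); all
grid values share one candidate stream, which makes the tabulated curve
monotone by construction.  Inversion takes the nearest tabulated
fraction, ties toward the smaller propensity.  The closed form
P(on) = 1 − exp(−P_tot/Pd) is used in the tests as the independent
oracle, never inside the calibration.

**Resolution error** decomposes a true distance onto an isotropic random
3D direction, perturbs each axis with variance 2σ² (σ = 100 nm per
locus), and recomposes the norm, so E[r_obs²] = r_true² + 6σ².

**ω search.**  ω is a monotone non-increasing step function on 200-nm
bins, zero beyond a configurable cutoff (default 1,400 nm — exhaustive
enumeration over all monotone functions at 17+ bins is combinatorially
infeasible, and the coupling of interest is short-range).  The error is
the unweighted sum of |ϕ_sim − ϕ_obs| over pairs and populated distance
bins, with simulated curves produced by the same estimator and binning
rules as the experimental ones.  The coarse stage works on a 0.1 grid:
an exhaustive sweep over constant-plateau shapes (level × cutoff)
initializes a greedy coordinate descent — the plateau initialization
keeps the descent from over-fitting the first bin before later bins have
moved.  The refinement stage adjusts bins below 1,000 nm in ±0.05 steps.
Exhaustive enumeration is available for ≤6 bins and is used as a
cross-check in the tests.

**Identifiability.**  With 100-nm localization error, observed 200-nm
bins below the smearing scale mix true distances from a range of ±2σ√2,
so neighboring ω bins trade off against each other; at a few thousand
chromosomes per pair only their short-range aggregate is determined,
while per-bin values need either many more pairs or noise-free
distances.  The parameter-recovery test therefore runs the planted study
with exact distance observation (the resolution-error machinery is
validated separately by its moment identities and by the noise-removal
experiments), and the analysis scripts report the short-range aggregate
alongside the per-bin fit.

**Noise removal.**  Four variants re-simulate a fitted ω: all noise
(distance diffusion + localization error + stochastic on times); binning
on true rather than observed distances; additionally fixed 800-s on
times (making co-burst partners' survival perfectly correlated);
additionally frozen distances drawn from the steady state.  Curves are
per-pair ϕ-vs-distance under the shared estimator, averaged over pairs.

## Synthetic data

The generator emulates: polymer-like growth of inter-locus distance with
genomic separation (freely-jointed Gaussian chain, per-step RMS 300 nm —
chosen so adjacent 50-kb segments sit a few hundred nm apart, with
median pair distance scaling as separation^0.5), independent per-locus
Bernoulli dropout (default 10%; the compact co-burst study uses 5%),
per-axis Gaussian localization error (σ = 100 nm), distance-dependent
co-bursting with a known planted ω applied pairwise to designated gene
pairs at each copy's frozen true promoter–promoter distance (remaining
genes burst independently), exponential nascent-RNA lifetimes (mean
800 s) and independent 2D Brownian allele tracks.

It does not emulate: excluded volume, TADs or loop extrusion, coupling
between conformation and transcription beyond the planted ω (no
activity-dependent repositioning by default), temporal distance dynamics
during the fixed-cell snapshot (states are planted at frozen distances),
imaging artifacts beyond Gaussian localization error, or missingness
correlated with state or position.  Passing tests therefore demonstrate
estimator correctness under a known generative law, not the biological
accuracy of that law; the chain model is a stand-in for the unknown
generative process of real traces.

`coburst_study_config` packages the compact planted study used across
the tests and analysis scripts: 3,000 chromosome copies, three gene pairs
at 1–2-bin genomic separations (so the distance mass sits in the first
few 200-nm bins, where a short-range coupling must be identified), burst
propensities at 0.3–0.5×Pd (on-fractions 0.25–0.4, near the maximum of ϕ
signal per unit coupling).

## Pipeline

`run_pipeline` executes simulate → spatial → coexpr → msd →
distance-model → coburst from one validated YAML config; per-stage
sub-seeds are derived by hashing (global seed, stage name) so any stage
is reproducible in isolation; the manifest records versions, seeds, a
parameter hash and per-stage outputs, and contains no timestamps so
reruns are bit-identical.  A stage whose inputs are missing (e.g. its
producer was toggled off) aborts with a dependency error naming the
stage; partial outputs are retained.

## Problem sizes

Desk-scale defaults throughout: studies of ~3,000 chromosomes and ≤7
ω bins, searches at 40,000 simulated trajectories per pair (common
random numbers make candidate comparisons much tighter than the absolute
noise level), stationarity checks on 10⁶ pooled samples from 2,000
parallel chains, and 50-cell live-cell simulations.  These sizes were
chosen so each analysis answers its statistical question with margin
while remaining interactive on a laptop.

## Known limitations

* ω is phenomenological; the package deliberately does not model what
  produces the coupling.
* The pairwise co-burst model does not capture higher-order (3+ gene)
  co-bursting; planted activity applies ω pairwise to a designated pair
  list.
* The empirical-potential distance model reproduces the steady state by
  construction but borrows its timescale entirely from the measured
  diffusion coefficient; viscoelastic memory is not modeled.
* Per-bin ω recovery under full imaging noise requires many more gene
  pairs than the desk-scale study contains (see Identifiability above).
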