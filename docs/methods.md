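# Methods

This note documents the models, conventions and numerical choices
behind `larvakin`, and what its synthetic validation does and does not
demonstrate.

## Kinematics extraction

Input is tracker output: per larva and frame, the centroid position
(pixels) and the body bend angle (degrees, 0 = straight), at a frame
rate of 5 frames/s and an image scale of 0.13 mm/pixel (both
configurable metadata of the `TrackTable`).

**Filtering.** A larva is retained only if its longest contiguous run
of frames is *strictly greater* than `min_frames` (default 300, i.e.
1 min; 150 for intraspecific comparisons), and is truncated to that
run.  Traces split by collisions carry distinct ids and count as
distinct larvae.

**Smoothing.** Centroid coordinates are smoothed with a centered
uniform window (default 5 frames) before speed computation; the window
shrinks symmetrically at the edges so the output stays centered and
length-preserving.  Smoothing exists to suppress pixel-quantisation
jitter in the speed estimate; it can be disabled (`smooth=False`).
Whether to smooth before computing speeds (rather than only for
display) is a convention of this package and is therefore exposed as a
flag.

**Labels and statistics.** A frame is *bending* iff |bend angle| is
strictly greater than the threshold (default 20°, either side); a bend
of exactly the threshold counts as crawling.  Per larva:

* bend probability = bending frames / total frames;
* crawling speed = median centroid speed over crawling-labelled frames
  (mm/s).  A whole-trace variant (`crawling_speed_scope="whole"`) is
  available because both definitions are defensible; the
  crawling-frames definition is the default used in species
  comparisons;
* crawling distance (1 min) = mean over non-overlapping 300-frame
  windows of the straight-line displacement between window start and
  end (mm).  The straight-line (not path-length) geometry is chosen
  because frequent bending shortens directed progress, which is the
  quantity of ecological interest;
* backward crawling = a bout of ≥ 10 consecutive frames (configurable)
  whose frame-to-frame displacement projects negatively on the
  tail-to-head axis while the speed exceeds 0.1 mm/s.  Head/tail
  coordinates are required; without them the flag is undefined rather
  than false.

Species summaries report the median and s.e.m. (sample sd/√n; 0 for a
single larva) of each per-larva statistic, and the backward fraction
p with binomial standard error √(p(1−p)/n).

## Divergence clustering

Pooled per-frame (speed, |angle|) points are binned into half-open
cells on a fixed grid: speed [0, 4) mm/s in 0.1 mm/s steps × angle
[0, 140)° in 2° steps, 2800 cells.  Points at or beyond the upper
limits are dropped and counted (`dropped_out_of_range`).  The angle
axis uses |bend angle| since the grid spans only non-negative angles.

A pseudocount ε (default 1e-9) is added to every cell before
normalisation.  KL(p,q) = Σ p ln(p/q) is undefined when q has an empty
cell on p's support; ε makes all divergences finite while perturbing
occupied-cell probabilities negligibly.  The symmetrised divergence
JS(p,q) = ½[KL(p,q)+KL(q,p)] is used for clustering; note this is the
symmetrised-KL form (unbounded), not the mixture-based
Jensen–Shannon variant.  Natural logarithms throughout (nats).

Agglomerative clustering runs on the pairwise JS matrix with average
linkage (UPGMA) by default; single and complete are available and the
linkage used is recorded.  The dendrogram exports to Newick with branch
lengths equal to merge-height differences.

## Habitat temperature

Rasters are ESRI ASCII grids (one layer each for annual minimum, mean
and maximum temperature); habitat masks are co-registered boolean
grids.  Masked values are binned at 1 °C (aligned to integer
multiples).  Tave and Tmax are the modes of the mean- and max-layer
histograms (ties break toward the warmer bin).  Tmin is the *warmest
peak* of the min-layer histogram: counts are smoothed (3-bin centered
average), local maxima are bins strictly above both neighbours
(plateaus take the warmest index; the warm boundary is zero-padded so a
peak truncated by the warm edge of the data range still counts), peaks
below 5% of the global maximum are discarded, and the warmest survivor
wins.  If no peak survives (e.g. a monotone-decreasing histogram) the
mode is used with a warning.  The warmest-peak summary exists because a
habitat extending into subarctic regions can have a sub-zero global
mode that does not represent where most of the population lives.
Bin width, smoothing window and prominence fraction are conventions of
this package (recorded in the output) — the choice of peak criterion is
genuinely open and results near the prominence floor depend on it.
The habitat temperature range is Tmax − Tmin; a negative range is
flagged, not fatal.

## Statistics

Pearson r comes with a Fisher-z 95% CI, tanh(atanh r ± 1.96/√(n−3)),
and a two-sided p from t = r√((n−2)/(1−r²)) on n−2 df.  The regression
band is the pointwise OLS confidence band for the mean response at
level 95%.  Kruskal–Wallis uses mid-ranks with tie correction and a
χ²(k−1) p value; one-way ANOVA is the standard F test.  Mann–Whitney U
uses the exact null distribution when n_a·n_b ≤ 400 and the pooled
sample is tie-free (the tie-free exact recurrence is invalid under
ties), otherwise the tie- and continuity-corrected normal
approximation.  Bonferroni adjustment is min(1, p·m), with m = 4 in
the habitat analysis (larval length, Tave, Tmax, Tmin).

## Brownian trait evolution

**Model.** Species-level traits are positive; each trait is
log-transformed, Z = ln(x + δ), with δ = 0 for traits without zeros
and δ = half the smallest positive observed value for traits containing
zeros (per-trait, configurable) — probabilities such as backward
crawling can be exactly zero and the additive-diffusion model needs
finite logs.  Tip values follow a matrix normal:

    vec(Z) ~ N(1 ⊗ μ, Σ ⊗ C(r)),

where C(r)[i,j] sums r_b·t_b over branches shared by the root-to-tip
paths of i and j (relative-time branch lengths t_b; the root edge is
excluded), and Σ = σ²·diag(√v)·R·diag(√v).

**Identifiability.** The likelihood is invariant under r → c·r,
σ² → σ²/c.  The relative trait rates v are therefore constrained to
mean 1 (scaled-Dirichlet prior), and σ² carries its own Lognormal(0,1)
prior; branch rates are identified through their informative relaxed-
clock prior.  Reported "relative evolutionary rates" per trait are the
variance scales v_k.

**Priors.** Branch rates: i.i.d. Exponential(λ), default λ = 10
("UCED"), or Gamma(α, α) with mean 1, default α = 2 ("UCG").
Correlation matrix: LKJ(η = 1), i.e. uniform over valid correlation
matrices.  Root state: Normal(per-trait data mean, 10 × data sd).

**Sampler.** Blockwise Metropolis–Hastings.  R is parameterised by
C-vine partial correlations mapped through tanh from unconstrained
coordinates, so every proposal is a valid correlation matrix; the
target in that space is the exact LKJ pushforward (layer-wise Beta
densities plus the tanh Jacobian).  Moves per sweep: multiplicative
random walk on each branch rate and on σ², a mass-preserving pair move
on v, coordinate-wise random walks on the vine coordinates, Gaussian
slides on μ.  Proposal scales adapt toward ~30% acceptance during
burn-in only (preserving detailed balance afterwards).  Likelihood
evaluations cache the Cholesky factor of C and the cross-product
M = (Z−1μᵀ)ᵀC⁻¹(Z−1μᵀ), so trait-side moves cost O(k³) and rate moves
O(n³) with n, k ≤ ~11, 8.  Defaults: 2 chains, 4000 sweeps, 25%
burn-in, thin 5; seeds are mandatory.  Diagnostics: per-block
acceptance rates and autocorrelation-based ESS (a warning is attached
when any monitored ESS falls below 100).

Prior-only runs (likelihood switched off) reproduce the analytic prior
moments — exponential and gamma branch-rate means, the Lognormal σ²
moments, and the uniform LKJ marginals — which validates the Hastings
ratios and the vine density independently of any data.

**Summaries.** Posterior means and 95% HPD intervals (shortest
contiguous interval containing ⌈0.95·n⌉ sorted draws) for branch
rates (annotated onto the Newick tree as `[&rate=...]`), relative
trait rates and pairwise correlations.

## Synthetic generators and what they show

**Tracks.** A run-and-bend model: bend events arrive as a Poisson
process (rate `bend_rate`/s); each event bends the body as a half-sine
pulse with Normal-sampled amplitude (s.d. 15% of the mean, floored at
30%) and Gamma(2)-distributed duration, slows the centroid
(multiplier 0.3), and turns the heading by half the pulse amplitude.
Between events the bend angle is uniform jitter below 5° and the
centroid advances at a per-run Normal-sampled speed while the heading
diffuses (Gaussian increments, rad²/s).  Backward bouts reverse the
centroid's motion relative to the (unchanged) body axis for a 10-frame
window.  For a pulse of amplitude A the angle exceeds a threshold θ
for a fraction 1 − (2/π)·asin(θ/A) of its duration, which gives the
planted bend-probability expectation.  Within-larva speed variability
and bend-duration shapes are conventions: the real distributions are
not reported, so recovery tests certify the extraction arithmetic, not
distributional realism of larval behaviour.

**Species panel.** Each of n species (default 11) draws a habitat Tmin
uniformly at random in [0, 25] °C (sorted); bend rate falls linearly
from 0.60/s at 0 °C by 0.022 per °C and run speed rises from
0.95 mm/s by 0.020 per °C, each with 5% lognormal noise — spanning
roughly the observed range of bend probabilities (~0.36 down to ~0.01)
and crawling speeds (~0.95–1.45 mm/s) across the real species.
Defaults: 24 larvae × 900 frames per species (3 min at 5 frames/s),
matching the per-species sample sizes of the study design.  Random
(rather than evenly spaced) Tmin assignment is essential for the
clustering check: it usually creates one distinctly most-similar pair,
whereas an even grid creates near-ties.  Some panel draws still yield
near-tied similar pairs; for those, the identity of the first merge at
study scale is effectively random among the tied pairs, which is why
the end-to-end outputs report the first merge's *rank* in the
population similarity ordering alongside the exact-match indicator.

**Ground truth for the clustering check.** "The two most behaviourally
similar planted species" is defined on the same scale the clustering
uses: the JS divergence between the species' population kinematic
distributions, approximated by re-simulating each species' parameters
at 96 larvae × 1500 frames with an independent seed.  Distance in
(bend, speed) parameter space is *not* a faithful proxy — JS between
sharply peaked (warm, low-bend) distributions grows much faster per
unit parameter change than between broad (cold, high-bend) ones.

**Climate rasters.** A north–south gradient minimum-temperature field
(mean and max layers offset +8/+18 °C) with rectangular boolean masks;
a designated mask can plant a bimodal minimum-temperature mixture (cold
mode −5 °C, warm peak +12 °C by default, s.d. 0.3 °C) with known peak
locations, exercising the warmest-peak extractor.

**Brownian traits.** Tips are drawn exactly from the matrix normal via
the symmetric square root of C and the Cholesky factor of Σ, so
moments can be checked against the analytic covariance and the MCMC
against planted parameters.

## Validation scale and limitations

The bundled 11-species tree uses the accepted genus topology but
*synthetic* relative-time branch lengths (root depth 1); it is a test
fixture, not an inferred chronogram.  Parameter-recovery runs use
n = 11 tips and k = 3 traits with 1500-sweep single chains (50
replicates), panel studies use 11 species × 24 larvae × 900 frames, and
calibration checks use 1000 null simulations — sizes chosen so the
full validation runs comfortably on a laptop while leaving the
estimates' Monte Carlo error well inside the asserted tolerances.
With n = 11 species the correlation posterior is diffuse and visibly
shrunk toward zero by the LKJ prior; coverage and sign, not point
accuracy, are the meaningful recovery criteria at this size.  Passing
synthetic tests certifies the pipeline's arithmetic and its Bayesian
calibration under the generative model; it cannot certify tracker
artefacts, habitat-polygon quality, or model adequacy on real data.
Reproducing the published per-species numbers requires the deposited
tracking data, which is not redistributed here.
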