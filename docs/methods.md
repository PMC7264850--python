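# Methods

## The problem

`hzclines` analyzes hybrid zones — geographic regions where two diverged
taxa meet and interbreed — through geographic clines: the change in an
allele frequency or a trait mean along a transect crossing the zone. The
motivating system is the Joshua tree contact zone (*Yucca brevifolia* in
the west, *Y. jaegeriana* in the east, with their respective yucca-moth
pollinators *Tegeticula synthetica* and *T. antithethica*), but every
stage is generic: any two-taxon zone with biallelic markers, a binary
cytoplasmic haplotype, quantitative traits and optional pollinator
counts fits the pipeline.

## Transect construction

Trees are sampled in two dimensions, so the first step flattens the zone
onto a single signed axis.

1. **Projection.** Geographic coordinates are projected onto a local
   planar frame by an equirectangular projection about the centroid
   (`x = R Δlon cos(lat̄)`, `y = R Δlat`, R = 6,371,000 m). Over the
   tens-of-kilometres extents of a hybrid zone the distortion is
   negligible; geodesic accuracy is a non-goal.
2. **Center line.** The hybrid index q (proportion of ancestry from the
   eastern taxon) is interpolated over a regular grid with a thin-plate
   radial basis function (`scipy.interpolate.RBFInterpolator`, one
   smoothing knob, default 1e-3), and the 0.5 iso-contour is traced by
   marching squares (`skimage.measure.find_contours`). The longest
   connected polyline is kept. A thin-plate spline was chosen over
   kriging because it is a smooth exact-interpolating surface with a
   single tunable parameter, which is all iso-contour extraction needs;
   the contour, not the surface, is the product.
3. **Signed distance.** Each tree maps to its shortest Euclidean
   distance to the contour polyline, negative on the side of a
   reference point (the centroid of the western parental pool), so the
   western taxon occupies negative distances. The side of a point is the
   sign of the cross product at its nearest contour segment.
4. **Binning.** Bin edges sit every 250 m (configurable) from the
   minimum distance. Bins with fewer than 3 trees are merged
   iteratively — the deficient bin nearest distance 0 merges with
   whichever neighbor is nearer 0 (ties to the smaller one) — so bins
   stay most granular where the action is. Bin position is the mean
   distance of member trees. The bins are computed once, from the
   genotyped trees, and reused for every character, so all clines share
   one set of standard bins.

## Cline models

The unit-scale cline shape is a logistic in signed distance d,

    Φ(d) = 1 / (1 + exp(−4 (d − c) / w)),

with center c (inflection point, m) and width w (inverse of the maximum
slope, m). Three families:

* **Model I** (4 free parameters): the plain logistic, plus the two
  asymptotic values.
* **Model II** (6): symmetric exponential introgression tails. At
  attachment points a = c ± δ the curve continues as an exponential
  approach to the parental value: on the left
  `Φ(a_L) exp(λ_L (d − a_L))` with `λ_L = τ Φ′(a_L)/Φ(a_L)`, mirrored
  on the right. δ ≥ 0 (m) sets where the tail attaches; τ ∈ (0, 1] is
  the ratio of tail slope to sigmoid slope at the attachment. The join
  is continuous for all (δ, τ) and C¹ when τ = 1; smaller τ means a
  shallower, longer tail.
* **Model III** (8): independent (δ, τ) per side — asymmetric
  introgression.
* **Null** (2): a straight line between the transect endpoints (no
  cline).

Values map to the data scale through pmin (western asymptote) and pmax
(eastern); decreasing clines are encoded by pmin > pmax rather than by
reflecting the axis. ΔP = |pmax − pmin| measures how differentiated a
character is across the zone.

The tail parameterization is the Szymura–Barton-style convention used
throughout the cline-fitting literature. Exact algebraic equivalence to
any particular software's internal form is not claimed; curve shape,
nesting structure and parameter counts are what the analyses rely on.

### Likelihoods

Frequency characters (SNPs, a haploid haplotype, moth species counts)
use a per-bin binomial likelihood of the focal-allele count, with fitted
frequencies clamped to [1e-6, 1 − 1e-6] so fixed ends (a chloroplast
cline reaching 1.00) keep the log-likelihood finite. Trait characters
use a Gaussian likelihood of the bin mean with variance v_i/n_i from the
within-bin variance; bins with n < 2 fall back to the pooled within-bin
variance. Traits are first transformed (log for tree height, square root
for trunk height, per the conventional transforms for these traits) and
min–max standardized to [0, 1], with the (transform, min, max) triple
retained for exact inversion.

## Fitting and model choice

Each family is fitted by random-walk Metropolis–Hastings on transformed
scales (log for w and δ, logit for τ/pmin/pmax, identity for c) with
uniform priors inside box bounds (c within the data span ± one span;
w ∈ (1 m, 10 span]; δ ∈ [1 m, 5 span]). Chains start from small
perturbations of a coarse grid-search optimum; a global proposal-scale
factor adapts toward 25% acceptance during burn-in and then freezes, so
runs are deterministic per seed. The reported fit is the
highest-likelihood visited state, refined by a Nelder–Mead polish.
Convergence is monitored by the Gelman–Rubin statistic across chains
(advisory warning at R̂ ≥ 1.1, never silently accepted). Defaults are 3
chains × 1e5 steps (1e4 burn-in, thin 10), suitable for a final run;
the recovery experiments in the test suite use 2 chains × 3000 steps,
which the experiments themselves show is sufficient for 19-bin tables.

**Support intervals.** The 2-log-likelihood interval of a parameter is
the min/max of that parameter over all retained states whose
log-likelihood is within 2 units of the maximum — the superlevel-set
reading of an approximate 95% interval. Finite chains almost never
visit the profile ridge of a ≥4-parameter likelihood, so the raw sample
projection badly understates the superlevel set (measured ~84 m vs
~500 m interval width on model-I recovery fixtures). The fitter
therefore traces the profile likelihood of each parameter (expanding
search with bisection refinement; nuisance parameters re-optimized by
warm-started Nelder–Mead) and appends those states to the sample pool
before interval extraction. If profile tracing finds a better optimum
than the chains (possible on sharply peaked trait likelihoods), that
state becomes the reported estimate, keeping the interval consistent
with the fit.

**Model choice.** Frequency characters: null, I, II and III are all
fitted and compared by AIC = 2k − 2 lnL (k = 2/4/6/8); the lowest AIC
wins, except that the simplest model wins whenever ΔAIC < 2. Trait
characters: an ordinary linear regression of bin mean on distance gates
the analysis — a slope with p ≥ 0.05 declares "no cline" — otherwise
I/II/III compete by AIC. This frequentist-gate-for-traits /
AIC-null-for-frequencies asymmetry is deliberate; it mirrors standard
hybrid-zone practice. Bin means are also screened by a Shapiro–Wilk
advisory (α = 0.01, warning only — some characters, like a bimodal
species frequency, are legitimately fitted untransformed).

## Comparing clines

Two clines differ significantly in a parameter when their 2LL intervals
are disjoint; touching endpoints count as overlap (the conservative
convention). The pairwise yes/no matrix is reported without
multiple-testing correction (deliberately — the analysis is
descriptive, and interval overlap is not transitive). Category
summaries (e.g. high-FST SNPs, random SNPs) exclude null-model clines
from means of center/width/ΔP but report their count and the fraction
of each model type chosen. A single cline is compared against a
category through the 2LL interval of the category's *representative*
fit — the non-null fit whose center is the category median — because a
category mean has no likelihood interval of its own; offsets are
classified west/east by the sign of the disjoint difference.

## Hybrid classes

For each individual, over its non-missing loci: hybrid index
HI = (focal-allele count)/(2 × loci) and interclass heterozygosity
H = fraction of heterozygous loci, where the focal allele at each locus
is the allele commoner in the designated eastern pool (the orientation
key is written as a sidecar so HI is reproducible). H ≤ 2 min(HI, 1−HI)
exactly, for any genotype — the triangle constraint.

Because real marker panels are semi-diagnostic, expected class
distributions come from in-silico crosses of empirical parental pools:
each offspring draws one parent per pool uniformly with replacement,
and each parent contributes per locus one of its two alleles chosen
independently (free recombination, r = 0.5; a missing parental locus
propagates). F1 = west × east, F2 = F1 × F1, and the two first
backcrosses, 500 simulated individuals per class by default. With fully
diagnostic pools the F1 cloud collapses to the analytic corner
(HI, H) = (0.5, 1.0) exactly.

Assignment is the minimum squared Mahalanobis distance to a class
cloud, admitted only below the χ²(2 df, 0.99) quantile; everything
beyond every gate is "advanced/unassigned". This replaces visual
overlap in a triangle plot with a formal, testable rule; the gate
quantile is configurable. Because the simulation assumes free
recombination, tightly linked markers would make advanced classes look
earlier-generation than they are.

## Pollinator host choice

Hybrid index and transect distance are strongly collinear in a clinal
zone, so the analysis reports both a Pearson correlation between them
(with t = r sqrt(df/(1−r²)), df = n − 2) and a binomial logistic
regression of per-tree moth species counts on hybrid index and
distance, fitted by IRLS through statsmodels. Complete separation
raises an explicit error rather than returning a silently huge
estimate; near-collinearity raises a condition-number warning but does
not block. The aggregated per-tree counts encoding and a per-moth
Bernoulli long format give identical binomial estimates.

## Synthetic data generator

The generator is first-class, tested code: it draws zones with known
ground truth so every stage has a parameter-recovery surface.

* Trees are placed uniformly over a 16 km × 4 km extent (real sampling
  is opportunistic; uniformity makes calibration checks exact). An
  optional excluded band mimics a low-density gap (a dry lakebed west
  of the motivating zone); off by default.
* The center line is a straight line or a sinusoid (amplitude 800 m,
  period 4 km by default); the hybrid index follows a model-I cline in
  signed distance, default width 2236.39 m (the magnitude reported for
  the motivating zone's hybrid-index cline).
* SNPs (default 84, the size of the motivating high-differentiation
  panel) are semi-diagnostic: parental frequencies 0.02/0.99, per-locus
  centers jittered N(0, 300 m) and widths log-normally (sd 0.3) around
  the zone cline; a configurable fraction of loci are flat "null" loci
  at a frequency drawn U(0.25, 0.75). Genotypes are Binomial(2, p(d)),
  independent across loci (free recombination — consistent with the
  class simulation).
* The chloroplast haplotype follows its own steep, offset cline
  (default center −852 m, width 276.4 m, pmin 0.02, pmax 1.0 —
  cytonuclear discordance built in).
* Traits have clinal means on the zone sigmoid with Gaussian noise
  (style length 10→4 ± 1; tree height 8→3 ± 0.8, log transform; trunk
  height 1.5→0.3 ± 0.25, sqrt transform). Draws are floored at 0.01 so
  transform domains hold; the defaults keep means ≥ 3 sd from zero, so
  the floor is essentially never hit.
* A flowering subset (default 25%) receives Poisson(5) trapped moths
  whose species is Bernoulli with log-odds intercept + 6 q + 3e-4 d.
  The intercept default −3 centers the species transition at the zone
  center, matching the strong-genotype/weak-location pattern the method
  is designed to detect. Only species *frequencies* are modeled in the
  field; trap totals are a free choice.
* Missingness is uniform at random per call, default 0.

What the generator does **not** emulate: linkage disequilibrium, drift
or migration dynamics (no forward simulation), spatially clustered
sampling, measurement error structure beyond i.i.d. Gaussian noise, and
moth dispersal. Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the model's own
assumptions, not robustness to violations of them.

## Numerical choices

* Frequency clamp 1e-6 in the binomial likelihood (fixed cline ends).
* Tail exponents clipped at −745 before exponentiation (IEEE underflow).
* Proposal reflection at transformed bounds (symmetric, preserves
  detailed balance); adaptation only during burn-in.
* Degenerate class-cloud covariances receive a 1e-6 ridge.
* Ties in bin collapse go to the smaller neighbor; zero-span tables put
  all trees in one bin.
* All TSV output uses "%.10g" floats, tab delimiter and "NA" missing
  token, so identical configurations reproduce byte-identical files.

## Experiment sizes used by the test suite

Recovery experiments run at 19 bins × 40 alleles (100 replicates,
2 chains × 3000 steps) for center recovery, and 50 replicates per
scenario for model selection. The strong-tail scenario samples 19 bins
laid out densely through the center with far bins at ±3.5–15 km,
because introgression tails are only identifiable when the transect
extends several decay lengths beyond the attachment points — a uniform
±5 km layout leaves models I and II statistically indistinguishable at
these sample sizes.

## Known limitations

* The mapping between this package's (δ, τ) tail parameters and other
  software's printed tail parameters is conventions-dependent; compare
  curve shapes, not raw parameter values.
* The 2LL interval is a likelihood support interval, not a posterior
  quantile interval; the two coincide only asymptotically.
* Contour estimation near the convex-hull boundary of the sampled
  points is extrapolation and can wobble; the tests evaluate the
  contour core away from the data edge, and so should users.
* The pipeline assumes one connected zone center; multiple disjoint
  contact fronts would be truncated to the longest contour component.
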