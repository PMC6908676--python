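# Methods

This note documents the models and procedures implemented in `divspace`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions a maintainer should
know about.

## Diversity model

Diversity is the similarity-sensitive Hill number of Leinster & Cobbold:
for relative abundances *p* over a species pool and a similarity matrix
*Z*, the "ordinariness" of species *i* is (Zp)ᵢ = Σⱼ Zᵢⱼ pⱼ, and

D_q = (Σᵢ pᵢ (Zp)ᵢ^(q−1))^(1/(1−q)),

with the analytic limits at q = 1 (exponential of the similarity-weighted
Shannon entropy) and q = ∞ (reciprocal of the maximal ordinariness).
Species with pᵢ = 0 are excluded from the outer sum and from the max at
q = ∞; q-values near 1 are not special-cased because the expression is
numerically stable away from the limit itself. D is an effective number:
1 ≤ D ≤ number of species present, and D is non-increasing in q. Rao* =
1/(1 − Q) (Q = Σᵢⱼ pᵢ pⱼ (1 − Zᵢⱼ)) equals D₂ algebraically; the package
implements both routes and the tests require agreement to 1e−10.

### Similarity construction

Both trees are ultrametric with total depth normalized to 1 (root at
depth 0, tips at depth 1). The similarity scale parameter δ raises every
node depth to the power δ. This matches the qualitative behaviour the
scale parameter is meant to have — δ < 1 inflates deep, close-to-root
branches, δ > 1 inflates shallow ones — and the δ → ∞ limit is handled
analytically as the rake (star) tree rather than by a large finite
exponent, so no overflow can occur. A node pinned at depth 1 (duplicate
species with identical traits) stays at depth 1 in the limit. Transformed
trees are *not* re-normalized: depths stay in [0, 1] by construction, and
re-normalizing would silently change the relative emphasis the transform
creates.

Cophenetic distances are dist(i, j) = 2·(1 − depth of the MRCA). The
functional and phylogenetic distance matrices are each scaled to maximum
entry 1 *at the species-pool level* before blending, so that the type
weight *a* mixes comparable quantities; the blend is

FPDist = (a·FDist² + (1 − a)·PDist²)^½,  *a* = trait weight,

and the combined matrix is scaled to maximum 1 again before conversion to
similarity Z = 1 − distance. Scaling at pool level (not per community)
keeps diversity comparable across communities and bins, which the
downstream regressions require. Subsetting the pool-level Z to a
community's members is then exactly equivalent to subsetting the distance
matrices first — an invariant covered by the tests.

On the convention for *a*: the blend is sometimes written with the weight
on the phylogenetic term. Here *a* is consistently the **trait** weight
(a = 1 ⇒ purely functional, a = 0 ⇒ purely phylogenetic), which is the
reading used everywhere in the package's outputs and plots.

### Trees

* **Functional dendrogram** — traits are log-transformed, standardized to
  zero mean / unit variance (n−1 denominator), distanced by Euclidean
  metric and clustered by UPGMA. Species are sorted lexicographically
  before clustering so merge-order ties resolve reproducibly. When the
  input distances are already ultrametric, the UPGMA cophenetic distances
  reproduce them exactly.
* **Phylogeny** — a genus-level ultrametric tree is expanded to species
  level by replacing each genus tip with a random Yule-topology subtree
  (uniformly chosen lineage splits). Split depths are uniform order
  statistics on (parent depth, 1): the pure-birth process conditioned to
  fit inside the terminal branch is well approximated by this and it
  guarantees the expanded tree is exactly ultrametric at the original
  depth. Expansion is seeded so replicate phylogenies are reproducible;
  diversity is averaged arithmetically over replicate phylogenies (on the
  diversity values, not the trees).
* **Mantel test** — Pearson correlation over strictly-lower-triangle
  entries; one-sided permutation p-value with the +1 correction,
  permuting rows and columns of one matrix simultaneously.

## NDVI proxies

Productivity is the mean interannual NDVI: a penalized cyclic cubic
regression spline of NDVI on Julian day (basis dimension 5) plus a
categorical year effect, Gaussian errors, fitted to quality-filtered
records ('clear' flag, NDVI in [−1, 1]). The fitted curve is averaged
over days 1–365 with the year effect averaged equally over observed
years; years with fewer than 3 usable records are dropped from the year
factor to avoid unstable levels. Land-use intensity is the mean absolute
residual of a low-rank smooth (basis dimension 3, quadratic B-splines) of
growing-season NDVI on Julian day: mowing/grazing/manuring produce abrupt
deflections the stiff smooth cannot follow. The growing-season window is
an explicit per-plot input (start, end Julian days); no year term enters
the land-use model. Smoothing weights are selected by generalized
cross-validation on a log-spaced grid (penalty applied per observation,
so the fit is invariant to duplicating the series); the spline bases come
from statsmodels, the penalized solve is a direct ridge computation.

## Community preparation

Ordinal coverage classes are converted to percentage midpoints; the
default table is Braun-Blanquet-style (0.5, 3, 15, 37.5, 62.5, 87.5%) and
is a configuration item, not a constant. Totals above 100% are retained
(layered vegetation). The quality filter applies four criteria in order —
complete sampling with ≥ 10 species; geo-positioning SE ≤ 10 m; total
coverage strictly between 30% and 250%; species with complete trait data
contributing ≥ 80% of total coverage — and records the first failed
criterion per plot in an audit log. Filtering is idempotent.

Ecosystem types are assigned from species habitat affinities: a plot is
forest if forest-typical species contribute ≥ 0.5 of coverage while
grassland-typical species stay < 0.25 (symmetric for grassland; otherwise
"other"). The thresholds are configurable defaults, chosen as the
simplest dominance/exclusion rule; the audit records the fractions used.

Plots are binned on NDVI with the fixed edges −0.04, −0.02, …, 0.32
(18 bins), half-open [lower, upper) with the last bin closed — the
half-open convention is a deliberate resolution of boundary membership.
A 5%-quantile binning is available as a sensitivity alternative.
Land-use tertiles split grassland intensities at the empirical 1/3 and
2/3 quantiles with boundary ties going to the lower class. Bootstrap
samples (default 100 replicates of 40 plots per bin; 20 for land-use
strata) are drawn without replacement by shuffled greedy accept/reject
under the constraint that all pairwise distances are ≥ 5 km (enforced
within each replicate; 1000 attempts per replicate before a bin is
dropped and logged).

## Response fitting and classification

For each (a, δ, q), replicate-level points (one pooled community per bin
× bootstrap replicate; coverage-summed abundances) are fitted as a
penalized smooth of **log** diversity on NDVI with basis dimension 3 and
Gaussian errors — effective numbers are positive and right-skewed, so the
log transform is used rather than an integer-count family. R² is the
explained variance after back-transforming fitted values to the diversity
scale by naive exponentiation (no variance correction), unadjusted.
Curves are predicted on 200 evenly spaced NDVI values over the observed
range and classified by ordered rules: R² < 0.15 ⇒ ns; interior maximum
⇒ concave−; interior minimum ⇒ concave+ *only if* predictions at both
edges exceed the minimum by 25% of the predicted range (this guards
against stiff smooths mislabeling exponential-like increases); otherwise
increasing / decreasing by which edge holds the maximum. "Interior"
means strictly between the first and last grid points; exact ties at an
edge count as edge. Classification is invariant to increasing affine
rescaling of the diversity axis.

## Null models and density bias

The null model randomizes the binary site × species matrix by repeatedly
flipping random 2×2 checkerboards, preserving row sums (site richness)
and column sums (occurrence frequencies) exactly; the default chain
length is 10 accepted swaps per presence. Observed per-site coverage
multisets are then randomly permuted onto the new species lists, so local
abundance distributions are preserved too. Null community sets (default
2000 × 40; 20 for land-use strata) draw equal numbers of sites per
occupied productivity bin, without replacement within a set, with the
remainder allocated to uniformly chosen bins.

The density bias compares observed and null diversity distributions:
Gaussian kernel densities at **twice** the Silverman reference bandwidth
(deliberately over-smoothed), evaluated on a shared 512-point grid
spanning both samples ± 3 bandwidths. The magnitude is the non-overlap
mass ½∫|f_obs − f_null| (symmetrized so the statistic is exactly
antisymmetric under swapping the samples); the sign is +1 when the
surplus-mass-weighted mean location of the observed surplus lies above
that of the null surplus — a rule that also resolves multi-modal
surpluses deterministically. The bias over high-productivity bins is the
arithmetic mean of per-bin biases over the 5 highest occupied bins
(3 for land-use strata), each bin's bootstrap sample compared against the
single null-set sample.

## Synthetic-data generator

The generator produces every input the pipeline consumes, with known
ground truth:

* **Genus phylogeny** — pure-birth (Yule) simulation from the root split,
  exponential waiting times, depth normalized to 1.
* **Traits** — log-normal; with the phylogenetic-signal switch on,
  log-traits evolve by Brownian motion along the species-level tree (tip
  SD equal to the configured scale), otherwise i.i.d.
* **Communities** — plots receive stratified latent productivity over the
  NDVI range. Species get niche windows (half-width 0.35 gradient units)
  whose center density follows the configured richness mean function, so
  the local candidate-pool size — and with it both per-plot and pooled
  richness — inherits the richness shape (increasing / decreasing /
  concave− / flat; default concave− with base 12 and amplitude 10
  species). The per-plot sampling fraction is auto-calibrated so expected
  per-plot richness equals that mean function in species units. Trait
  and phylogenetic diversity shapes are dialed independently through a
  dispersion bias β(t) ∈ [−6, 6]: membership sampling and, crucially, the
  geometric dominance ranks (evenness 0.8) are biased toward
  trait/phylogenetically extreme species where β > 0 (dispersed) and
  central species where β < 0 (clustered), so the signal reaches
  abundance-weighted orders q > 0. Wide niche windows are essential
  here: with narrow windows the local pool's chance trait geometry
  produces systematic bumps along the gradient that can mislead the
  shape classifier. Coverages follow a geometric series scaled to a
  60–120% total and are discretized into the six coverage classes.
  Plot coordinates sit on a 6-km grid (with jitter) so the 5-km bootstrap
  constraint is feasible by construction.
* **NDVI series** — 16-day revisit with day jitter and random gaps over
  1999–2017; value = plot mean + seasonal sinusoid + yearly offset +
  growing-season land-use deflections (negative, magnitude set by the
  plot's land-use class) + Gaussian noise; a configurable fraction of
  records is flagged bad quality.

Every generator is a pure function of (arguments, seed).

**What the generator does not emulate.** Spatial autocorrelation of plots
and environments (coordinates are a regular grid); raster-level NDVI
structure (series are generated at plot level); observer error in
coverage estimates beyond class discretization; temporal trends in
productivity; realistic phylogenetic imbalance beyond the Yule model; and
trait correlation structure (traits are independent given the tree).
Passing end-to-end tests therefore demonstrates that the *pipeline*
recovers structure it is designed to detect under its own assumptions —
not that those assumptions hold in any particular survey data set.

## Scaled problem sizes

The end-to-end recovery checks run the full design — 18 NDVI bins × 40
plots per bootstrap × 100 bootstrap replicates, ~200 species — on a
reduced parameter grid (a ∈ {0, 1}, δ ∈ {1, ∞}, q ∈ {0, 2}) with one
phylogeny replicate, repeated over many seeds; these sizes keep a desk-
scale run of the whole suite practical while leaving the per-bin sampling
density at the level the full design uses. Inside those loops plots are
binned on the generator's ground-truth productivity; the NDVI proxy
estimators are validated separately against series with known seasonal,
yearly, and disturbance structure. Null-model comparisons default to 200
null sets in the acceptance run for the same reason.

## Known limitations

* The GAM penalty is selected on a fixed log-grid of 26 values; extremely
  large samples might prefer a finer search.
* `land_use_intensity` with fewer than ~10 growing-season records is
  refused rather than estimated.
* The swap chain uses a fixed attempt budget; a matrix with extremely few
  checkerboards may return with fewer accepted swaps than requested (the
  matrix is still a valid member of the null space).
* Bootstrap feasibility under the 5-km rule is resolved by dropping bins
  after a retry budget; no maximal-independent-set search is attempted.
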