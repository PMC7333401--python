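# Methods

This note documents the statistical models implemented in `wolbiome`,
the design choices made where conventions genuinely diverge, what the
synthetic community generator does and does not emulate, and the
numerical details a user auditing results will want.

## Scientific setting

A maternally inherited intracellular symbiont such as *Wolbachia*
spreads through insect populations by cytoplasmic incompatibility. Once
it approaches fixation, its 16S reads can dominate amplicon libraries
(read shares of 60–90% per host are typical), which mechanically and
biologically restructures the rest of the bacterial community. The
package provides the statistics used to characterize that
restructuring: within-sample diversity, between-sample and
between-population community distances, a probabilistic
(heavy-tail/KL) characterization of abundance distributions, and tests
relating community structure to host genetics (mitochondrial
F<sub>ST</sub>), geography and climate.

## Power-law characterization of abundance distributions

OTU abundance distributions in these communities are strongly
aggregated: a few taxa carry most reads. We model the tail above a
threshold x′ with the density p(x) = a·x^(−ε), x > x′.

* **Exponent.** Continuous maximum likelihood on the tail:
  ε̂ = 1 + n_tail / Σ ln(x_i/x′). This is the standard heavy-tail
  (Hill-type) estimator; its sampling sd is ≈ (ε−1)/√n_tail.
* **Threshold.** When not fixed by the caller, x′ is selected over the
  distinct abundance values (thinned to ≤100 candidates) by minimizing
  the Kolmogorov–Smirnov distance between the empirical tail CCDF and
  the fitted (x/x′)^(1−ε) — the usual Clauset-style recipe. Candidates
  leaving fewer than 10 tail points are excluded; a fit whose final
  tail is that small is flagged rather than refused.
* **Exceedance curve.** The empirical CCDF is the rank staircase
  P(X ≥ x_(i)) = (n−i+1)/n; the model curve is (x/x′)^(1−ε) for
  x ≥ x′. The homogeneity factor multiplying the tail CCDF is taken as
  the pure power-law normalization, so the fitted curve is exactly
  (x/x′)^(1−ε); the reported KS statistic is the sup gap between the
  two, evaluated on both sides of each step.
* **Moment classes.** ε ≤ 2 → mean and variance infinite; 2 < ε < 3 →
  mean finite, variance infinite; ε ≥ 3 → both finite. The class is
  assigned from ε̂; near the boundaries it inherits the estimator's
  sampling noise, so class statements at |ε̂ − 2| or |ε̂ − 3| below
  ~2(ε−1)/√n_tail should not be over-read.

Degenerate inputs (all abundances equal, or no threshold with ≥10 tail
points) raise errors rather than returning a fit.

## KL-divergence community distance

Per population, sample reads are pooled per OTU; the positive pooled
abundances are binned into a histogram density on **log-spaced bins
shared across all populations** (default 32 bins spanning the pooled
range of the whole table; observations outside a shared support are
clipped into the end bins). Empty bins receive an additive mass of
1e-10 before renormalization so divergences are finite. The matrix
entries are symmetrized (Jeffreys) divergences
J = ½[D(p‖q)+D(q‖p)], because the downstream Mantel and path-model
stages assume a symmetric dissimilarity; the directed divergence is
also exposed. Choices made here (binning rule, smoothing, direction)
are conventions, not canon — the KL surrogate should be read as a
relative, not absolute, measure of community difference.

## Alpha diversity conventions

Shannon uses the natural log. Simpson is the finite-sample *dominance*
form Σ n_i(n_i−1) / (N(N−1)) — large when one taxon dominates. The
dominance convention is forced by internal consistency: in a
symbiont-swept system Simpson must *rise* with symbiont load while
Shannon falls, and the per-individual diversity table bundled in
`wolbiome.datasets` shows exactly that pattern. Chao1 is the
bias-corrected variant Sobs + F1(F1−1)/(2(F2+1)) (defined even when
F2 = 0). ACE uses the conventional rare/abundant cutoff of 10 reads
(configurable), with coverage correction and the γ² coefficient of
variation term; when the rare class is all singletons its coverage is
zero and the implementation falls back to Chao1 with a warning. Good's
coverage is 1 − F1/N.

## Rarefaction and symbiont exclusion

Rarefaction is subsampling **without replacement** (one multivariate-
hypergeometric draw per sample, explicit seed) to the minimum sample
depth, matching the "rarefy to the lowest-coverage sample" convention
of the standard amplicon toolchains; repeated-subsample averaging is
deliberately not done. The symbiont-exclusion analysis drops every OTU
of the focal genus and re-rarefies the residual counts to the new
residual minimum, so infected and uninfected hosts are compared on the
community the symbiont leaves behind. A sample with zero residual reads
is an error, not a silent drop.

## Beta diversity, ordination, PERMANOVA

Bray–Curtis d(u,v) = Σ|u−v|/Σ(u+v) on counts (equal row sums after
rarefaction make this compositional). PCoA double-centers −D²/2 and
eigendecomposes; coordinates are eigenvectors scaled by √λ on the
positive axes, proportions explained are over positive eigenvalues
only, and the negative-eigenvalue mass Σ|λ⁻|/Σ|λ| is reported rather
than corrected (no Lingoes/Cailliez), since Bray–Curtis matrices are
mildly non-Euclidean and the diagnostic is more useful than a silent
fix. One-way PERMANOVA partitions ΣΣd²/n into within- and among-group
sums; the pseudo-F uses (k−1, n−k) degrees of freedom and R² =
SS_among/SS_total, with significance by label permutation (999 by
default, seeded; the observed arrangement counts via the
(hits+1)/(n_perm+1) estimator). On designs of at most 9 samples an
exact mode enumerates every label permutation, giving the exact
permutation p (identity included). Survey-level effect sizes reported
as "r" by ADONIS-style software correspond to this R².

## Mantel tests and the path model

Mantel r is the Spearman correlation over strict lower triangles,
computed as Pearson correlation of tie-averaged ranks; permutations
rearrange the rows and columns of the second matrix jointly (ranks are
precomputed once, since a joint permutation permutes the triangle's
rank multiset). Default 1000 permutations, one-tailed positive; an
exact mode enumerates all n! permutations for n ≤ 8.

The path model is recursive path analysis by per-equation ordinary
least squares: every variable — |Δlatitude|, |Δlongitude|, |ΔBio1|,
|ΔBio12|, F<sub>ST</sub>, community distance — enters as the strict
lower triangle of a population-level pairwise matrix, so the Mantel
tests and the path model consume identical objects. For a fully
recursive graph this coincides with covariance-based SEM point
estimates. Two caveats are deliberate: (i) pairwise vectorization
violates independence, so normal-theory p-values are *nominal*; a
matrix-permutation mode (jointly permuting the response matrix) is
provided for distance responses and used by the analysis drivers;
(ii) when F<sub>ST</sub> is itself generated (or evolved) as a function
of latitude, |Δlat| and F<sub>ST</sub> are nearly collinear parents of
community distance, and multi-parent slopes split that shared signal —
the bivariate Mantel battery is the honest reading of each predictor's
marginal association. Collinear parent sets are flagged in
`fit_notes`, not fatal.

## Group comparisons

Welch's t (unequal variances, Satterthwaite df) is used for diversity
indexes — never Student's t. Mann–Whitney U is exact by full
enumeration when the pooled sample is ≤12 with no ties, otherwise
normal approximation with tie and continuity corrections; per-genus
comparisons run on per-sample relative abundances, report direction by
median, significance stars (*P<0.05, **P<0.01, ***P<0.001), and always
emit a Benjamini–Hochberg adjusted column alongside the unadjusted p
(reproduction-mode reporting is unadjusted per-genus stars; the
adjusted column is there so users can do better). Note that under a
dominant symbiont, per-genus relative-abundance tests are strongly
compositionally confounded: the symbiont's share mechanically depresses
every other genus, which is visible in the analysis drivers.

## The synthetic community generator

The generator produces the statistical structure the analyses assume,
under the survey conditions as defaults: 17 populations × 3
individuals, 34135 reads/sample, 314 taxa; 13 populations with symbiont
mean read share 0.879 and 3 with 0.664 (the observed dominance levels
of the two country-level groups), plus one polymorphic population at
infection rate 0.5. Mechanics:

* **Symbiont.** Per infected sample, the symbiont proportion is a Beta
  draw with mean = population mean and concentration 30 (between-host
  titer variability of roughly ±7% sd at mean 0.88); uninfected samples
  get exactly 0.
* **Residual community.** Per population, residual relative abundances
  are Pareto draws with density exponent ε (default 2.5 — finite mean,
  infinite variance, the regime typical of these data), tilted
  multiplicatively along a fixed random direction scaled by the
  population's position on a 0–1 gradient axis (a latitude stand-in,
  effect 2.0) plus log-normal noise (sd 0.6), then renormalized. The
  tilt is what makes geographically close populations host similar
  communities, so the latitude → F<sub>ST</sub> → community-distance
  path is recoverable.
* **Counts.** One multinomial draw of the stated depth per sample; row
  sums equal the depth exactly.
* **Metadata/F<sub>ST</sub>.** Latitudes sorted ascending over the
  population order (so the gradient axis is latitude order), climate
  linear in latitude with noise and clipped into range, and
  F<sub>ST</sub>(i,j) = clip(0.02·|Δlat| + N(0, 0.02), [0, 1)),
  symmetrized, zero diagonal — differentiation accumulating along the
  transect.
* **Determinism.** All randomness flows from one `numpy` Generator
  seeded explicitly; identical spec + seed reproduces tables bit for
  bit.

What it does **not** emulate: sequence-level noise (chimeras,
clustering artifacts), taxon–taxon ecological interactions, secondary
effects of infection on particular residual taxa (the residual
community of an infected host is exchangeable with an uninfected one,
so symbiont-exclusion reanalyses are true nulls by construction),
spatially realistic climate surfaces, or the population dynamics of the
symbiont's spread. Passing tests on this generator therefore
demonstrate that the estimators and tests recover the structure they
target at realistic sizes and noise levels — not that real communities
obey the generator's laws.

## Problem sizes and runtime choices

The analysis drivers and test suite run at the survey scale (51 samples
× 314 taxa × 34135 reads) where that is what is being demonstrated, and
at reduced sizes (a few thousand reads, 100–200 taxa, 99–199
permutations) where only the statistical behavior matters — e.g. the
type-I-error calibrations use 500 null replicates of 10–12 samples with
199 permutations each, which bounds the p-value granularity at 0.005
and keeps each calibration in a few seconds. Exact-enumeration checks
are run at n = 5 (Mantel, 120 permutations), n = 6 (PERMANOVA, 720)
and pooled n ≤ 10 (Mann–Whitney), the sizes at which full enumeration
is the unambiguous oracle.

## Known limitations

* The power-law machinery fits and describes; it does not test the
  power law against alternatives (lognormal, truncated power law) — no
  likelihood-ratio model comparison is provided.
* KL divergences depend on the binning rule; only comparisons made on
  shared bins are meaningful, and the δ-smoothing floor makes
  near-disjoint densities finite but large rather than infinite.
* The path model is not a latent-variable SEM: no covariance-matrix
  fitting, no fit indices (CFI/RMSEA), and distance-data p-values
  should be taken from the permutation mode.
* Per-genus differential abundance is deliberately simple
  (Mann–Whitney on relative abundances); no zero-inflated or
  compositional (CLR-type) modeling.
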