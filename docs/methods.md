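# Methods

This note records the models, algorithms, numerical choices, and open
design decisions behind `cohorttda`, at the level of detail a maintainer
or a methods-minded user needs.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Mixed-type distances

Subject dissimilarity is the Gower general coefficient
d(i,j) = Σ_k δ_ijk·d_ijk / Σ_k δ_ijk with per-feature contributions:

* continuous and ordinal: |x_ik − x_jk| / R_k, where R_k is the feature's
  observed range and ordinal levels are first replaced by rank codes
  0..k−1 (ranks scaled by the range, the daisy default treatment);
* nominal and symmetric binary: 1 if the levels differ, else 0;
* asymmetric binary: as above, but the pair is dropped from the average
  (δ_ijk = 0) when both subjects sit at the non-positive level — joint
  absence of a rare trait carries no similarity information.

δ_ijk is also 0 whenever either value is missing.  A pair with Σδ = 0 has
no defined distance and is an error; a continuous feature with zero
observed range is dropped with a warning (real clinical extracts contain
constant columns).  Feature weights are uniform by default; a weights
mapping is accepted for generality.  The Pearson feature-space distance is
mapped to [0,1] as (1−r)/2; this transform is a documented choice, with
(1−r) trivially obtainable from it.

## Persistence engine

Homology is computed over Z/2 on the Vietoris–Rips filtration, dimensions
0–2.  Simplices are ordered by (diameter, dimension, lexicographic
vertices); the tie-break matters only for representative chains, not for
diagrams.  Dimension 0 uses Kruskal union-find (single-linkage
equivalence: finite deaths are exactly the MST edge weights).  Dimensions
1–2 use the standard left-to-right boundary-matrix reduction, one
dimension at a time (per-dimension reduction provably yields the same
pairing as the global matrix), with the clearing optimization: pivot rows
of the dimension-(d+1) reduction are known-positive columns of the
dimension-d reduction and are skipped.

The reduction kernel is numba-compiled.  The working column is a dense
uint64 bitset over row ranks while stored reduced columns stay sparse, so
each XOR in a collision chain costs O(entries of the stored column) and
the pivot scan only ever moves downward.  This matters because Gower
distances on cohorts are heavily tied, which makes collision chains long.

Two exactness-preserving economies keep cohort-scale runs tractable:

* with the default scale cutoff (the maximum observed distance), simplex
  enumeration for dimensions ≥ 1 stops at the *enclosing radius*
  min_i max_j d(i,j), beyond which the complex is a cone and therefore
  contractible — diagrams in dimensions ≥ 1 are identical;
* zero-persistence pairs are dropped before any downstream analysis (the
  mixture model takes only positive durations).

Representative cycles are the reduced boundary columns at each death
simplex: a mod-2 cycle whose maximum simplex diameter equals the class
birth (up to ties).  The essential dimension-0 class reports its component
vertex set.  A sizing guard refuses filtrations whose projected simplex
count Σ_d choose(n, d+1) (d ≤ max_dim+1) exceeds a ceiling (default
5×10⁷): at n = 266 patients, voids already require 3,101,560 triangles and
203,927,570 tetrahedra, which is why homology above dimension 2 is out of
scope.

The test oracle is an independent dense reduction over the full complex
written with Python sets (tests/_oracles.py); the two agree exactly on
random metric spaces, including tie-heavy ones.

## Empirical Bayes significance

Durations of bars in dimensions ≥ 1 are modeled per dimension as the
two-group mixture f(x) = p0·f0(x) + (1−p0)·f1(x) with an exponential null
f0(x) = λe^(−λx).  Fitting choices:

* **λ by median matching**, λ = ln 2 / median: exact under the null,
  insensitive to the long alternative tail (a single huge duration leaves
  it unchanged).
* **marginal density f̂ by a penalized Gamma fit**: maximum likelihood
  over (shape, scale) with the shape constrained to ≥ 1 and its logarithm
  given a quadratic penalty centered at 0 worth 10 pseudo-observations.
  A cohort produces only ~40–130 bars per dimension; unpenalized flexible
  estimators (log-scale KDE, higher-order Poisson-regression smooths) put
  spurious bumps and dips in the ratio f̂/f0 at that sample size, which
  both drags the conservative prior down and hands intermediate null bars
  high posteriors.  Restricting f̂ to the Gamma exponential family
  anchored at the exponential boundary keeps the ratio smooth under null
  data while contamination by genuinely long bars still inflates the
  fitted scale, so real features score near 1.  The shape floor also makes
  the posterior monotone in the tail (long bars never score below shorter
  ones).  A log-scale KDE (Silverman bandwidth) and a histogram estimator
  remain available behind `estimator=`.
* **p0 as the most conservative prior**: p0 = min(1, min over observed x
  of f̂(x)/f0(x)), the largest value keeping every posterior
  non-negative.  This minimum over a noisy ratio is biased downward, i.e.
  deliberately conservative: simulations in the test suite check that the
  estimate errs on the null side rather than tightly recovering p0.
* **posterior(x) = clamp(1 − p0·f0(x)/f̂(x), 0, 1)**, evaluated at the
  observed durations.  Infinite bars are excluded from fitting and
  scoring; dimensions with fewer than 10 bars are scored but flagged
  unstable.

One model is fitted per homology dimension (loops and voids have very
different duration scales); `pool_dimensions=True` fits a single model to
the pooled durations instead.

## Loop and void interpretation

All geometric interpretation happens in an embedding of the daisy matrix:
classical (Torgerson) MDS by default, UMAP (seeded, precomputed metric) as
an alternative, and the raw numeric feature space behind
`space="numeric"`.  Where the original analyses of this kind performed
sector averaging and centroid separations is not fully determined; the
2-D MDS default is consistent with separations well below typical
full-space distances, and all three spaces are supported.

* **Loop centroid**: the mean embedded position of the distinct vertices
  of the representative cycle (the drawn "support" of the loop), not of
  all subjects near it.
* **Sectors**: 20° wedges about the centroid (width must divide 360);
  subjects exactly at the centroid are excluded with a warning.  Feature
  values use the numeric encoding (binary → {0,1}, ordinal → ranks);
  nominal features with more than two levels are excluded from sector and
  centroid analyses unless dichotomized first, since their codes are
  unordered.
* **Sinusoid fit**: OLS of sector means on (1, sin θ_s, cos θ_s) at the
  sector-center angles θ_s = (s+0.5)·20°.  MSE = RSS/S and σ² = total sum
  of squares/S over the same S non-missing sectors, so κ = MSE/σ² ∈ [0,1];
  κ is invariant to affine rescaling of the feature.  Constant sector
  means leave κ undefined; such features are flagged and excluded from
  rankings.  The peak angle is atan2(β1, β2).  Embedding orientation is
  arbitrary (MDS sign, UMAP seed), so peak angles are reported in each
  run's own frame and only phase *differences* are frame-invariant.
* **Centroid separation**: Euclidean distance between the two group mean
  positions of a binary feature (continuous features are median-split
  first: values ≤ median → "Low", the boundary deliberately in the low
  group, matching the clinical convention that cutoffs like B2M ≤ 4 mg/L
  define the low-risk class).
* **Void axes**: for three binary features, the segments joining group
  centroids in a 3-D embedding; the 3×3 matrix of unit directions and its
  determinant diagnose linear independence (statistically dependent
  features can still span independent directions).  |det| < 1e−6 is
  flagged, not an error.  The void's representative triangles export as an
  OFF mesh; subjects project onto the unit sphere around the void
  centroid for surface plots.

## Synthetic cohorts

The generators define the study conditions the tests measure under.

* **Loop cohorts** (default n = 300): latent angle φ ~ U[0, 2π), radius
  1.0 with radial noise sd 0.1; two continuous features are the noisy
  coordinates; three planted binary features are half-circle indicators
  cos(φ − ψ) > 0 at phases 0°/120°/240°, so each level covers a 180° arc
  and the three centroid axes point in distinct directions; plus 2
  nuisance N(0,1) features, 2 nuisance Bernoulli(0.5) binaries, and 5%
  missingness completely at random.  The nuisance features and missingness
  deliberately dilute the loop to a realistic strength: in the noiseless
  limit the planted bar dominates the second-longest by well over an order
  of magnitude (asserted in the tests), while under the default conditions
  detection is the empirical-Bayes posterior's job rather than being
  readable off the raw bar lengths.
* **Void cohorts** (default n = 120): subjects uniformly on the 8 vertices
  of a unit cube, diffused with sd 0.15 and pushed radially onto the
  circumscribed sphere (radius √3/2) with probability 1.  The radial push
  is the key modeling choice: a filled cube has no dimension-2 homology,
  and with exact vertices every simplex enters at one of three tied
  diameters and all classes die instantly — diffusion on the shell is what
  produces a persistent void.  The three planted binaries are the vertex
  coordinate signs: statistically near-independent axes.
* **Null cohorts**: n×p standard normal continuous features — the
  unstructured reference under which bar durations are approximately
  exponential.  The approximation is good in the direction that matters
  (the tests check, one-sided, that pooled null durations are not heavier-
  tailed than the fitted exponential); the exact shape deviates slightly,
  which is part of why the mixture's marginal smooth is kept conservative.

What the generators do *not* emulate: the marginal distributions of any
real cohort (they are structural, not demographic), informative
missingness, ordinal/nominal features beyond the binary planted ones, and
correlations among nuisance features.  Passing tests therefore demonstrate
recovery of planted topology under realistic mixed-type noise, not
performance on any particular clinical dataset.

## Problem sizes and determinism

The test suite and acceptance script run the operating-characteristic
batteries at 20 replicates (tests) and 10 replicates (acceptance script)
of the loop/null cohorts, and 5 void cohorts — sizes chosen so the full
suite completes in tens of minutes on one CPU while keeping the binomial
assertions meaningful.  All randomness flows through explicit seeds
(generators take a seed; UMAP is seeded; the acceptance script derives all
sub-seeds from `--seed`), so every reported number is reproducible
bit-for-bit.

## Known limitations

* Homology stops at dimension 2; the simplex-count guard makes higher
  dimensions an explicit error rather than a silent hang.
* The exponential null is an approximation; per-dimension duration
  distributions deviate from it in shape, and the conservative prior
  absorbs part of that misfit.  Posteriors are best read as a ranking with
  a calibrated-by-simulation threshold (0.8 in the tests), not as exact
  probabilities.
* p0 is estimated conservatively (biased low); it is not a consistent
  estimator of the true null fraction.
* Representative cycles are one choice of cycle per class (dependent on
  the simplex tie-break order); they are geometrically reasonable but not
  minimal-length.
* Sector averaging and centroid separations depend on the embedding
  choice; results in MDS, UMAP, and numeric space can differ, which is why
  all three are exposed.
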