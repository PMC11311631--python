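# cohorttda

Topological data analysis for mixed-type clinical cohorts.

Clinical tables mix continuous measurements (age, serum markers), ordered
stages, nominal categories, and binary traits, with plenty of missing
entries.  Each patient is a point in a high-dimensional "patient space";
the shape of that point cloud carries information that plain clustering
misses.  Beyond clusters (dimension 0), persistent homology can find
**loops** (dimension 1) and **voids** (dimension 2): combinations of
patient characteristics that are never observed together, enclosed by the
patients who surround them.

`cohorttda` is a library + CLI for the full workflow on such tables:

1. **Gower/daisy distances** between patients on mixed-type data with
   missing values (`mixed_distance`): continuous and ordinal features
   contribute range-normalized absolute differences, nominal and symmetric
   binary features contribute mismatch indicators, and asymmetric binary
   features are excluded from the average when both patients lack the
   trait.  All distances lie in [0, 1].
2. **Vietoris–Rips persistent homology** over Z/2 in dimensions 0–2
   (`rips`), built from scratch on a sparse GF(2) boundary reduction with
   representative cycles, so every loop and void comes with the patients
   that bound it.  A sizing guard refuses runs whose simplex count
   choose(n, d+2) is infeasible.
3. **Empirical Bayes significance** (`eb`): bar durations are modeled as a
   mixture p0·Exp(λ) + (1−p0)·f1 of an exponential null and an unknown
   alternative.  λ is estimated robustly (ln 2 / median), the marginal
   density by a penalized Gamma-family smooth, and p0 as the most
   conservative prior keeping every posterior non-negative.  Each bar gets
   a posterior probability of being a real feature.
4. **Loop/void interpretation** (`geometry`): MDS/UMAP embeddings; sector
   averaging of each feature in 20° wedges around the loop centroid;
   sinusoidal fits mean(θ) = β0 + β1·sin θ + β2·cos θ with the
   goodness-of-fit statistic κ = MSE/σ² (κ near 0 ⇒ the feature varies
   circularly around the loop); centroid-separation axes for binary
   features; 3-D void axes with a linear-independence diagnostic; circos
   export tables and OFF meshes.
5. **Dependence diagnostics** (`dependence`): pairwise Yates-corrected
   chi-squared tests between binary features, silhouette widths, and
   feature clustering under Sokal–Michener and Pearson distances.
6. **Synthetic cohorts** (`synthetic`): generators that plant a latent
   loop (phase-shifted binary features around a circle), a void (patients
   diffused near unit-cube vertices on a sphere shell), or nothing
   (multivariate-normal null), so the whole pipeline is testable without
   any external data.

## Worked example

Simulate a 300-patient cohort with a planted loop, then run the pipeline:

```bash
cohorttda simulate --kind loop --n 300 --seed 1 --out-prefix demo/loop
cat > demo/config.yaml <<EOF
table: demo/loop.csv
schema: demo/loop.schema.yaml
outdir: demo/out
max_dim: 1
seed: 1
EOF
cohorttda run --config demo/config.yaml
```

The bundle in `demo/out/` contains `barcodes.tsv`, `scored.tsv`,
`kappa.tsv`, `circos.csv`, `centroid_separation.tsv`, a silhouette table,
plots, and a manifest.  For seed 1 the scored table starts (rounded):

```
dim   birth     death     duration   posterior
1     0.06798   0.25362   0.18564    0.995
1     0.07161   0.19775   0.12614    0.974
1     0.03979   0.16517   0.12538    0.974
```

The most persistent dim-1 bar is the planted loop: its duration (0.186)
sits far out in the tail of the exponential null (132 loop bars in this
cohort, median duration ≈ 0.01), so its posterior probability of being a
real topological feature is 0.995.  `kappa.tsv` ranks features by κ
ascending:

```
feature    kappa    peak_angle_deg
coord_y    0.035    204.9
coord_x    0.065    297.9
phase000   0.128    290.0
phase240   0.178     56.0
phase120   0.198    176.9
noise_b1   0.588    183.4
```

The two informative coordinates trace the loop exactly (κ ≈ 0.04–0.06),
the three planted phase-shifted binary features take the top κ ranks among
binary features with peak angles spread around the circle, and the
nuisance features fall far behind (κ ≥ 0.59) — exactly the features a
practitioner would read off the circos table to explain the loop.

The same stages run standalone: `cohorttda distance`, `persist`, `score`,
`interpret`, `depend` each consume the previous stage's files.

## Analyzing the published CLL cohort

The 266-patient chronic lymphocytic leukemia table this methodology was
developed around ships inside the `RPointCloud` R package (CRAN) as a
binary R data object, and cannot be redistributed here.  To analyze it,
export it to CSV once:

```r
install.packages("RPointCloud")
data(CLL, package = "RPointCloud")
write.csv(clinical, "cll_cohort.csv")   # subjects x 30 clinical variables
```

then declare each column's type in a schema (continuous / ordinal /
nominal / binary_symmetric / binary_asymmetric) and run
`cohorttda run` on it.  Placing the export at `tests/data/cll_cohort.csv`
with a `cll_schema.yaml` enables the reproduction test in
`tests/test_acceptance.py`, which checks the published loop interval
(0.193, 0.267), void interval (0.179, 0.213), and centroid separations
(0.185 for binary Rai stage, 0.171 for dichotomized B2M).  Exact interval
reproduction can depend on the original backend's scale cutoff and the
embedding space used for separations; see `docs/methods.md`.
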