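# Methods

This note records the statistical model behind `morphodrift`, the
numerical conventions that make results reproducible, what the synthetic
generator does and does not emulate, and the known limitations of the
β-test at realistic sample sizes.

## Procrustes superimposition

`gpa` implements iterative generalized Procrustes analysis: every
configuration is centered, scaled to unit centroid size (full Procrustes;
`scale=False` gives partial Procrustes), and rotated onto the running
consensus by the proper orthogonal least-squares rotation; the consensus
is the arithmetic mean of the aligned configurations, iterated until it
moves less than 1e-10 (Procrustes distance) or 200 iterations.
Conventions that matter:

- **Reflections are disallowed** (rotation determinant +1). Landmarks
  are placed on one anatomical side only, so an improper rotation would
  superimpose a right half onto a left half.
- **Deterministic orientation.** After convergence the consensus is
  rotated onto its principal axes; each axis is signed so the landmark
  with the largest absolute coordinate on it is positive. The sign rule
  reads the rotated *shape*, not the eigenvector entries, so it is
  invariant to the (arbitrary) input frame; if the sign choice would
  produce a reflection, the smallest-variance axis is flipped.
- **No explicit tangent projection.** Aligned coordinates are used
  directly; at the small Procrustes distances of conspecific skulls the
  difference from an orthogonal tangent projection is far below the
  tolerances of any downstream test. (Both behaviors were considered;
  the simpler one was kept as the default since no result here depends
  on it.)
- Reported centroid sizes are pre-scaling values in input length units;
  units are otherwise treated as opaque.

## Digitizing precision and the discard rule

A voucher digitized r times (r = 10 by convention) is superimposed by
GPA *without* scaling — the replicates are the same physical object, so
size must not be renormalized away. Per landmark: s.d. is the
root-mean-square deviation of the r replicate positions about their mean
(denominator r − 1; for isotropic per-axis jitter σ its expectation is
σ√3), S.E. = s.d./√r, and CV = s.d. divided by the landmark's mean
distance from the configuration centroid. A 3D point has no natural
scalar mean, so this CV is a noise-to-signal ratio: dispersion relative
to how far the landmark sits from the centroid. Landmarks are ranked
ascending by (CV, S.E., index).

The discard rule compares measurement error against biological signal:
for every unordered pair of locality groups, the Euclidean norm of the
difference in group-mean landmark position (after unscaled GPA of the
full dataset, keeping units commensurate with S.E.) is compared with the
landmark's S.E. A landmark whose sub-S.E. pair count exceeds half of all
pairs (strict majority; configurable) is discarded. The norm of the mean
difference is used rather than per-axis comparisons; the per-axis
variant was considered and rejected as the default because it triples
the number of comparisons without an obvious decision rule for partial
failures.

## Shape statistics

- **Allometry**: multivariate regression of the n×3k shape coordinates
  on log centroid size (log by default — the conventional allometric
  scale; raw size by flag). Percent shape variance predicted is
  SS_pred/SS_total × 100; significance by permuting sizes across
  specimens (default 10,000 permutations) with Goodall's F as the
  parametric fallback. Size-adjusted residuals (mean shape added back)
  feed downstream stages when the effect is significant at the
  configured α.
- **PCA**: eigendecomposition of the sample covariance (denominator
  n − 1), eigenvalues clipped at 0, eigenvector signs fixed by the
  largest-|loading| rule.
- **CVA**: because 3k generally exceeds n, coordinates are first
  projected onto the PCs carrying all non-negligible variance
  (relative threshold 1e-12), capped at n − g dimensions so the pooled
  within-group covariance is invertible; the among/within generalized
  eigenproblem is solved there and axes are mapped back. At most g − 1
  variates have nonzero among-group variance, and their percentages sum
  to 100 by construction.
- **Procrustes ANOVA**: Goodall-style — sums of squares accumulated over
  all coordinates, with univariate degrees of freedom multiplied by the
  shape dimension m = 3k − 7 (3D similarity shape space: translation 3,
  rotation 3, scale 1). A 2-level factor with 56 specimens of 24
  landmarks therefore reports F with (65; 3510) df, and 51 specimens of
  15 landmarks (38; 1862). Sequential (type-I) SS in the order the
  factors are listed; permutation p by residual randomization of the
  model reduced by the term under test.
- **Geography**: simple regressions of PC1 scores on latitude and on
  longitude, reported separately.

## The β-test

Successive inter-landmark distances D_i (the chain (1,2), (2,3), …,
(k−1,k) in stored landmark order — the only reading consistent with 23
distances from 24 landmarks) are the traits. W is the residual
covariance of the additive model D ~ locality + sex with denominator
n − rank (the MANOVA error SSCP over its df), so locality and sex mean
effects are excluded from the within-population variance. B_j is the
variance (denominator g − 1, which keeps E[B] unbiased under neutrality)
of the g locality means projected on within-population eigenvector j.

The regression is ln(B) on ln(W): B is the response, W the predictor.
PC retention is cumulative-from-largest at 95%, with eigenvalues below
1e-12 of the largest always dropped; retained PCs with non-positive B or
λ raise an error rather than being silently dropped, so degenerate data
surface. Inference: two-sided t-test of H0: β = 1 with df = n_PCs − 2
and a t-based 95% CI (normal quantiles were the alternative; t is used
and documented). A numerically perfect log-linear fit (residual SS below
1e-24 of the total) is treated as exact, so B ∝ W returns slope 1 with
t = 0 and p = 1.

### Finite-sample behavior

Two properties of the test deserve emphasis; both are measured by the
test suite rather than assumed.

**Plug-in attenuation.** λ̂ and the eigenvectors are estimated, and
sample eigenvalues over-disperse (top biased up, bottom down) while the
projection variance B̂_j through estimated eigenvectors shrinks toward
the spectrum's center. Both effects flatten the ln B–ln λ relation, so
the fitted slope sits slightly below 1 under exact neutrality. At the
calibration scale used in the acceptance checks (10 traits, 8 localities
of 50, ≈390 residual df) the attenuation is ≈ 0.015–0.02 — within the
Monte-Carlo resolution of a 500-replicate calibration — and the type-I
error of the drift test stays at its nominal 5%.

**Small-sample collapse.** The attenuation grows rapidly as residual df
approach the trait count, because eigenvector estimates mix across
close eigenvalues. End-to-end simulations with study-scale samples
(4 localities, 5–25 specimens each, 23 distance traits, ≈50 residual
df) show the neutral slope attenuating to ≈ 0.4 with drift rejected in
≈ 40% of neutral replicates; at 40 specimens per locality — the sample
size the quantitative-genetics literature recommends for drift tests —
the rate falls to ≈ 10%. The practical reading: a slope far below 1 at
small n/p is weak evidence against drift on its own, and the package's
calibrated tests therefore run the slope calibration on the
distance-trait scale at adequate df.

## Modularity

The covariance ratio for a two-module landmark partition is

    CR = sqrt( tr(S_AB' S_AB) / sqrt( tr(S*_AA S*_AA) · tr(S*_BB S*_BB) ) )

with S the sample covariance of the flattened coordinates and S* the
within-block matrices with zeroed diagonals. The population CR is 0 for
independent blocks and near 1 for fully integrated traits; the sample
statistic is not clamped and can exceed 1 (it does, for example, on
integrated data with finite blocks), which is documented rather than
"corrected". The permutation null reassigns whole landmarks to modules
(a landmark's three coordinates are not separately exchangeable),
preserving module sizes, with the +1-corrected one-tailed p toward small
CR; Z_cr standardizes the observed CR against the raw permutation
distribution (a log-scale variant is available, as effect-size
conventions vary). Default 999 permutations.

## Synthetic data

The generator emulates the statistical skeleton of a multi-locality
skull study: a deterministic template shape (3D helix or jittered grid;
centroid at origin, unit centroid size), locality groups with study-like
sizes (default 25/14/12/5), synthetic localities on a 16°S–32°S
latitudinal gradient, alternating sexes, optional allometric deformation
tied to log centroid size, and optional replicate digitizing error.
Group means and within-group noise come from independent seed streams,
so enlarging a group never moves its mean.

Evolutionary modes set the law of the group means: **drift** draws them
with covariance c·Σ_W (B ∝ W holds by construction; c defaults to 0.5),
**directional** displaces them only along chosen within-covariance
eigenvectors (variance c·inflation·λ on those axes, nothing elsewhere —
the sharpest violation of proportionality), and **stabilizing** shrinks
a neutral draw toward the grand mean. Within-group covariance families:
isotropic, single common factor, and modular (two landmark blocks with
within-module correlation r_w and between-module correlation r_b on
same-axis coordinates).

Noise can be injected at two scales. Coordinate-scale noise perturbs the
3k landmark coordinates and exercises the full pipeline, but the
distance transform then makes the distance-trait B only approximately
proportional to W. Distance-scale simulation defines Σ_W directly on the
k − 1 distances, giving exact β-test calibration; the calibration and
power acceptance checks use it, end-to-end tests use the coordinate
scale. `random_psd` supplies the within-covariance for distance-scale
work: a geometric eigenvalue profile (condition number 20) in a seeded
uniformly random orthogonal basis. The profile mirrors empirical
distance-trait spectra, where a 95% cumulative-variance cut retains most
axes, while keeping adjacent eigenvalue gaps large relative to their
sampling error at the calibration df — a clustered spectrum would make
every plug-in eigen-quantity unstable (see the attenuation discussion
above).

What the generator does **not** emulate: realistic skull geometry,
anatomically structured covariance beyond two blocks, phylogenetic
structure across species, missing landmarks, or digitizer-specific error
models. Passing tests therefore demonstrate the statistical machinery
under its stated assumptions, not robustness to every property of real
µCT-derived landmark data.

## Degenerate inputs and tie-breaks

Zero centroid size is an error naming the specimen; identical replicates
produce exact zero dispersion (superimposition round-off below 1e-12 of
the configuration scale is snapped to zero); a within-covariance that is
exactly zero raises before logs are attempted; aliased ANOVA factors,
singleton CVA groups, constant sizes, and constant geographic
coordinates all raise with explicit messages. Precision ranking breaks
ties lexicographically on (CV, S.E., landmark index); eigenvector signs
follow the largest-|loading| rule everywhere.

## Known limitations

- The β-test inherits Lande's model's assumptions: additive within- and
  between-population structure, no shared selection gradient mimicking
  proportionality, equilibrium divergence.
- Slope attenuation at small n/p (above) means "drift rejected" and a
  very low slope at study-scale samples should be read together with the
  sample size.
- Sliding semi-landmarks, multi-block (> 2) modularity hypotheses,
  likelihood-based module search, and PLS integration analyses are out
  of scope.
- Jackknife-by-locality (site-exclusion) variants are exposed only as a
  configuration stub; small locality counts make them uninformative.
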