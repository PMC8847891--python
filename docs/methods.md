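# Methods

## Model and null hypothesis

The object of study is a set of n phenotypic change vectors
x_i ∈ R^p (descendant minus ancestor trait means, one per lineage),
compared only through their directions z_i = x_i/‖x_i‖. The reference null
hypothesis throughout is *independent directions with no preferred
orientation*: each z_i uniform on the unit hypersphere S^(k−1), where k is
the effective dimensionality of the trait space. Equivalently, the
population inter-lineage correlation matrix is the identity, Γ = I_n.

Under this null the angle θ between two directions has density
sin^(k−2)(θ)/B(1/2, (k−1)/2); the correlation r = cos θ has density
(1−r²)^((k−3)/2)/B(1/2, (k−1)/2); s = r² is Beta(1/2, (k−1)/2); and
√(k−1)·r/√(1−r²) is t-distributed with k−1 df. All single-angle p-values
are routed through the exact t CDF (`angle_cdf`), never through asymptotic
approximations; the axial (polarity-blind) alternative uses the Beta upper
tail. These are textbook results of directional statistics; the package's
contribution is wiring them into a coherent workflow for trajectory
analysis.

The standardized effect size √(k−2)(π/2 − θ) converges to a standard
normal under the null as k → ∞ and makes angles comparable across trait
spaces of different dimensionality; it is exposed for meta-analytic use
but not used internally for p-values.

## Effective dimensionality

k is always supplied by the caller (directly or as `p − lost_df`), never
inferred from the column count: traits can be linearly dependent — the
canonical case being Procrustes-aligned 2-D shape coordinates, which lose
4 df to translation/rotation/scaling — and using nominal p would make every
test anticonservative. Rows of Z are deliberately not mean-centred across
traits: directions, unlike residuals, retain full dimensionality.

## One-step uniformity tests

`schott_test` uses S = Σ_{i<j} r²ᵢⱼ = (‖C‖²_F − n)/2, with closed-form
null moments E(S) = n(n−1)/(2p), Var(S) = n(n−1)(p−1)/(p²(p+2)) (pairs are
uncorrelated under the null, so the per-pair Beta moments simply add). The
asymptotic reference is the standard normal for Z = (S−E)/√Var, one-sided
upper by default since concentration inflates S. Because the asymptotics
are slightly liberal for small matrices, `mode="auto"` switches to Monte
Carlo when min(n, k) < 16 (default 10,000 replicates). Two equivalent null
generators are provided and cross-checked in the tests: row-normalized
Gaussian matrices, and Wishart(k, I_n) draws rescaled to correlation form.

`rayleigh_test` uses T = nk‖z̄‖² with the chi-square(k) asymptotic
reference or a Monte Carlo null. Its supplementary-material variants exist
in the literature in several corrected forms; the classical statistic is
implemented here, with the Monte Carlo mode available whenever the
asymptotic reference is in doubt. T depends only on the mean resultant, so
antipodal and girdle patterns are invisible to it — that is a property of
the statistic, not a defect: it is exactly what makes a significant
Rayleigh result interpretable as *unimodal* concentration.

Measured at the suite's simulation sizes (α = 0.05, k = 10, n = 20,
asymptotic modes), the two tests behave as their constructions predict:
on antipodal axial data (vMF κ = 20 with random sign flips) Schott rejects
essentially always while Rayleigh stays near its nominal level — slightly
above it (~0.12) because a binomial imbalance of sign flips leaves a small
mean resultant; on unimodal vMF data Rayleigh is near-certain to reject
already at κ = 5 while Schott's power is partial there (~0.6) and reaches
~1 by κ = 20. The package asserts these qualitative contrasts, which are
the decision-relevant facts, rather than idealized power values.

`mean_pairwise_angle_test` (Monte Carlo, default 10⁵ iterations, +1 tail
correction) is provided as a descriptive companion; pairwise angles share
vectors and are mutually dependent, so the mean pairwise angle has no clean
interpretation away from the uniformity null. Every result carries this
caveat in its notes.

## Eigenstructure

C = ZZᵀ and A = ZᵀZ are decomposed with symmetric eigensolvers; their
nonzero spectra coincide and both traces equal n. The dispersion identity
Σ(l−l̄)² = Σ(k−k̄)² + n²/p − n = 2S ties the spectral view to the Schott
statistic and is property-tested over random (n, p) configurations.
Eigenvector polarity is fixed by making the largest-magnitude element of
each vector positive; with tied eigenvalues any orthonormal basis of the
eigenspace is acceptable and tests compare only eigenvalues and
reconstructions. Ordination uses the trait-side (A) decomposition by
default because its eigenvectors live in trait space and its scores ZV
place lineages directly in interpretable axes.

## Exploratory tools

*Biplot.* The SVD convention Z = (U S^(1−α))(V S^α)ᵀ with α ∈ [0, 1]
allocates singular values between lineage scores and trait coefficients;
the rank-2 reconstruction is invariant to α, which only redistributes
scale. Default α = 1 (full singular values on the trait coefficients).
Degenerate components (zero singular value) get zero score columns so the
identity holds at the actual rank. This convention is a package choice
among the standard biplot family.

*Bootstrap.* Specimens are resampled with replacement within each
lineage × role cell; change vectors are recomputed, renormalized (the
direction is the quantity of interest, so replicate vectors are projected
as unit vectors — a package convention), and projected onto the *fixed*
leading trait-space eigenvectors of the observed data. Confidence ellipses
are normal-theory: replicate covariance scaled by the chi-square(2)
quantile of the requested coverage. Cells with a single specimen yield
degenerate resampling and are flagged with a warning note rather than an
error. Short trajectories with fixed specimen noise produce visibly larger
directional ellipses — length, not just noise, controls directional
precision.

*Clustering.* Standard k-means on the unit rows with multiple restarts
(default 50, best within-group sum of squares kept, seed recorded). No
automatic selection of the number of clusters is attempted.

## Synthetic data generator

`simulate` produces the regimes the tests are designed to separate:
uniform (normalized isotropic Gaussians — this is also every Monte Carlo
null), von Mises–Fisher (rejection sampling of the cosine component),
antipodal vMF (sign flipped with probability 1/2, giving an axial pattern
with zero mean resultant), and a girdle regime. The girdle
parameterization is a package convention, since only the pattern — not a
model — is standard: the Gaussian component along the girdle normal is
shrunk by 1/√(1+κ) before renormalization, so κ = 0 is uniform and
κ → ∞ collapses onto the equatorial great hypersphere. The specimen-level
generator draws Gaussian noise of stated sd around programmed
ancestor/descendant means.

What the generator does *not* emulate: phylogenetic correlation between
lineages (the null assumes independence, and so does the generator),
trait-trait covariance structure within groups (noise is isotropic),
measurement error distinct from individual variation, and non-Euclidean
trait spaces. Tests passing on these synthetics therefore validate the
statistical machinery under the stated model, not robustness to correlated
lineages or anisotropic within-group variation.

## Numerical choices

- Correlations are clipped to [−1, 1] with tolerance 1e−12 before arccos;
  larger excursions raise (they indicate a real input error, not rounding).
- At k = 2 the correlation density diverges at |r| = 1; +inf is returned
  (the CDF remains proper) instead of raising.
- Unit rows are normalized twice to push row norms to within 1e−10 of 1.
- Eigenvalues below −1e−10 raise; small negatives above that are clipped
  to zero.
- Monte Carlo p-values use the (1 + #extreme)/(1 + reps) correction and
  are bit-reproducible under a fixed seed (PCG64); auto-drawn seeds are
  recorded in the result.
- Pairwise-report boundary: a pair exactly at the α/2 quantile is flagged
  null-consistent (strict inequalities).
- Simulation sizes in the test suite (e.g. 5000 null replicates for
  type-I calibration, 1000 for power, 10⁵ pairs for distributional KS
  checks) were chosen so Monte Carlo error is small relative to the
  asserted bands while the whole suite stays fast.

## Known limitations

- Non-null distributions of r (arbitrary population correlation) are not
  implemented; tests against *complete parallelism* need a sampling model
  for the vectors and are out of scope.
- The Schott statistic is sign-blind; significant results require the
  exploratory tools to characterize the pattern.
- Bonferroni adjustment of the pairwise report is conservative but not
  exact under the dependence among pairs.
- k-means on unit vectors uses Euclidean (chordal) distance, the standard
  choice, not geodesic distance.
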