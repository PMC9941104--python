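# Methods

This note documents the models and procedures implemented in `valveshape`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Superimposition

Configurations are centred, scaled to unit centroid size and iteratively
rotated to the consensus (partial Procrustes / GPA). The per-shape rotation
is the proper orthogonal Procrustes solution (SVD of the 2×2
cross-covariance with the determinant constrained positive): reflections
are forbidden in the fit because valve side is handled explicitly upstream
by `reflect_side`, which mirrors one side about the vertical axis through
its centroid while preserving landmark order (matching symmetry). The
default mirroring axis is vertical (an anterior–posterior flip); the axis
and an optional landmark relabelling map are configurable because the
digitization mirroring convention of a given dataset may differ.

Convergence: root-mean-square change of the consensus < 1e-10, at most 100
iterations; non-convergence returns the result with a warning flag. After
convergence the whole sample is rotated to a canonical orientation (the
consensus aligned with its principal axes, the 180° ambiguity resolved by
the sign of the consensus' third moments). This makes the GPA output
strictly invariant — not merely invariant up to rotation — under arbitrary
similarity transforms of the inputs, which both the tests and downstream
truth-comparisons rely on. The one degenerate case is a consensus with a
perfectly isotropic or symmetric landmark distribution, where no canonical
orientation exists; valve outlines are far from this regime.

Tangent projection is the orthogonal projection onto the hyperplane through
the consensus and orthogonal to it; it is idempotent, fixes the consensus,
and moves shapes within Procrustes distance 0.05 of the consensus by less
than 1e-4 per coordinate.

Outline resampling places n interior points per arc at equal arc-length
spacing (n points divide the arc into n + 1 equal sub-arcs), anchors first:
2 + 28 dorsal + 18 ventral = 48 landmarks by default. Semilandmark sliding
(minimum bending energy along outline chords) is provided but OFF by
default: the resampled points are treated as fixed landmarks in all
standard analyses, matching the convention of analysing converted outline
points directly; the slider exists for sensitivity analysis.

## Procrustes ANOVA

The asymmetry design is a sequential (Type I) least-squares decomposition
in the fixed order species → sex → individual (nested in species × sex) →
side → individual × side. With one digitization per valve the
individual × side stratum coincides with the residual and serves as the
terminal error (fluctuating asymmetry); no measurement-error term is
modelled. Sequential fitting makes the effect sums of squares add exactly
to the total SS about the grand mean for any design, balanced or not —
this, rather than reproducing any particular software's Type II/III
conventions, is the reproducible choice for unbalanced valve data.
Individuals represented by a single valve are excluded from the ANOVA with
a warning (they remain available for per-side analyses); species with one
individual are kept but flagged, contributing zero individual-level df.

Degrees of freedom come from the realized design (column-rank increments of
the growing design matrix), never from a printed table. For shape, SS are
summed over all 2k coordinates and each univariate df is multiplied by
2k − 4, the tangent-space dimension. Goodall's F tests species and sex over
the individual mean square and individual and side over the FA mean square,
with parametric p from the F distribution at the multiplied df. Pillai's
trace is computed per effect as tr(H(H+E)⁻¹) with the inverse restricted to
the rank support of H + E (eigenvalues above a relative tolerance); the
support dimension enters the standard F approximation. On small samples
where the error stratum has fewer univariate df than the tangent dimension,
PT saturates at its upper bound — an inherent property of MANOVA statistics
on rank-deficient cross-products, reported as computed.

p-values below 1e-4 are formatted "< 0.0001" in summaries.

## Allometry

Shape is regressed on log CS per coordinate by least squares: with
intercept for the total level; after removing group means from both sides
for the pooled-within level; and through the origin for the evolutionary
level, because independent contrasts have zero expectation — a regression
with intercept would be mis-specified there. Strength is reported as
percent predicted, SS_pred/SS_total in the summed (Procrustes) metric. The
permutation test shuffles the independent variable (size) against the
shapes, with the add-one convention p = (#{SS_perm ≥ SS_obs} + 1)/(N + 1)
and a mandatory seeded generator; N defaults to 10,000.

Species averages are computed after a single joint GPA of all specimens
(averaging before superimposition would make the mean shapes depend on
arbitrary per-species frames); Procrustes coordinates are averaged
arithmetically per species and CS is averaged arithmetically, then logged
— the log of the mean, a documented order of operations.

Size correction returns residuals + consensus, so corrected shapes stay in
the same tangent space; re-regressing them on the same sizes yields ~0%.

## Comparative methods

Independent contrasts use Felsenstein's pruning algorithm, vector-valued:
contrast (x_a − x_b)/√(v_a + v_b), node value the variance-weighted mean,
parent branch extended by v_a·v_b/(v_a + v_b). Polytomies are resolved
upstream (left-first, deterministic) with epsilon = 1e-8 branches, and
zero-length branches are replaced by the same epsilon, so standardization
is always defined; the reference use case consumes an already-binary tree.

Squared-change parsimony minimises Σ_edges (x_parent − x_child)²/length.
Two independent routes are implemented: the two-pass weighted-average
algorithm (producing the ancestral states) and the exact quadratic form
x'Kx with K the Schur complement of the edge-weight graph Laplacian onto
the tips (used to evaluate the many permutations of the signal test
cheaply). The two agree to machine precision, and both equal the
Brownian-motion GLS/ML ancestral reconstruction, verified against a
brute-force matrix-inversion oracle in the tests. Branch-length weighting
is the default; an unweighted option exists.

The phylogenetic-signal test permutes tip rows jointly across all trait
dimensions and uses the lower tail (signal = shorter-than-random tree
length), add-one convention, 10,000 permutations by default. For size, CS
is mapped onto the tree by default with log CS available as an option.

PCA uses the covariance matrix with divisor n − 1; mean-centred for species
averages, uncentred for contrasts (their expectation is zero; a flag
restores centring for sensitivity analysis). Eigenvector signs follow a
fixed convention (largest-magnitude loading positive) for cross-platform
reproducibility. Wireframe extremes are mean ± magnitude × eigenvector with
the outline-ordered neighbour edge list.

## Sequence utilities

Simple indel coding: each distinct internal gap extent (start, end) is one
binary character — 1 for a taxon with exactly that gap, 0 for residues
across the region, ? when a different overlapping gap (or a terminal gap)
obscures the region. Terminal gaps are always missing data, never
characters, since they usually reflect incomplete reads. Concatenation
appends gene blocks and then the indel characters, retaining a block
coordinate map. p-distances use pairwise deletion of gap/N sites by
default (complete deletion by flag); group summaries report the mean and
the min–max range per within/between cell, with singleton-group within
cells left undefined.

## Synthetic-data generator

The generator emulates the statistical structure of a paired-valve
radiation study: a Yule tree (height normalized to 1), Brownian motion of
shape in the tangent space at a bean-shaped template with a rank-3
covariance (spectrum 0.60/0.25/0.15 of a total trace σ²_shape), Brownian
log-CS, an allometric vector β applied per valve as β(log CS − mean), a
directional-asymmetry vector d (+d/2 right, −d/2 left before mirroring), a
sexual-dimorphism vector, isotropic individual and fluctuating tangent
noise, and an arbitrary rotation/translation/pixel-scale per valve with the
TPS SCALE record restoring physical units. All randomness flows from one
seed through named substreams (tree, structure, species, specimen, valve,
digitization).

Default magnitudes were chosen to mirror the variance ratios reported for
Baikal candonid valves: fluctuating-asymmetry per-df mean square ≈ 7.9e-6
gives σ_fa ≈ 0.0028 per tangent dimension; a directional-asymmetry
Goodall's F near 55 gives |d| ≈ 0.021; a sexual-dimorphism F near 4 gives
|s| ≈ 0.0065; a shape individual F near 1 motivates small σ_ind = 0.001;
the size F ratios (species ≈ 470, individual ≈ 1.5, side ≈ 90) give
σ²_CS ≈ 0.014 per unit height, σ_ind,logCS = 0.005, σ_fa,logCS = 0.01 and a
1% log-size side offset; the evolutionary allometric fraction defaults to
15%, from which |β| is derived. `SimulationParams.study_scale()` reproduces
the bookkeeping of the reference dataset — 46 species, 202 individuals (18
species with 5 specimens, 28 with 4), 386 valves via 18 one-valved
individuals — and the default simulation at that scale yields shape F
ratios of the same order as the reference table (species ≈ 44, DA ≈ 58).

Note one structural consequence of the model: a side offset in log size
combined with allometry produces an additional right-left shape difference
β·d_size, so the expected right-minus-left vector is d + β·d_size; the
truth record exposes both (`da_vector`, `da_shape_total`).

What the generator does *not* emulate: digitization error with replicate
measurements, landmark-swap outliers, non-Brownian (selective,
early-burst) evolution, covariance between sexes and size, missing
classifier metadata, or ecological structure (depth/basin) beyond labels.
Tests passing on these simulations therefore demonstrate the correctness
and calibration of the estimators under the stated model, not robustness
to every pathology of real SEM-digitized material.

## Test and calibration problem sizes

Unit and property tests run on 2–12 species toys. Calibration uses the full
generator → GPA → ANOVA pipeline under the null (FA as the only variance
source; 6 species × 2 specimens, k = 8) with 800 replicates for the
parametric Goodall tests, and 1000 replicates × 199 permutations for the
permutation tests (16-tip trees for signal, n = 46 for allometry).
Parameter recovery runs 120 species-level replicates at n = 46 for the
evolutionary-allometry fraction, one full 386-valve pipeline for the
directional-asymmetry direction, and 200 replicates for signal power. The
directional-asymmetry direction check uses a low-FA regime
(σ_fa = 0.001): at the study-implied σ_fa = 0.0028 the expected angular
error of a mean over 182 individuals is ≈ √92·σ_fa·√(2/182)/|d| ≈ 7.7°, so
direction recovery to within 5° is informative about estimator correctness
only where the noise allows it.

## Known limitations

* Pillai's trace p-values use the classical F approximation on the rank
  support; they are not permutation-calibrated (permutation MANOVA is out
  of scope).
* The GPA canonical orientation is undefined for perfectly symmetric
  consensus shapes.
* Indel coding implements the simple (extent-equality) scheme only, not
  multi-state or complex coding.
* The CLI's evolutionary-allometry path averages species after a joint GPA
  of all valves; alternatives (per-side GPA) are a one-line library call
  but not a CLI switch.
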