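# Methods

`codniche` implements a two-part analysis of intraspecific niche
variation in fish: (1) delineation of morphotypes from photographic
landmarks, and (2) quantification of individual habitat/trophic
specialization from two-tissue stable-isotope data, per morphotype. This
note records the models, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer would want to know.

## Morphometrics

**Superimposition.** Landmark configurations (21 two-dimensional
landmarks per fish) are aligned by *partial* generalized Procrustes
analysis: each configuration is centred, scaled to unit centroid size,
and rotated onto the running mean shape, which is re-standardized each
pass; iteration stops when the change in summed squared Procrustes
distance falls below `tol = 1e-8` (maximum 100 iterations;
non-convergence is flagged, never fatal). Rotations are proper
(determinant +1): all photographs are same-side lateral views, so
reflections would be artefacts. Aligned shapes are orthogonally
projected onto the tangent plane at the mean by default; for the shape
variation encountered here (small dispersion around the mean) the
projection changes coordinates at roughly the squared Procrustes
distance, i.e. negligibly, but it makes the PCA Euclidean geometry
exact. Shape variation is summarised by centred PCA of the flattened
Procrustes coordinates; "deformation" output is numeric — per-landmark
displacement vectors of the extreme shapes along each component —
rather than rendered grids.

**Coordinate convention.** TPS files store image coordinates (y
increasing downward); the reader negates y so the in-memory convention
is mathematical (y up). Alignment and distances are invariant to this,
but the templates and any plots assume it.

**Linear measurements.** Nine named inter-landmark distances (CP, BDP,
BDA, PPFL, HD, HL, SL, EW, ML) plus fork length are computed from a
configurable landmark-pair map. The shipped default pair map matches the
measurement names against the synthetic template's anatomy (e.g. HL =
snout tip to posterior operculum; fork length = snout tip to posterior
caudal peduncle). For real datasets the pair map is a required piece of
configuration, not something to guess.

**Allometric size adjustment.** Each measurement M is standardized to a
common fork length L_m by the allometric (Reist) correction

    Y_i = log10(M_i) + b ( log10(L_m) − log10(L_i) ),

where b is the pooled OLS slope of log10(M) on log10(L) across all
retained fish (pooled, not per-group: the adjustment is meant to remove
the population-level size trend before any grouping exists). L_m
defaults to the mean fork length of the retained fish and accepts an
override (e.g. 368.1 mm) to reproduce an external alignment point.
Adjusted values are dimensionless log10(mm) quantities and are labelled
as such in every output header. If all fish share one length the slope
is unidentifiable; the correction is then exactly zero at the default
alignment point and that case is allowed, while aligning to any other
length raises an error.

## Morphotyping

PCA of the nine size-adjusted measurements uses the correlation matrix
(variables standardized to unit variance), the common choice when
measurements span different magnitudes; covariance-matrix PCA is
available. Component signs follow a deterministic convention (largest
loading positive). Clustering operates on the first two components by
default — the configuration that matches plotting practice and the
head/body-depth drivers of between-group variation — and can be switched
to all components.

The number of clusters is chosen by maximising the mean silhouette width
(Euclidean) over k in {2..5}, ties resolving to the smaller k. k-means
is Lloyd's algorithm with 50 seeded random restarts, keeping the best
within-cluster sum of squares; an emptied cluster is re-seeded at the
point farthest from its centre. The per-iteration objective trace of the
winning restart is retained and is non-increasing by construction (the
test suite asserts it); an independent implementation (scikit-learn) and
exhaustive partition enumeration serve as cross-checks in tests.

Between-cluster differences are tested by one-way MANOVA using Pillai's
trace, V = tr(H(H+E)^-1), with the standard F approximation, followed by
per-measurement two-sample tests. The post hoc default is Welch's
unequal-variance t with Welch–Satterthwaite degrees of freedom — the
fractional dfs this produces match how such comparisons are reported in
practice — with a pooled-variance Student variant available. Bonferroni
control over the nine comparisons is reported both as adjusted alpha
(0.05/9) and adjusted p (min(1, 9p)). Shapiro–Wilk and Levene checks are
emitted as diagnostics only and never gate the pipeline.

## Isotope metrics

δ13C and δ15N are per-mil deviations from V-PDB and atmospheric N2.
Raw tissue values are corrected by subtracting the diet–tissue
discrimination factor Δ = δ_consumer − δ_food for that tissue and
isotope; defaults are the lipid-extracted blood-fraction factors from a
controlled feeding study of a marine predatory fish (δ13C: plasma 1.2‰,
RBC 0.1‰; δ15N: plasma 0.9‰, RBC 1.1‰). Whether such factors should be
subtracted or added is a convention; subtraction (mapping consumer
tissue onto the diet scale) is adopted and isolated in a single
function so it can be swapped. All variance-based niche metrics are
invariant to the choice within tissue, and the rigid-shift property
(between-group differences unchanged by correction) is asserted in
tests. Per-fish habitat/trophic switch metrics are RBC − plasma
differences of the corrected values; fish missing either tissue are
excluded with a logged count.

## Specialization

**Variance decomposition.** For each isotope and each group (each
morphotype cluster, and the pooled population — fitted separately, so
every group gets its own fixed effects and components), the model is

    y_it = b0 + b1 FL_i + b2 tissue_t + u_i + e_it,
    u_i ~ N(0, σ²_B),  e_it ~ N(0, σ²_W),

fit by REML. σ²_W is the within-individual component (WIC), σ²_B the
between-individual component (BIC), TNW = WIC + BIC, and
IS = WIC/TNW ∈ [0, 1] (0 = individual specialists, 1 = individuals as
generalist as the population).

The fitter is native and exploits the model's structure: the criterion
is profiled over λ = σ²_B/σ²_W, with the per-fish block inverse
(I + λJ)^-1 = I − λ/(1+λn_g) J reducing every evaluation to per-fish
sufficient statistics computed once (O(G p²) per λ). Optimization is a
65-point log-spaced scan over λ ∈ [1e-8, 1e8] followed by bounded scalar
search, then a root-polish of the analytic criterion gradient (the
criterion is too flat near its optimum for value-based search to
localise λ to the precision the closed-form equalities below require).
λ = 0 is evaluated explicitly and wins ties, so BIC = 0 boundary
solutions are reported exactly, with a flag. Rows are put into a
canonical content-based order before summation, making the estimates
bit-identical under fish relabeling and row shuffling. In the balanced
intercept-only limit the estimates coincide with the one-way
random-effects ANOVA method-of-moments estimators (truncated at zero),
which the tests assert to 1e-8, alongside a dense-grid criterion oracle
and an independent mixed-model implementation.

**Individual WIC.** Per isotope, an OLS line is fit between the two
tissues pooled across paired fish — plasma predicted from RBC by
default (fast tissue from slow); the direction is unstated in common
practice and switchable here — and each fish's absolute residual is its
individual WIC (‰). WIC values are log10-transformed before modelling;
exact zeros are floored at half the smallest positive value with a
logged count. The GLM on log10 WIC includes morphotype cluster
(categorical), fork length (mm), and year (categorical); optional
interaction terms are simplified sequentially: among non-significant
(p ≥ 0.05) interactions, the one with the smallest |t| is dropped, but
restored if removal raises AIC by more than 2. Main effects are never
dropped; every decision is logged. AIC is the Gaussian-likelihood AIC
(equivalent to n ln(RSS/n) + 2k up to an additive constant). Estimates
and standard errors are additionally reported back-transformed as
10^value.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with known truth, so every stage is testable by parameter recovery:

- **Landmarks.** A stylized 21-landmark lateral cod outline; morphotype
  2 contracts the eight head landmarks toward the head centroid by
  `head_offset_magnitude` (default 0.25). Each specimen is its template
  scaled isotropically through the allometric exponent (default 1,
  isometry; the exponent is a scalar applied to the whole configuration,
  so all nine distances share it — a per-measurement exponent cannot be
  realised by a similarity transform), randomly rotated and translated,
  with Gaussian digitization noise (default sd 2 mm, a typical
  landmark-placement error at this body size) and a per-photo mm/px
  scale.
- **Isotopes.** Latent per-fish means Normal(group mean + fork-length
  trend, σ²_B); tissue observations add the tissue offset (defaults
  equal the discrimination factors, so the generator emits *raw* values
  and the pipeline's correction step is genuinely exercised) and
  within-fish noise σ²_W. A deterministic count round(n × fraction) of
  fish lose one tissue at random.
- **Defaults** mirror the magnitudes of the study population this
  package analyses: 26:19 morphotype mix, fork lengths
  Normal(388.6, 57.6²) mm, group isotope means from the printed tissue
  summaries, σ²_B = 0.36 and σ²_W = 0.24 ‰² (expected IS = 0.40), 31%
  unpaired-tissue fraction, years 2018/2019.
- **Seeding.** One master seed; per-stage sub-streams derived from it,
  so a truth object maps to a byte-identical dataset, and the landmark
  and isotope streams share one fish table.

What the generator does *not* emulate: non-Gaussian digitization error,
fish bending and perspective distortion, correlated δ13C/δ15N errors,
seasonal or ontogenetic isotope structure, and shape variation beyond
the two-template head contrast. Passing recovery tests therefore
demonstrate correctness of the estimators under the assumed model, not
robustness of the field protocol.

## Problem sizes and tolerances used in verification

Recovery and calibration checks run at sizes chosen to make Monte Carlo
error small relative to the asserted tolerance: IS recovery at 200 fish
× 2 tissues × 200 replicates (mean within ±0.05 of truths 0.2/0.5/0.8);
allometric slope at n = 200 with 0.2 mm digitization noise (±0.02, about
three standard errors for the smallest measurement); silhouette
k-selection and label recovery over 100 generator seeds; MANOVA and GLM
null calibration at 2,000 simulations with four-binomial-SD acceptance
bands. Oracle equivalences use a 1e-3 rad rotation-grid GPA oracle,
exhaustive 6-point partition enumeration for k-means, an eigenvalue
identity for Pillai's trace, and dense-grid / method-of-moments oracles
for REML.

## Known limitations

- The nine-measurement pair map and the landmark numbering are package
  conventions; applying the pipeline to an external landmark protocol
  requires supplying the matching pair map.
- The REML engine is specific to a single random intercept (one grouping
  factor); crossed or nested random effects are out of scope.
- IS is reported as a point estimate; no bootstrap or profile interval
  is provided.
- Isotopes are modelled independently; a joint bivariate niche model is
  out of scope.
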