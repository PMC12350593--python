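# Methods

## Box-counting dimension

The estimator is the classic Minkowski–Bouligand box count on a binary
occupancy grid. All counting is anchored at the minimum corner of the tight
bounding box of occupied cells, which makes the counts — and hence the
fitted dimension — bit-identical under translation of the pattern inside a
larger empty volume. Partial boxes at the far edges are counted: the
partition must cover every occupied cell, and omitting rim boxes biases
N(s) low at coarse scales. Scales form a geometric grid {1, b, b², …} with
b = 2 by default (b = 3 for base-3 self-similar phantoms), capped at half
the longest bounding-box side; for b = 3 the full side is appended when it
is an exact power of 3 so that exact-power phantoms contribute their
coarsest level (the Menger sponge's single coarsest box is what makes its
recovery exact rather than asymptotic). At least 3 scales are required for
a fit; requesting more than the grid admits raises an error naming the
limiting axis.

The slope is ordinary least squares of ln N against ln(1/s), natural log on
both axes (slope is invariant to the shared base). A constant series
returns slope 0 with r² = 1 by convention, so a single occupied cell has
dimension exactly 0. Sliding (overlapping) box counting is deliberately not
offered as a default; the partition definition is the established one and
the gliding construction is reserved for lacunarity.

## Gliding-box lacunarity

Window masses are computed from an n-dimensional summed-area table
(inclusion–exclusion over the 2ⁿ window corners), which makes exhaustive
enumeration O(volume) per scale and a subsampled evaluation O(k·2ⁿ) for k
positions. The statistic is Λ(s) = 1 + (σ/μ)², i.e. one plus the squared
coefficient of variation of the window-mass distribution, with population
variance — the statistic is a ratio of moments of the empirical mass
distribution, not an inference about a super-population. The +1 (the
standard Allain–Cloitre form) keeps ln Λ defined for homogeneous patterns,
where CV = 0; a `convention="cv2"` flag preserves the bare-CV² reading and
drops zero-Λ scales from the fit with a warning. Λ ≥ 1 always, with
equality exactly when all evaluated masses are equal (full grid;
checkerboard at even scale).

Windows glide at stride 1 over every position fully inside the occupied
bounding box by default; partial windows are excluded because gliding-box
statistics assume constant window volume. A `domain="grid"` option glides
over the full grid as supplied instead, which makes the statistic sensitive
to empty padding around the mask — occasionally wanted when the grid itself
is the object of interest. A scale admitting fewer than two gliding
positions is rejected (and dropped, with a warning, by the index fit); the
index requires at least three surviving scales.

Subsampling draws ceil(rate·n_positions) positions (minimum 2) uniformly
without replacement, seeded per scale by mixing the master seed with the
scale into the PCG64 seed sequence, so per-scale draws are independent and
a rate of 1.0 reproduces exhaustive enumeration regardless of seed. All
evaluation is serial vectorized numpy; there is no partitioning across
workers, so determinism is unconditional.

## The 4D intensity surface

In-mask intensities are min-max mapped to integer levels
round((v − vmin)/(vmax − vmin)·(L−1)) with numpy's round-half-even;
constant-intensity masks map to level 0. L defaults to the largest spatial
extent of the mask bounding box so the intensity axis is geometrically
commensurate with the spatial axes; it is configurable. Quantization is
invariant under strictly increasing affine transforms of the intensities,
so the sequence LI inherits that invariance. The lift places one occupied
4D cell per in-mask voxel (occupancy conservation holds for every input —
it is checked property-style in the tests). 4D windows use the same scale
on all four axes, clipped per axis to the axis extent, so a
constant-intensity volume (intensity axis of extent 1) reproduces the 3D
lacunarity of its mask exactly. The default position subsample rate is 0.01
(1:100). Nonlinear (histogram-equalized) quantization is not offered.

## Scoring tables

A table is a linear rule on raw feature units (years, cm³, unitless FD/LI):
the published weights fold the 0–1 scaling of the derivation cohort into
the coefficients, so no rescaling happens at application time. Score above
threshold assigns the positive class (grade 2 / soft), below the negative
class; exact equality assigns the negative class with a logged warning,
since the published rule defines only strict comparisons. The consistency
model's LI input is the FLAIR-sequence LI by convention (configurable);
measured LI is insensitive to sequence choice at the 5% level in the source
cohort, and FLAIR is the sequence the source highlights. "Miscellaneous"
consistency cases are outside the binary model and rejected by validation.

The self-check recomputes exp(w) per row and compares with the published
odds ratio to 3 decimals. Five rows agree; the grade-model FD row's printed
OR equals exp(−w), a sign inconsistency in the published table. The score
uses the printed weight (+0.312) and the mismatch is reported, not patched:
silently flipping the sign would change published predictions.

## Model builder

Continuous features are min-max scaled to [0, 1] with bounds computed once
on the full cohort (not per bootstrap sample) so that scale-folded weights
are commensurable across replicates and their average is well-defined on
one raw scale. Fits are scikit-learn logistic regression with C = 1e8 — a
ridge of 1e−8, i.e. maximum likelihood up to numerical stabilization.
Constant features are dropped with a warning; suspected separation
(|coef| > 15 on the scaled design) is flagged but returned.

Each of the n_boot = 100 replicates resamples the cohort with replacement
at full size (replicate seed = master seed + replicate index), fits, and is
evaluated on its out-of-bag patients: AUC (the Mann–Whitney statistic),
plus accuracy/precision/recall at the 0.5-probability operating point.
Single-class resamples or out-of-bag sets are redrawn, capped at 10·n_boot
attempts. Raw-scale weights are the replicate average; the score threshold
is minus the mean raw intercept, making score > threshold equivalent to
averaged-model probability > 0.5. Out-of-bag evaluation is the low-bias
choice for small cohorts; an identity switch (`resample=False`) exists so a
single "bootstrap" reproduces a plain fit exactly.

Feature selection is a two-stage exhaustive search: every non-empty subset
of the fractal features first, then — the winner fixed — every subset of
the clinical features, maximizing mean out-of-bag AUC, ties to smaller
subsets then lexicographic order. Candidates must pass a univariate screen
(equal-variance two-sample t-test for continuous features, two-sided
Fisher's exact for binary ones) at p < 0.05, applied as a pre-filter; if no
fractal feature passes, all are retained with a warning because stage 1
must select something. Stage 2 cannot drop stage-1 features. No
multiple-testing correction is applied to the screen.

A caveat the test suite quantifies: when a pure-noise feature does pass the
screen (expected for ~5% of noise features per cohort), its spurious
association is cohort-wide, so out-of-bag evaluation cannot reject it and
the enlarged subset can win the AUC comparison by a small margin
(~0.001–0.003). On 100 synthetic cohorts (n = 400, one planted feature at
scaled weight 2.5, two noise features) the search recovers exactly the
planted feature in ~88–93 runs; the residual failures are this mechanism,
an inherent property of same-cohort selection rather than an implementation
artifact.

## Phantoms and synthetic cohorts

The study's patient data are not public, so phantoms and cohorts generated
by this package are the test substrate. Deterministic phantoms are built on
exact grids — the Menger sponge by Kronecker construction on side 3^k
(size-guarded at k ≤ 5), cube/slab/line/ball/checkerboard directly — so
dimension recovery is bit-exact rather than asymptotic. Tumor phantoms are
the largest connected component of thresholded, center-biased smoothed
Gaussian noise with an independent smooth intensity texture and an optional
low-intensity necrotic core; they emulate blob topology and smooth texture
but none of MRI physics (no sequences, bias fields, noise spectra, or
scanner heterogeneity), so tests passing on them demonstrate correctness of
the measurements, not clinical performance.

Synthetic cohorts draw features from stated distributions (uniform, normal,
Bernoulli) and labels from a logistic model on [0,1]-scaled features with
configurable true weights; a draw whose minority class falls below 5% is
rejected as degenerate. The "paperlike" presets encode only the directions
of the published group differences (FD higher in grade-1 tumors, grade-2
patients younger, inhomogeneous enhancement and larger volume at higher
grade; LI higher in hard tumors, homogeneous enhancement in soft), with
invented magnitudes — chosen to give roughly balanced classes at n ≈ a few
hundred — that are not claimed to match any cohort. All generators are
pure functions of their spec including the seed (numpy PCG64), so outputs
are bit-identical across runs and platforms.

## Problem sizes and numerical choices

Default test and acceptance problem sizes are: phantoms up to 64³ voxels,
4D lifts up to ~48³×16 cells, cohorts of 400–1000 patients, 100 bootstrap
replicates, and 100-cohort search sweeps at 25 replicates per subset —
sizes at which every guarantee in the suite is exercised in well under a
minute each on one CPU while keeping statistical assertions comfortably
powered. Masses and box counts are exact int64 arithmetic; fits are
closed-form OLS; tolerances are 1e−9 for analytic-phantom slopes (pure
float error) and 1e−12 for oracle-vs-implementation slope agreement on
identical masses.

## Known limitations

- Anisotropic voxel spacing is ignored by all fractal measures (a warning
  fires above 5% anisotropy); inputs are assumed resampled to isotropic
  grids upstream.
- MRI resolution limits the usable scale range on real tumors; with few
  admissible scales the log-log fit is correspondingly uncertain (r² is
  reported with every result).
- The scoring tables are decision rules, not calibrated probabilities, and
  the binary consistency model does not cover mixed-consistency tumors.
- DICOM ingestion, registration and resampling are out of scope; inputs
  are NIfTI-1 only.
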