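# Methods

This note documents the models, algorithms and design choices behind
`osteospec`: what is computed, under which assumptions, and what the
synthetic cohort does and does not establish about real data.

## Spectral model and pre-processing

Absorbance is computed from raw diffuse-reflectance counts as
`A(λ) = -log₁₀((R(λ) - D(λ)) / (W(λ) - D(λ)))`, where `D` is the dark
spectrum and `W` a 99 %-reflectance standard. Channels where `R ≤ D`
(detector noise at very low signal) are masked and linearly interpolated
from their neighbours; a spectrum with more than 5 % masked channels is
rejected outright rather than patched.

Analysis is restricted to one of the three tissue optical windows —
650–950 nm, 1100–1350 nm, 1600–1870 nm, bounds inclusive — regions of
relatively low soft-tissue absorption that reach different depths of an
osteochondral specimen. The pre-processing chain is applied in a fixed
order: **window extraction → MSC → Savitzky–Golay derivative**. MSC runs
after windowing so its reference (by default the mean spectrum of the set
being corrected) is local to the window under analysis. MSC regresses each
spectrum on the reference, `xᵢ ≈ aᵢ + bᵢ·ref`, and returns
`(xᵢ - aᵢ)/bᵢ`; it removes per-sample multiplicative and additive scatter
distortion exactly when the distortion is affine.

Savitzky–Golay derivatives default to 2nd order with a 35-point window and
quadratic fit on the 1 nm grid, scaled to physical units (per nm²). Edge
points use one-sided polynomial fits (scipy's `mode="interp"`), so the
column count is stable. The window length was set wider than the common
25-point habit because with ~40 nm-wide absorption bands the extra
smoothing costs no signal while markedly reducing 2nd-derivative noise
amplification; both parameters are configurable. A non-uniform wavelength
grid is rejected with instructions to resample, rather than silently
mis-scaling the derivative.

## PLS1 calibration and validation

The regression core is single-response partial least squares fitted by
NIPALS on column-centred predictors and centred response: each component
takes the weight direction `w ∝ Xᵀy` (unit norm), scores `t = Xw`,
loadings `p = Xᵀt/tᵀt`, `q = yᵀt/tᵀt`, then deflates both `X` and `y`.
The regression vector is assembled as `b = W(PᵀW)⁻¹q`. Score vectors are
pairwise orthogonal, one component reproduces the covariance direction,
and with as many components as the predictor rank the fit coincides with
ordinary least squares — these three properties anchor the test suite, and
scikit-learn's implementation serves as an additional independent
cross-check in tests only. Deflation is stopped (with frozen predictions
in the cross-validation path, or an error in an explicit fit) when the
residual covariance norm falls below 1e-10 of its initial value.

Validation is seeded shuffled 10-fold cross-validation over a component
grid (default 1–15). Components are nested in NIPALS, so each training
fold is fitted once at the largest grid size and every smaller model is
read off the same pass. Pre-processing that learns from data (the MSC
reference) is refit inside every training fold and applied to the held-out
fold, so no information leaks from test spectra into their own correction;
a non-fold-wise variant is available for comparison. RMSECV is computed on
the pooled held-out predictions and RMSEC from an all-data fit, both as
percent of the reference range: `100·RMSE/(max(y) - min(y))`. R² is the
squared Pearson correlation between measured and cross-validated predicted
values, switched to Spearman when the response fails the
D'Agostino–Pearson normality test at α = 0.05 (as bone volume fraction
typically does).

The number of components is chosen by a parsimony rule: the smallest count
whose RMSECV is within 5 % of the grid minimum. This operationalises the
usual multi-objective statement ("few components, low RMSECV, high R²")
as a single deterministic rule; the tolerance is configurable.

A note on the null behaviour of cv-R²: because R² is a squared
correlation, a chance correlation between the response and any strong
latent spectral factor propagates consistently through cross-validation,
giving the permuted-response cv-R² a heavy right tail at n = 48. Its mean
over permutations is the meaningful null-safety summary (a few percent
under the default generator); individual permutations can exceed 20 %.

## Bone morphometry

Input volumes are isotropic binary voxel grids, axis order (z, y, x) with
z increasing from the cartilage-facing surface. A 1.0 × 1.1 × 1.8 mm³
volume of interest at 12.5 µm voxels is cropped laterally centred and
anchored at the first bone-containing slice. A convenience Otsu threshold
is provided for grayscale stacks, but the analysis contract is binary
input — threshold selection on real reconstructions is a separate problem.

**Plate/trabecular split.** The subchondral plate is the bone component
reaching the top face, bounded below per (y, x) column by the first
background run of at least 75 µm (+1 voxel, since a discretised pore of
physical size d can span d/voxel + 1 voxels) — the first large marrow
space. Background components enclosed in the plate band are intracortical
pores; each is kept as plate porosity iff its voxel count is less than
twice the mean pore size in the region, or its equivalent spherical
diameter (26-connectivity component) is smaller than the distance from its
centroid to the endocortical boundary minus a 2-voxel margin. Pores
failing both are counted as marrow-side space; since pores contain no
bone, this bookkeeping does not move bone labels. The pore table and
boundary surface are returned for audit.

**Parameters.**
* *BV/TV* — bone voxels over total voxels in the compartment's z-band,
  excluding voxels claimed by the other compartment; exact integer
  counting.
* *Sb.Th, Tb.Th* — local thickness by the largest-inscribed-sphere
  definition: Euclidean distance transform for maximal sphere radii,
  followed by sphere painting from the largest radius down. Radii are
  floored into quarter-voxel bins and each bin painted with its upper
  edge, so every exact sphere is covered by its painted counterpart and
  the recorded diameter undershoots by at most half a voxel; thin rim
  shells between bins are the residual error mode. The depth axis is
  padded with background before the distance transform (the top and deep
  faces are real surfaces; lateral faces are ROI cuts and are not).
* *SMI* — `6·V·S′/S²` evaluated on the surface offset two voxels outward:
  surface areas come from marching-cubes isosurfaces of a half-voxel-
  corrected, lightly smoothed signed-distance field at offset levels 1, 2
  and 3, with `S′` by central difference and `V` by anti-aliased counting
  at offset 2. For the ideal shapes the index characterises (plate 0,
  rod 3, sphere 4) it is invariant under such offsets, and the offset
  lifts the estimate off the voxel staircase; structures closer together
  than twice the offset partially merge, and strongly concave structures
  can legitimately give negative values. The field is not padded, so
  structure faces on the array boundary stay open — a slab or rod spanning
  the region behaves as its infinite analytic counterpart.

## Synthetic cohort

The generator emulates the study conditions of a cadaver cohort: 48
samples from 13 donors at four locations (FG 11, FLC 11, TLP 13, TMP 13 —
two of a nominal 50 excluded), spectra on a 650–1870 nm grid at 1 nm, and
per-sample bone volumes at 12.5 µm voxels.

**Morphometry draws** are truncated normal per location. Default means
(mm / fraction / unitless) place TMP strictly highest in Sb.Th
(0.26/0.28/0.31/0.40 for FG/FLC/TLP/TMP), Tb.Th (0.15/0.16/0.18/0.23) and
BV/TV (0.20/0.23/0.27/0.38), with SMI trending lower at TMP
(1.9/1.7/1.5/1.2); SDs 0.06, 0.035, 0.07 and 0.5. These are
order-of-magnitude emulation choices inside physiological ranges — the
source cohort is not deposited, so nothing is fitted.

**Mankin scores** (1–9) are linked to plate thickness: the probability of
a score above 4 is logistic in the *within-location* standardised Sb.Th
with slope 3.0, intercept solved so the expected high-score rate is 0.30.
Conditioning within location keeps the link from aliasing the anatomical
location differences into the other parameters, so Tb.Th and BV/TV stay at
the nominal false-positive rate in class comparisons; the resulting class
separation is ≈1.4 within-location SD ≈ 1 cohort SD of Sb.Th, and scores
within a class follow fixed decreasing distributions (1–4 and 5–9).

**Spectra** are a fixed quadratic baseline plus Gaussian bands (truncated
to compact support at 5σ). Four 18 nm-wide bands in the first window (720,
780, 845, 905 nm) have amplitudes `0.05 + 0.0021·z` in the standardised
parameters (one band per parameter); six bands in the second and third
windows vary independently of morphometry (SD 0.005). Each spectrum then
receives multiplicative scatter `(1+slope)·x + offset` (slopes SD 0.05,
offsets SD 0.02) and additive channel noise (SD 5·10⁻⁴ AU in OW1, rising
to 3·10⁻³ in OW3, as for an InGaAs detector after co-added scans). The
attainable (population) R² is set by per-sample band-amplitude jitter of
0.0007 = coeff/3, i.e. R²_pop = 1/(1+1/9) ≈ 0.90: the limiting noise is
compositional variation the morphometric parameters do not explain, not
detector noise — which is also why the full pipeline's cross-validated R²
(mean ≈ 86–87 % over cohorts, single-cohort spread roughly ±6 points)
comes close to the population value.

**Volumes** are a solid plate slab of thickness Sb.Th with sparse
spherical pores of two physical size classes (30 and 60 µm), a ~100 µm
marrow gap, and below it a jittered three-axis rod lattice with strut
radius Tb.Th/2 and spacing set by the overlap-corrected occupancy relation
`1-(1-f)³ = BV/TV`, `s = r√(π/f)`. The final strut radius is the exact
BV/TV quantile of the distance-to-axes field, which pins the volume
fraction while keeping strut thickness within ~10–20 % of target (sphere
junctions inflate measured thickness; the effect cancels in paired
comparisons of geometrically similar lattices). When a dimension would
hold fewer than ~2.5 lattice cells the spacing is capped and the rod
population randomly thinned instead, preventing the quantile from
fattening struts. The marrow gap detaches vertical rods from the plate so
the endocortical boundary is defined in every column — a deliberate
idealisation; real trabeculae merge into the plate. The drawn SMI value
drives the spectra only; the volume's actual SMI is determined by its
structure.

**What passing tests show** — that the pipeline recovers known signal at
realistic sample size, noise and effect scales; that its nulls are
calibrated; that the morphometry operators agree with analytic and
exhaustive oracles. **What they do not show** — performance on real
tissue: real NIR spectra have correlated, chemistry-driven band structure
and nonlinear scattering, real trabecular bone is not a rod lattice, and
real segmentation starts from grayscale reconstructions. The cohort is an
analogue, not a reproduction.

## Statistics

Group comparisons are gated on the D'Agostino–Pearson omnibus test per
group at α = 0.05 (groups below n = 8, the test's minimum, are routed
non-parametric): ANOVA with pairwise t-tests when all groups pass,
Kruskal–Wallis with pairwise Mann–Whitney otherwise; the branch taken is
recorded in every result. Pairwise p-values are reported raw by default
(Holm correction available). Mankin classes use strict inequalities
(< 4, > 4); scores of exactly 4 are excluded and counted. Summaries are
means with 95 % t-intervals. All tests are deterministic given the data.

## Problem sizes and determinism

Default analyses use the 48-sample cohort, 10-fold CV over 1–15
components, and replications of 20 cohorts (calibration band, window
ordering, permutation nulls) or 200 draws (power and null calibration of
the group statistics); phantom checks use 40³–100·51² voxel structures and
generator phantoms at 25 µm. These sizes make every property statistically
decidable while keeping a full run in minutes on one core. Every source of
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configuration and seed reproduce
every output file byte for byte.
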