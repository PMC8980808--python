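# Methods

## Imaging model and normalization

A study is five co-registered 3D scalar volumes (T1w, Gd⁺ T1w, T2w, FLAIR,
ADC), an integer label map (0 background/normal-appearing, 1 necrosis,
2 CET, 3 nCET, 4 edema, 5 hemorrhage) and an intracranial-volume (ICV)
mask, all on one grid. Registration, bias-field correction and skull
stripping are upstream concerns; the loader validates their postcondition
(identical shapes, affines agreeing within 1e-3) and refuses to resample.
Non-finite voxels are rejected at load time rather than masked, because a
silently imputed value could enter the normalization reference extrema.

Normalization is the affine map `(x − min_ref)/(max_ref − min_ref)` with
the extrema taken over *normal-appearing* voxels: ICV ∧ label 0. Hemorrhage
is excluded both from the reference region and from every feature ROI.
Values are not clipped — lesion voxels legitimately fall outside [0, 1] and
the fraction outside is logged. The map is invariant to affine intensity
rescaling of the input, which the tests assert numerically. ADC maps are
normalized like the structural images for uniformity; users who need
physical diffusion units can pass raw volumes directly to the feature
functions.

## Feature schema

Per compartment: ROI volume (mm³) and volume normalized to the ICV voxel
count; per compartment × image: mean, sample SD (n−1; a single-voxel ROI
has a missing SD), and fractality — 17 features per compartment, 68 total.
Missing ROIs produce missing cells, never zeros. Column names follow
`{tissue}__{image}__{kind}` with `image = none` for the two morphological
kinds.

### Fractality

`fractal_dimension_mask` partitions the mask's bounding box (anchored at
its minimal corner, padded with background to a multiple of the box size)
into s³-voxel boxes, counts occupied boxes N(s), and returns the
least-squares slope of log N(s) against log(1/s), clipped to [0, 3] (the
raw slope can overshoot 3 slightly through edge effects). Default box
sizes are powers of 2 from 1 up to half the bounding box's shortest side,
with a floor of {1, 2} for thin boxes; a single box size is an error. The
implementation is verified against analytic values (full cube → 3, single
voxel → 0, level-3 Menger sponge → log 20/log 3, slab → ≈2) and against an
independent triple-loop counter on random masks, exactly.

`fractality` binarizes the masked intensities at 9 equally spaced levels
strictly between the ROI minimum and maximum (superlevel sets, `≥ level`)
and averages the dimension over the nonempty level sets; a
constant-intensity ROI falls back to the dimension of the ROI mask itself.
Both the threshold count and the box sizes are configurable; the default 9
thresholds split the intensity range into deciles.

One property of this construction deserves emphasis: the level sets are
*solid* regions, so smoother texture produces more compact, blob-like sets
whose box-count dimension approaches 3, while rough, fine-grained texture
produces scattered sets with dimension near 2. The threshold-averaged
dimension therefore *increases* with the spatial smoothness of the signal.
The per-sample statistic is noisy in the texture scale — strict pairwise
ordering between a rough and a smooth rendering of the same noise field
fails in roughly a quarter of cases at desk-scale ROIs — so the test suite
asserts monotonicity of the seed-averaged response across a smoothing grid
together with a strong pooled rank correlation (measured ρ ≈ 0.71), not
per-pair ordering. A boundary-counting variant (dimension of the level-set
surface) was evaluated and discarded: its threshold average is not
monotone in the texture scale in either direction.

## PCA machinery

Features are z-scored per column (mean 0, SD 1, n−1 denominator; constant
columns dropped with a warning, all-missing columns are errors). PCA is a
full SVD (scikit-learn) on complete rows — rows with any missing cell in
the block are dropped, which preserves the largest per-block n; pairwise
completeness is used only in the correlation stages. Explained-variance
fractions sum to 1 and loadings are orthonormal; both are asserted to
1e-9/1e-8. A deterministic sign convention — each component's
largest-magnitude loading is made positive — removes the SVD sign
ambiguity so repeated fits are bit-identical.

The retained-component count is the smallest k whose cumulative explained
variance reaches 80% (inclusive, configurable).

**Multi-group PCA:** each group is z-scored within itself, per-group
models are fit per group, and the pooled model is fit on the stacked
within-group-standardized rows (groups with fewer than two complete rows
are skipped with a warning). Within-group standardization prevents group
offsets and scale from masquerading as components; the construction is
deliberately simple and stated here because more elaborate common-loading
estimators exist.

**Loading similarity:** a single-window SSIM over the entries of two
feature-aligned loading matrices truncated to `k_used = min(k_a, k_b)`
components (by default the minimum of the two 80%-variance counts):

    SSIM = l · cs,  l = (2 μ_a μ_b + C1)/(μ_a² + μ_b² + C1),
                    cs = (2 cov + C2)/(σ_a² + σ_b² + C2),

with C1 = (0.01·L)², C2 = (0.03·L)², L = 2 for the loading range [−1, 1].
Loading matrices are small (~17 × 4–6), so a single global window is used
rather than local windows. Two numerical guards: the luminance factor `l`
is floored at 0 — for matrices with nonzero entry means, anti-alignment
drives *both* factors negative and their product would spuriously approach
+1 — and the final value is clamped to [0, 1]. Identical matrices score
exactly 1; anti-aligned matrices score 0; the index is symmetric.

Two limitations of the sign-alignment + SSIM combination, found during
validation and left visible rather than patched: (i) when a component's
top two loading magnitudes are near-tied with opposite signs, the argmax
convention can orient the component differently in two samples from the
same population, collapsing the similarity to ~0; (ii) components beyond
the true factor rank of the data are noise and never replicate across
samples, so similarity over the 80%-variance components is only a
repeatability measure when those components reflect genuine structure.
The stability test in the acceptance suite uses an anchored 3-factor
model for exactly these reasons.

**Rank tests:** Kruskal–Wallis (ties-corrected, χ² p-value) and two-sided
Mann–Whitney (exact enumeration when both n ≤ 20 and no ties, otherwise
the ties-corrected normal approximation), thin wrappers over
scipy.stats with degenerate all-tied inputs short-circuited to
(H = 0, p = 1) and (U = n₁n₂/2, p = 1), where the generic tie correction
would divide by zero. Measured null rejection rates at α = 0.05 are
0.044/0.0435 over 2000 replicates.

## Immune model and the BMDM/MG ratio

Specimens carry the gating hierarchy: leukocytes (% of live), myeloid
(% of leukocytes), BMDM and MG (% of myeloid, BMDM + MG ≤ 100). Parsing
rejects out-of-range frequencies, gating violations and unknown sites.
Within each (subject, site) the four frequencies are averaged *first* and
the ratio computed from the averages — the alternative (averaging
per-sample ratios) is unstable when a sample's MG is near zero, and the
tests keep a counterexample showing the two orders genuinely differ. A
zero averaged MG makes the ratio undefined (neither 0 nor ∞); undefined
ratios are excluded from comparisons and correlations with counts logged,
rather than papered over with an epsilon.

Site comparisons run one Kruskal–Wallis across sites plus all pairwise
Mann–Whitney tests at α = 0.05 for each of the four populations and the
ratio.

## Synthetic cohort

The generator plays the role of the study population; its defaults are the
package's study conditions.

**Geometry.** Concentric ellipsoidal shells (necrosis ⊂ CET ⊂ nCET ⊂
edema; base radii 10/20/28/40 mm) centered in an ellipsoidal ICV (66 mm)
on a 48³ grid of 3 mm voxels. Real lesions are irregular; concentric
shells are the simplest geometry that makes all four compartments and
their features well-defined. Per-subject log-normal common scale (σ = 0.15)
plus per-shell jitter (σ = 0.05, with nesting re-enforced) keeps the
morphological features informative rather than constant.

**Contrast and texture.** Each sequence has fixed per-compartment mean
intensities encoding standard GBM appearance (dark T1w necrosis, avid CET
enhancement on Gd⁺ T1w, bright T2w/FLAIR edema, elevated ADC in necrosis
and edema), flat background noise (SD 0.02) inside the ICV, and a lesion
texture field: white noise smoothed with a Gaussian kernel whose width
maps linearly from the subject's latent roughness u ∈ [0, 1]
(σ = 2.0 voxels at u = 0 down to 0.5 at u = 1), scaled by 0.25 and added
within the lesion. The smoothed noise is deliberately not re-normalized:
rough subjects get both higher within-ROI SD and lower threshold-averaged
fractality, giving the correlation stage two monotone feature families.

**Immune frequencies.** Leukocyte and myeloid percentages are logit-normal
around the configured site medians — central sites 41.5% leukocytes,
margin 29.2%, myeloid 94.3/92.3/92.8% — so the configured medians are
exact distribution medians. BMDM and MG are built from a total macrophage
share t of myeloid (logit-normal, median (bmdm+mg)/100, σ = 0.3) and a
BMDM-vs-MG split s (logit-normal, σ = 0.6): BMDM = 100·t·s,
MG = 100·t·(1−s). The gating bound holds by construction and the ratio
equals s/(1−s), exactly log-normal with median bmdm_med/mg_med. Default
ratio medians 2.5/2.0/0.8 (necrosis/core/margin) encode the
BMDM-high-central, MG-high-marginal gradient; the source data report the
gradient direction but not dispersions, so the σ values are realistic
choices, stated here and not claimed as measured. Note that the BMDM% and
MG% medians themselves are medians of products of logit-normals and so
track their nominal values only approximately; the exact calibration
parameters are the leukocyte, myeloid and ratio medians.

**Coupling.** A Gaussian copula ties the core-site split to the roughness
latent: with z₁ the roughness normal score (u = Φ(z₁)) and
z₂ = ρ z₁ + √(1−ρ²) ε, the core-site split uses z₂ while the other sites
draw independent scores. The planted ρ (default −0.4) lives on the normal
scores; the Pearson correlation between the observed uniform roughness and
log-normal ratio attenuates to ≈ 0.90 × 0.98 × ρ ≈ −0.36, within the
recovery band the tests check. Specimen availability is Bernoulli per
site (present with probability 58/62, 37/62, 31/62 for core, necrosis,
margin), exercising pairwise-complete handling downstream.

**Determinism.** All randomness descends from a single `default_rng(seed)`
consumed in a fixed order; equal (seed, config) pairs give byte-identical
serialized cohorts, which the tests assert by hashing both an in-memory
canonical serialization and the written files.

### What the generator does not emulate

No MR physics (bias fields, partial volume, scanner differences), no
irregular lesion shapes, no spatial correlation between the imaging
texture and the *within-lesion* location of specimens, and no
cross-population covariance among the four immune variables beyond the
BMDM–MG complementarity — so the cross-site *immune* loading-similarity
analysis runs but is not a calibrated recovery target, and passing tests
demonstrate correctness of the computational chain on data with the
planted statistical structure, not clinical performance on patient data.

## Pipeline and problem sizes

`analyze_cohort` chains normalization → feature extraction → per-tissue
and aggregate PCA → cross-tissue PC correlation (first 4 PCs) → loading
similarity → immune aggregation and site tests → the PC × site ratio
correlation table (Pearson r, two-sided t-distribution p with n−2 df,
n ≥ 3 pairwise-complete subjects per row; PCs beyond the 80% cut retained
but flagged). No multiple-testing correction by default, matching the
raw-α reporting convention of the analysis it implements;
Benjamini–Hochberg is available via the `fdr` flag, and a log-ratio
option exists for users worried about the ratio's skew.

Default analysis scale is 62 subjects on the 48³ grid (≈8 s per cohort
end-to-end on one core). The statistical acceptance suite uses 50 such
cohorts for the end-to-end recovery check, 100 immune-only cohorts for the
gradient power check, 2000 replicates for test calibration, and n = 200
for calibration of medians and coupling — sizes at which the Monte-Carlo
error is comfortably inside each asserted band.
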