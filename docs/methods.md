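# Methods

## Data model

The pipeline operates on cell-level phenotype tables: one row per segmented
cell with patient id, ROI id, staining panel, x/y position in μm (origin at
the ROI top-left; there are no global tissue coordinates because every
analysis is per-ROI), and a phenotype label. Two panels are modeled. Panel 1
identifies CK⁺ tumor/epithelial cells, CD3⁺Foxp3⁻ T cells, CD3⁺Foxp3⁺
regulatory T cells, CD20⁺ B cells and CD117⁺CK⁻ mast cells, with a Ki67
proliferation co-flag. Panel 2 identifies CK⁺ tumor cells, CD8⁺ cytotoxic T
cells (Tc), CD8⁻ T cells and CD68⁺ macrophages, with PD-1 and PD-L1
co-flags. Co-flags are stored separately from the phenotype so PD-1/PD-L1
positivity composes with any phenotype.

Phenotypes are derived from marker flags by first-match-wins rules in a
fixed priority order — CK > (CD3·Foxp3) > CD3 > CD20 > CD117 on panel 1 and
CK > (CD3·CD8) > CD3 > CD68 on panel 2 — so that rare double-positive
conflicts resolve toward epithelial identity, keeping the TPS/CPS
denominators stable. Cells matching no rule are "other".

### Marker gating

The upstream study assigned phenotypes with automated cytometry-style
gating whose internals are not part of this package's scope; the gating
operator here is a deliberately simple stand-in, not a reproduction. Per
marker, the pooled log-intensity distribution across the cohort is smoothed
with a Gaussian KDE and thresholded at the deepest density minimum between
the two largest modes; positivity is intensity strictly above the
threshold. A unimodal distribution falls back to a configurable intensity
quantile (default 0.99) with a warning, so degenerate markers produce
(almost) no positives rather than arbitrary splits. Thresholds are logged.

## Density features

Population fractions are 100 × (cells in population, pooled over all of the
patient's ROIs of that panel) / (total cells in those ROIs) — cell-weighted
pooling, not a per-ROI average, matching the percent-of-total-cells
convention. Panel-1 and panel-2 fractions use their own panel's
denominator; the registry ships 18 populations (T = all CD3⁺ including
Tregs; TIL = T + B; Ki67⁺ tumor/T/B; Tc, CD8⁻T, macrophages; PD-1⁺ and
PD-L1⁺ subsets). A patient with no cells on a panel gets missing values,
not zeros. TPS and CPS follow the clinical definitions with the
tumor-cell denominator; CPS is not capped at 100 (some clinical conventions
cap it; the choice is logged per run) and CPS ≥ TPS holds by construction.

## Spatial metrics

**Morisita–Horn.** Each ROI is divided into non-overlapping 200 μm × 200 μm
squares anchored at the ROI origin with half-open membership
[k·200, (k+1)·200); partial edge squares are kept, since dropping them would
discard cells. The index for count vectors a, b with totals A, B is

    MH = 2 Σᵢ aᵢbᵢ / [(Σᵢaᵢ²/A² + Σᵢbᵢ²/B²) · A · B]

— the standard Morisita–Horn similarity, symmetric, 0 for disjoint support,
1 for proportional vectors. Per patient, square vectors are concatenated
across ROIs before a single evaluation (per-ROI averaging is available
behind a flag for sensitivity analysis). A pair needs ≥ 10 cells of each
type patient-wide (configurable) to be reported; sparser patients get a
missing value rather than a noise-dominated index. 21 unordered pairs are
registered: 8 panel-1 pairs (tumor against T/Treg/B/mast/TIL, plus
T–Treg, T–B, Treg–B) and 13 panel-2 pairs (tumor against Tc/CD8⁻T/Mac,
Tc–Mac, and the nine PD-1⁺ × PD-L1⁺ combinations).

**G(r) and SPS.** G(r) is the empirical fraction of type-a cells whose
nearest type-b cell (exact Euclidean nearest neighbor via KD-tree) lies
within r, evaluated on a 0–20 μm grid with 0.25 μm steps. No edge
correction is applied: the score is the raw observed fraction, and the
20 μm horizon is small relative to the 600 × 450 μm field, so boundary
effects are minor — a deliberate divergence from the defaults of
general-purpose point-pattern software. The per-ROI area under G(r)
(trapezoid rule; integration error < 10⁻³ for step functions with ≥ 4
cells) is normalized by the 20 μm horizon and averaged without weights over
the patient's ROIs that contain at least one a-cell; an ROI without
b-cells contributes G ≡ 0. The resulting SPS is unitless in [0, 1] and
directional; the raw-AUC convention in μm is recoverable by multiplying
by 20. Normalization is a monotone rescaling and does not affect
rank-based association. 20 ordered pairs are registered, mirroring the MH
pairs plus the reverse tumor/lymphocyte directions.

## Multi-platform features

Expression-signature scores are unweighted means of member-gene values on
the log2 scale — the simplest rule consistent with standard signature
practice; weighted definitions can be supplied per signature in config. The
registry names 38 signatures (26 immune, 10 DNA-damage-response, 1
proliferation, 1 hormone-receptor); gene lists are configuration, and
synthetic runs use synthetic five-gene lists wired to per-patient latent
scores.

RPPA arrays are standardized before concatenation by subtype-balanced
resampling: per array, draw 5,000 subtype-stratified resamples matching
the reference receptor-subtype mix (HR⁺HER2⁻ 0.384, TN 0.368, HR⁺HER2⁺
0.158, HR⁻HER2⁺ 0.09), compute the mean of resample means and the mean of
resample standard deviations per endpoint, and z-score by those moments.
Strata are drawn without replacement when the stratum is large enough
(falling back to replacement otherwise), so a single full-sample resample
reduces exactly to a plain z-score. Proportions are renormalized over the
subtypes present in an array, logged; zero-variance endpoints become
missing.

The biomarker matrix outer-joins the platform blocks on patient id —
patients missing from a platform get missing values, never zeros — and
enforces the registry arithmetic 18 + 2 + 21 + 20 = 61 mIF features and
61 + 38 + 27 = 126 total as a configuration self-check.

## Association screening

Each feature is tested per cohort (arm × receptor subtype, with "ALL"
pooling subtypes; cohorts below 10 patients are skipped with a warning) by
a likelihood-ratio test between nested logistic models, logit(pCR) ~
covariates + feature versus covariates only, 2(ℓ₁ − ℓ₀) ~ χ²₁. Features
enter continuous and z-scored (no dichotomization); missing patients are
dropped listwise per feature, with no imputation; tests are two-sided and
the direction is the coefficient sign. Quasi-complete separation —
non-convergence or |coefficient| > 20 on standardized predictors — triggers
a refit of both nested models with an L2 ridge penalty of 10⁻⁴ and the
result is flagged. Benjamini–Hochberg correction is applied within cohort ×
platform families by default (whole-cohort families behind a flag; the
family definition is genuinely open and both are useful), and results are
tiered BH-significant / nominal / not-significant at α = 0.05. The
interaction test adds a feature × arm term over feature + arm and tests it
by the same LR construction.

## Microenvironment classes

TIL < 12.5% of total cells defines TIL-low; TIL-high patients split at the
median PD1Tc_PDL1 MH index of the cohort being classified (a fixed cut can
be supplied). Boundary conventions — TIL exactly at the cut is high, MH
exactly at the median is low — are arbitrary where the convention is
unstated, chosen once and logged. Class–response association uses Fisher's
exact test: 2×2 through scipy, r×c by exhaustive enumeration over all
tables with the observed margins (total probability of tables no more
probable than the observed one), with a Monte-Carlo fallback above 2,000
subjects. Cross-platform agreement is quantified with Pearson correlations
per configured feature pair.

## Synthetic cohorts

The generator's defaults mirror the study conditions the pipeline targets:
~98 patients, HR⁺HER2⁻:TN ≈ 55:45, experimental:control ≈ 55:45, 15–20
ROIs per patient per panel. ROI fields default to 600 × 450 μm — the true
field dimensions of a 20× multispectral scan are not critical so long as
they are comfortably larger than the 200 μm quadrat; the default gives a
3 × 3 quadrat grid with partial edge squares, exercising the edge-handling
path. Expected cells per ROI (~200/panel: 120 tumor, 40–50 other, the rest
immune) give cohort-level immune fractions spanning roughly 5–60% of
cells once per-patient heterogeneity is applied: a shared lognormal
immune-abundance multiplier (σ = 0.7) plus per-phenotype lognormal noise
(σ = 0.3), yielding a TIL-low (< 12.5%) fraction of roughly 15–20% of
patients. Co-flag positivity rates are Beta-distributed per patient
(Ki67 ~ Beta(2, 10); PD-1 and PD-L1 ~ Beta(1.5, 12)); these rates are
higher than the rarest clinical PD-1/PD-L1 fractions so that
colocalization indices are defined for most simulated patients.

Colocalization between chosen spatial-type pairs uses a Thomas-type
parent/offspring cluster process: shared parents uniform in the window
(one per ~20 cells), offspring displaced by isotropic Gaussian noise with
dispersion σ and wrapped toroidally at the window edges. Wrapping keeps
the marginal intensity uniform — clipping would pile points on the
boundary and artificially inflate proximity at large σ — so σ → ∞
recovers independent uniform patterns and a single σ knob maps
monotonically to both MH and SPS. Segregated pairs occupy disjoint window
halves; independent pairs are homogeneous uniform. A per-patient σ can be
drawn log-uniformly from a range to create between-patient colocalization
variance.

Response is Bernoulli with logit = intercept + Σ coef · z(feature), where
the features are the *realized* values computed by the pipeline's own
feature code from the simulated cells (or the latent signature/endpoint
scores for mRNA/RPPA features), z-scored within the cohort so coefficients
are scale-free. Arm-specific coefficients (active in the experimental arm
only) generate treatment interactions. All randomness flows from one seed;
per-(patient, ROI, panel) substreams are derived by seeding from the index
tuple, so any subset of patients reproduces identically regardless of
cohort size.

A patient-level shortcut, `simulate_feature_matrix`, draws the biomarker
matrix directly as independent standard normals with the same logistic
response link. Calibration, false-discovery and power simulations use this
path (hundreds to thousands of replicate screens; the spatial generative
detail is irrelevant to those properties), while cell-level simulation
backs the spatial and end-to-end checks.

### What the generator does not emulate

Raw fluorescence images, segmentation error, staining batch effects,
between-platform batch structure, correlated feature blocks (fast path),
and tissue architecture (stroma/epithelium compartments, tertiary lymphoid
structures). Passing tests therefore demonstrate correctness of the
computations and calibration of the statistics under idealized sampling,
not robustness to the artifacts of real staining and segmentation.

## Numerical conventions and problem sizes

Quadrat membership is half-open with partial edge squares retained; the
radius grid is 0–20 μm in 0.25 μm steps; MH requires ≥ 10 cells of each
type; logistic fits use Newton iterations with a ridge fallback at 10⁻⁴;
the r×c Fisher test enumerates exactly up to 2,000 subjects and samples
100,000 margin-fixed tables beyond. Simulation-backed checks in the test
suite use 200–300 seeds for Monte-Carlo comparisons, null calibration at
2,000 replicates (n = 120), screen-level false-discovery control at 200
replicate 126-feature screens (n = 150), and recovery/interaction power at
50 replicates (n = 300–400) — sizes at which the Monte-Carlo error of each
check is small relative to its acceptance margin. The
dispersion-monotonicity check uses 60-cell patterns on a 1200 × 800 μm
window: at the fixed 200 μm quadrat scale the MH index saturates for dense
patterns (hundreds of cells in a handful of squares), and a sparse pattern
keeps the index's dynamic range so that the σ ordering is resolvable.

## Known limitations

- The gating operator is a stand-in; real auto-gating pipelines use
  per-image templates and hierarchical gates.
- Whether panel-1 and panel-2 fractions should share a denominator across
  panels is ambiguous when a single case pools both panels; the
  implementation is strictly per-panel.
- The per-signature gene lists and the exact 21/20 spatial pair rosters are
  configuration seeded with the named, published pairs plus
  panel-consistent completions to the stated counts; analyses of real
  cohorts should supply the study's own registries.
- No spatial edge correction; estimates of G(r) near ROI boundaries are
  slightly biased downward, identically across patients.
- The BH family definition (per platform vs whole cohort) changes which
  features clear the significance threshold; both scopes are implemented
  and the choice is recorded in the manifest.
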