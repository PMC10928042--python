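# Methods

## Signal models and units

All computation uses an internal unit system of mm, s and T: diffusivities
in mm²/s, b-values in s/mm², the microstructural length μ in mm, the
gyromagnetic ratio γ in rad s⁻¹ T⁻¹ (default 2.6752×10⁸, the proton value;
configurable on `AcquisitionProtocol`). Parameter *maps* are rendered in the
field's reporting units — diffusivities in 10⁻³ mm²/s, μ in μm — so ROI
summaries read like published tables.

The four decay models of the relative signal S(b)/S(0) are

| model | form | fitted b subset |
|---|---|---|
| IVIM | (1−f)·e^(−b·D_t) + f·e^(−b·D_p) | 0, 50, 80, 150, 300, 500, 800 |
| DKI | e^(−b·MD + b²·MD²·MK/6) | 0, 500, 800, 1000, 1500, 2000, 3000 |
| SEM | e^(−(b·DDC)^α) | same as DKI |
| FROC | e^(−D·μ^{2(β−1)}·(γG_dδ)^{2β}·(Δ − ((2β−1)/(2β+1))δ)) | all 11 |

All four return exactly 1 at b = 0 and are strictly decreasing in b inside
their validity ranges (for DKI, up to b = 3/(MD·MK); beyond it the quadratic
cumulant turns upward and the model emits a `DkiValidityWarning` rather than
refusing to evaluate, because fitted MK moves through invalid territory
during optimisation).

The b ↔ G_d mapping uses the conventional rectangular-lobe Stejskal–Tanner
relation b = (γG_dδ)²(Δ − δ/3). The FROC model's modified diffusion-time
term Δ − ((2β−1)/(2β+1))δ appears only inside its exponent; scanners report
b computed with the conventional form, so the conventional form is what the
inversion must match. At β = 1 the two coincide and FROC collapses to
e^(−D·b) exactly (μ cancels).

## FROC identifiability

With a single (Δ, δ) pair and b varied only through the gradient amplitude,
q = γG_dδ is a bijection of b and the FROC exponent factorises as
C · q^{2β} · τ(β) with C = D·μ^{2(β−1)}. A measured decay therefore
determines exactly two quantities — β and C — while D and μ individually
lie on an exactly flat ridge (for any μ′, D′ = D·(μ/μ′)^{2(β−1)} produces
the identical signal). Consequences adopted here:

* `fit_froc` performs the conventional staged joint fit (D initialised from
  the log-linear slope over b ≤ 1,000; β = 0.9, μ = 5 μm; joint bounded
  refinement) and returns the (D, β, μ) decomposition, but the result object
  also carries the identifiable composite and flags μ as non-identifiable;
  a μ pinned at its box bound is flagged separately.
* Round-trip validation of FROC asserts β and the composite (both recover to
  machine precision on noise-free decays); D and μ individually land near
  the initialisation's projection onto the ridge and should not be compared
  against generating truth.
* Separating D from μ would need acquisitions at two or more diffusion
  times (varying Δ or δ), which is outside this package's scope.

## Voxel-wise fitting

One bounded least-squares machine (`scipy.optimize.least_squares`,
trust-region reflective — the box-bounded member of the Levenberg–Marquardt
family; ftol = xtol = gtol = 10⁻¹⁴) backs all models. S(0) is always the
measured (smoothed) b = 0 voxel value, never a free parameter. Box bounds,
physiological ranges plus headroom:

* D_t, MD, DDC, D ∈ (10⁻⁵, 3×10⁻³) mm²/s; f ∈ [0, 1]; MK ∈ [0, 3];
  α, β ∈ (0.01, 1]; μ ∈ (0.1, 50) μm.
* D_p ∈ (3×10⁻³, 0.1) mm²/s. The lower edge sits above the D_t ceiling, so
  d_p ≥ d_t holds structurally, and it keeps the pseudo-diffusion
  compartment from merging with tissue diffusion under noise: without the
  floor roughly one noisy voxel in seven (SNR 50, f ≈ 0.03) collapses into
  a degenerate single-compartment solution with f > 0.5. Reported tumor D_p
  values (≈6–14×10⁻³ mm²/s) are far above the floor.

Initialisation is deterministic: IVIM uses a segmented pre-fit (log-linear
tail b ≥ 300 → D_t and intercept; f = 1 − intercept; D_p from the low-b
residual) followed by full joint refinement — the segmented step is
initialisation only, the reported parameters come from the joint fit. DKI
and SEM start from a two-point log-linear diffusivity with MK = 0.8,
α = 0.9. If a joint IVIM solution comes out with d_p < d_t the compartments
are swapped (the biexponential is symmetric under f → 1−f), preserving the
type invariant exactly.

Pre-smoothing is an isotropic in-plane Gaussian of FWHM 3 mm
(σ = FWHM/√(8 ln 2)), 2-D only because the slice thickness (2 mm) is much
larger than the in-plane voxel (0.6 mm); boundary mode "reflect"; FWHM 0 is
the identity. Signals at or below 10⁻⁶·S(0) after smoothing are clipped up
to that floor before ratios/logs; voxels with S(0) ≤ 0 are marked
unfittable. Non-converged voxels are excluded from the fit mask (and hence
from ROI statistics) rather than imputed.

## ROI analysis and tumor volume

ROI means average successfully fitted voxels only and report the
contributing count. Repeated measurements (2 observers × 2 sessions) are
averaged per observer first, then across observers — equal to the grand
mean in a balanced design, and weighting observers equally when a session
is missing. Tumor volume integrates per-slice contour areas over the slice
spacing; spacing = thickness + intersection gap (2.0 + 0.2 mm by default)
since the acquisition leaves a gap between slices.

## Histology metrics

* Gray-level SD uses the population (N) denominator — at slide scale the
  difference from N−1 is negligible, and the choice makes constructed-image
  tests exact. RGB inputs convert by 0.299/0.587/0.114 luminance weights.
* Necrotic fraction is |necrosis ∩ tumor| / |tumor|; intersecting with the
  tumor mask makes stray necrosis annotations harmless.
* Hotspot MVD: vessels are 8-connected components located by centroid; a
  square window (default 500 μm) scans every pixel offset via an integral
  image; the k (default 3) highest-count windows are chosen greedily without
  overlap, ties broken in scan order (top-left first). Fewer than k
  vessel-containing windows produces a mean over the available ones plus a
  warning. Vessel identity comes from a provided binary mask; stain
  deconvolution is out of scope.

## Statistics

* Spearman ρ on mid-ranked data; two-sided p by full permutation
  enumeration for n ≤ 9 (≤ 362,880 permutations) and the t-approximation
  otherwise. Pairs with missing values are dropped pairwise.
* Kruskal–Wallis with tie correction; the all-values-identical degenerate
  case returns (H = 0, p = 1) explicitly.
* Pairwise Mann–Whitney reported as tie-corrected normal-approximation Z
  without continuity correction (matching the Z-and-adjusted-p reporting
  style of treatment studies); an exact enumeration p is available behind a
  flag for small samples. Bonferroni multiplier = number of pairs actually
  tested (6 for four groups), capped at 1.
* ICC defaults to the two-way random-effects absolute-agreement
  single-measure form ICC(2,1) (pingouin's ICC(A,1)), with ICC(3,1)
  selectable, because intra- and inter-observer designs differ in whether
  raters are a random effect; F-based 95% CI and p. Zero between-subject
  variance leaves the coefficient undefined and raises.
* Two-sided tests throughout, significance threshold 0.05.

## Synthetic generators

The phantom builder emulates the study acquisition: 11 b-values with
per-b excitation counts (1,1,1,1,2,2,3,3,4,4,5), Δ = 42.7 ms, δ = 29.4 ms,
voxel 0.6×0.6×2.0 mm³. Noise is Rician — |S + n₁ + i·n₂| with i.i.d.
zero-mean Gaussians — applied to the scaled signal S(0)·S_rel with
σ_b = (S(0)/SNR)·√(averages[0]/averages[b]), i.e. SNR is referenced to the
averaged b = 0 image and higher-b images benefit from their larger averaging
counts. Default region parameters centre on the study's group summaries
(control-like lesion, combination-treated-like background), e.g. lesion
f = 0.038, MK = 1.020; background f = 0.016, MK = 0.665. A composite region
generates from a two-compartment (biexponential) truth so that single-model
DKI/SEM/FROC fits exhibit MK > 0, α < 1, β < 1, mimicking real tissue
non-Gaussianity.

Synthetic histology is a two-level gray mixture whose level separation d and
mixing weight w solve w(1−w)d² = SD_target², giving realised SD within the
pixel-count quantum (≤2% for slides ≥ 64²; SD targets above 127.5 are
infeasible on 8-bit images and rejected); the necrosis mask is a contiguous
block of exactly round(NF·N) pixels; vessels are disjoint 2×2 blobs placed
on a guarded grid in uniform, clustered or random layouts.

The cohort builder draws per-subject study rows from per-group Gaussians
(defaults: the study's group sizes 5/6/5/6 and published mean ± SD for every
DWI and histology column), clipped to physical ranges. Cross-column
dependencies are injected by sharing latent z-scores
(z_target = ρ·z_source + √(1−ρ²)·ε), so the association holds cohort-wide on
top of the group structure.

What the generators deliberately do not model: anatomy, partial-volume
mixtures at region borders, motion/eddy/ghosting artifacts, spatially
correlated noise, stain variability, or vessel-shape diversity. Passing
tests therefore demonstrate correctness of the estimation and statistics
machinery under the stated noise model, not robustness to real-scanner
confounds.

## Validation problem sizes

Chosen as the package's standard verification settings: noiseless recovery
uses 100 random truths per model inside physiological ranges (IVIM
D_t ∈ [0.3, 1.2]×10⁻³, D_p ∈ [5, 20]×10⁻³, f ∈ [0.01, 0.3]; DKI
MD ∈ [0.4, 1.2]×10⁻³ with MK capped at 3/(3000·MD) to stay inside the
cumulant validity range; SEM DDC ∈ [0.3, 1.5]×10⁻³, α ∈ [0.5, 1]; FROC
D ∈ [0.2, 1.0]×10⁻³, β ∈ [0.6, 1], μ ∈ [3, 8] μm — the box-bound corners are
excluded because they are non-identifiable by construction, e.g. f → 1 or
D_p → D_t). Noise behaviour uses 200 voxels per SNR level over
SNR ∈ {10, 20, 50, 200} with a 10% Monte-Carlo allowance on adjacent-level
RMSE comparisons. The synthetic study uses 500 replicates for both the
group-effect power check (two groups of 6, affected variables separated by
3 pooled SDs, Bonferroni multiplier 6) and the correlation-sign check
(|ρ| = 0.75 injected, n = 22). All stochastic steps run under fixed seeds
(package default 20240312) and are bit-reproducible.

## Known limitations

* FROC D and μ are reported but not separately identifiable at a single
  diffusion time (see above); μ under noise tends to drift along the ridge
  and can pin at its bounds, which the fitter flags.
* Least-squares fitting of magnitude data ignores the Rician likelihood;
  at very low SNR (≲ 10) this biases diffusivities downward and kurtosis
  upward. Rician-bias-corrected fitting is out of scope.
* IVIM f is upward-skewed at low true f even with the D_p floor (median
  fitted f ≈ 0.040 for truth 0.03 at SNR 50) — an inherent property of the
  biexponential least-squares estimator, not of the implementation.
* The ROI engine assumes one shared single-slice ROI per subject across all
  maps, per the study protocol; hemorrhage-avoiding slice substitution is
  the caller's responsibility, recorded in the ROI provenance note.
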