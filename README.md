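# mbdwi

Multi-*b*-value diffusion-weighted MRI (DWI) analysis for small-animal tumor
studies: forward signal models and voxel-wise fitting for four diffusion
models, ROI statistics, quantitative histology metrics, nonparametric group
statistics, and digital phantoms with known ground truth.

## The problem

Treatment response in tumors (the motivating setting is orthotopic
hepatocellular-carcinoma xenografts imaged at 3 T) shows up in diffusion MRI
before the tumor shrinks: perfusion falls with anti-angiogenic therapy,
diffusivity rises with necrosis, and non-Gaussian decay parameters track
spatial heterogeneity. Quantifying this requires fitting several competing
decay models to the per-voxel signal S(b)/S(0) measured over a wide b-value
range (here 0–3,000 s/mm², 11 b-values), then relating ROI summaries to
histology (necrotic fraction, microvessel density, gray-level heterogeneity)
with rank-based statistics. `mbdwi` implements that whole chain as a tested
library, with synthetic generators standing in for animals so every step can
be validated against known truth.

## Models

With b in s/mm² and diffusivities in mm²/s:

* **IVIM** (intravoxel incoherent motion):
  `S(b)/S(0) = (1 − f)·exp(−b·D_t) + f·exp(−b·D_p)` — tissue diffusion D_t,
  pseudo-diffusion D_p, perfusion fraction f. Fitted on
  b ∈ {0, 50, 80, 150, 300, 500, 800}.
* **DKI** (diffusion kurtosis):
  `S(b)/S(0) = exp(−b·MD + (1/6)·b²·MD²·MK)` — valid for b ≤ 3/(MD·MK).
* **SEM** (stretched exponential):
  `S(b)/S(0) = exp(−(b·DDC)^α)` — heterogeneity index α ∈ (0, 1].
  DKI and SEM are fitted on b ∈ {0, 500, 800, 1000, 1500, 2000, 3000}.
* **FROC** (fractional-order calculus):
  `S(b)/S(0) = exp(−D·μ^{2(β−1)}·(γ·G_d·δ)^{2β}·(Δ − ((2β−1)/(2β+1))·δ))`
  fitted on all 11 b-values; the gradient amplitude G_d is recovered from b
  through the Stejskal–Tanner relation `b = (γ·G_d·δ)²·(Δ − δ/3)` with
  Δ = 42.7 ms, δ = 29.4 ms.

  *Identifiability caveat*: at a single (δ, Δ) the decay determines only β
  and the composite `D·μ^{2(β−1)}`; fitted D and μ are a conventional
  decomposition of that composite, flagged as such by the fitter
  (`FrocFit.mu_identifiable`). See `docs/methods.md`.

Fitting is bounded trust-region least squares (the box-bounded
Levenberg–Marquardt family) with model-specific deterministic
initialisation, after in-plane Gaussian pre-smoothing (FWHM 3 mm).

The statistics layer provides Spearman correlations with the graded |r|
interpretation (poor-to-no / fair / moderate / good / excellent),
Kruskal–Wallis omnibus tests, Bonferroni-adjusted pairwise Mann–Whitney Z
tests, and ICC(2,1)/ICC(3,1) observer-agreement coefficients.

## Worked example

```python
import numpy as np
from mbdwi import (PhantomSpec, make_phantom, fit_volume, RoiMask, roi_mean,
                   CohortSpec, make_cohort, analyze_study)

# Digital phantom: control-like lesion in treated-like background, SNR 50
spec = PhantomSpec(model="dki", shape=(24, 24, 3), snr=50, seed=7)
vol, truth = make_phantom(spec)
maps = {m.name: m for m in fit_volume(vol, "dki", fwhm=3.0)}
lesion = np.isclose(truth["MK"].values[:, :, 1], 1.020)
roi = RoiMask(slice_index=1, mask=lesion, provenance="lesion truth mask")
md, n = roi_mean(maps["MD"], roi)
mk, _ = roi_mean(maps["MK"], roi)
print(f"lesion ROI ({n} voxels): MD = {md:.3f} x10-3 mm2/s (truth 0.505), "
      f"MK = {mk:.3f} (truth 1.020)")

# Synthetic 22-subject study with an injected MK–heterogeneity dependency
table = make_cohort(CohortSpec(seed=7, dependencies=(("SD", "MK", 0.8),)))
report = analyze_study(table)
row = report.correlations.query("parameter == 'MK' and target == 'SD'").iloc[0]
print(f"MK vs histology SD: r = {row['r']:.3f}, p = {row['p']:.2g} ({row['grade']})")
pw = report.pairwise.query("variable == 'MK' and pair == '(BS)-(C)'").iloc[0]
print(f"MK, BS vs C: Z = {pw['Z']:.3f}, adjusted p = {pw['p_adjusted']:.4f}")
```

prints

```
lesion ROI (144 voxels): MD = 0.550 x10-3 mm2/s (truth 0.505), MK = 0.936 (truth 1.020)
MK vs histology SD: r = 0.888, p = 3.4e-08 (excellent relationship)
MK, BS vs C: Z = -2.739, adjusted p = 0.0370
```

The lesion ROI means sit near the generating truth — the residual offset is
the partial-volume effect of the 3-mm pre-smoothing kernel mixing lesion and
background, exactly as it would on real maps. The injected rank dependency
between mean kurtosis and histological gray-level SD is recovered with the
correct sign, and the combination-treated vs control contrast in MK survives
Bonferroni adjustment over the six group pairs.

A CLI mirrors the library: `mbdwi fit`, `mbdwi histo`, `mbdwi stats`,
`mbdwi simulate {dwi,cohort,histo}` (see `--help`).

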