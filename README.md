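# strokeperf

DSC-MR perfusion analysis for acute ischemic stroke, aimed at researchers who
need a transparent, fully scriptable alternative to black-box clinical
perfusion platforms: it turns a 4-D dynamic susceptibility contrast (DSC)
series into CBF/CBV/MTT/Tmax maps, segments the ischemic core and penumbra,
computes the perfusion–diffusion mismatch, classifies late-window
thrombectomy eligibility under the DAWN and DEFUSE-3 imaging criteria, and
provides the agreement statistics (Lin's CCC, Bland–Altman, Cohen's kappa)
used to compare two such platforms head to head. A digital phantom module
generates studies and paired cohorts with known ground truth, so every stage
is testable end to end.

## The model

Bolus tracking measures the gradient-echo signal drop during the first pass
of a gadolinium bolus. Signal is converted to relative contrast
concentration via

    C(t) = -(1/TE) · ln(S(t)/S0),

with S0 the pre-bolus baseline. Tissue concentration obeys the indicator
dilution relation

    C(t) = CBF · (Ca ⊛ R)(t),

where Ca is the arterial input function (selected automatically as the
top-scoring early/tall/narrow voxel curves, gamma-variate filtered) and
R(t) the residue function. Embedding Ca in a block-circulant matrix D and
truncating small singular values (cSVD) gives the delay-insensitive
deconvolution k = D⁺C with k(t) = CBF·R(t − delay); then

* CBF = maxₜ k(t) (relative units),
* Tmax = TR · argmaxₜ k(t) (seconds, on the TR grid),
* CBV = ∫C dt / ∫Ca dt, MTT = CBV/CBF (central volume principle).

Lesions follow the operational trial thresholds: hypoperfusion is
Tmax > 6 s, ischemic core is ADC < 620×10⁻⁶ mm²/s, mismatch volume is
hypoperfused − core (mL) and the mismatch ratio their quotient. DAWN
eligibility applies per-stratum core cutoffs (21/31/51 mL over the
age/NIHSS strata); DEFUSE-3 requires core < 70 mL, ratio ≥ 1.8 and
mismatch ≥ 15 mL. Platform agreement uses Lin's concordance correlation
ρc = 2s₁₂/(s₁² + s₂² + (μ₁−μ₂)²), Bland–Altman limits bias ± 1.96 SD, and
Cohen's κ = (p₀−pₑ)/(1−pₑ) on 2×2 eligibility tables.

## Worked example

```python
from strokeperf import DscPerfusion, PatientProfile, OcclusionSite
from strokeperf.phantom import default_spec, make_study

study, truth = make_study(default_spec(seed=0, noise_sd=1.0))
study.patient = PatientProfile(70, 15, OcclusionSite.ANTERIOR_LVO)
results = DscPerfusion(study).fit()
print(results.summary())
```

prints

```
DSC perfusion analysis summary
  grid: (64, 64, 10, 60) @ (3.4, 3.4, 5.0) mm, TR 1.5 s
  brain voxels: 14403; vessel-excluded: 145
  bolus arrival frame: 8
  ischemic core:           6.4 mL
  hypoperfused (Tmax>6s):     36.3 mL
  mismatch volume:        29.9 mL  (ratio 5.66)
  DAWN: eligible
  DEFUSE3: eligible
```

The phantom's planted lesion is 36.3 mL of delayed tissue (arrival delay
9 s, so Tmax lands above the 6 s threshold) containing a 5.8 mL
low-diffusivity core; the pipeline recovers both within the noise-driven
mask uncertainty, and with a 70-year-old NIHSS-15 anterior-LVO profile the
small core and large mismatch satisfy both trial rules.
`results.save(outdir)` writes the maps and masks as NIfTI plus a summary
JSON. The same run is available from the shell:

```bash
strokeperf analyze --series study.nii.gz --adc adc.nii.gz \
    --age 70 --nihss 15 --site anterior_lvo --out out/
```

Agreement statistics work on paired per-patient tables or raw 2×2 counts:

```bash
strokeperf agree --cells 88,2,4,29 --out out/
# kappa = 0.873 (95% CI 0.775 to 0.972); agreement 95.1% (excellent)
```

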