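# Methods

## Signal model and concentration conversion

The pipeline assumes a gradient-echo DSC acquisition in which the gadolinium
first pass induces a transverse relaxation change proportional to local
contrast concentration, so that S(t) = S0·exp(−TE·C(t)) in relative
concentration units. The proportionality constant between ΔR2* and true
gadolinium concentration is set to 1: all flow and volume outputs are
therefore *relative*, which is sufficient because the clinical thresholds
this package implements (Tmax, ADC, volumes in mL) do not depend on absolute
calibration, and absolute CBF quantification from DSC is not attempted.

Bolus arrival is detected on the whole-brain mean signal: a trailing
3-frame moving average is compared against baseline mean − 2·SD, with the
baseline statistics taken from the first 8 frames (both parameters
configurable). The S0 baseline is the mean over frames before the detected
arrival. Voxels whose baseline is non-positive or below 5% of the in-brain
median S0 are excluded from conversion — these are mask-edge voxels with no
usable signal whose log-ratio curves would otherwise be huge noise spikes
(and, before this guard existed, could hijack AIF selection); more than 10%
of the brain being unusable aborts the run as a masking/acquisition error.

## Preprocessing

Motion is modelled as a per-frame 3-D translation estimated by phase
cross-correlation against the temporal mean (sub-voxel, upsampling factor
10) and corrected by trilinear resampling. Estimated shifts below 0.1 voxel
are not resampled, which makes correction exactly idempotent on static
series; shifts beyond a quarter of the field of view are flagged as
registration divergence and left uncorrected rather than applied. Rotational
motion is not modelled: at the matrix sizes this pipeline processes
(≤ 128² in-plane, ~10 slices) a rotation large enough to matter also
produces a large translation component, and the per-study maximum
displacement is reported so callers can apply their own exclusion rule.

Brain extraction is deliberately simple and deterministic: Otsu threshold
on the temporal mean, morphological closing with a 3-voxel ball (computed on
a zero-padded array so the operator stays extensive at volume borders),
largest connected component, hole filling. A uniform nonzero image yields
the full grid; an all-zero image is an error.

Vessel voxels — which carry disproportionate intravascular contrast and
would otherwise inflate lesion statistics — are those strictly above the
99th percentile of the CBV map within the brain; ties at the quantile are
not flagged, so a constant map yields an empty vessel mask.

## AIF selection and gamma-variate filtering

Arterial voxels show the earliest, tallest, narrowest concentration curves.
Each candidate brain voxel is scored

    score = peak / (FWHM_frames × arrival_rank)

where FWHM is measured by linear interpolation at half peak and the arrival
rank is the ordinal of the first half-peak crossing. The mean curve of the
top 10 voxels is the AIF; a gamma-variate A·(t−t0)^α·exp(−(t−t0)/β) is
fitted by least squares on frames up to the first post-peak local minimum
(the recirculation cutoff) and used for deconvolution when the fit
converges (fitted peak within 20% of observed), otherwise the raw mean
curve is used. A venous output function (largest-area, latest-arriving
curves) is selected for QC reporting only; no partial-volume rescaling of
the AIF by the VOF is performed. The scoring function is a documented
heuristic — commercial platforms do not publish theirs — and its selection
quality is verified against phantoms with designated arterial voxels.

## Deconvolution

The AIF is zero-padded to twice the time dimension and embedded in a
circulant matrix D[i,j] = TR·a[(i−j) mod L]. The residue field is
k = D⁺C with the pseudo-inverse truncated at singular values below 10% of
the largest (configurable within (0, 0.5)). The circulant (block-circulant
over the time axis) embedding makes the estimate insensitive to tracer
arrival delay: delayed tissue shifts k along the lag axis without changing
its maximum, which is what makes Tmax = TR·argmax k a meaningful delay
surrogate. Tmax is reported on the TR grid without sub-frame interpolation,
ties broken by the earliest frame; lags in the wrap-around half of the
circulant axis (negative delays) are clamped to zero and counted in the
diagnostics. CBV is deconvolution-free (ratio of trapezoidal areas) and
MTT = CBV/CBF where CBF exceeds 10⁻⁶ of its in-brain maximum.

Two numerical properties are worth stating plainly. First, truncated cSVD
systematically underestimates CBF when MTT is short relative to TR (the
sharp residue edge lives in the truncated part of the spectrum): at
MTT = 4 s, TR = 1.5 s and the default threshold the recovered maximum is
~78% of truth, rising to ~93% at MTT = 10 s. Rank order across tissues is
preserved, which is what the Tmax/volumetric thresholds rely on. Second,
the same truncation smearing shifts the argmax systematically by one frame
on noiseless phantoms, so Tmax estimates sit at the upper edge of the ±TR
band; both effects are deterministic and covered by tests. An adaptive
oscillation-index threshold (oSVD) would reduce the CBF bias and is a noted
extension, not implemented in v1.

## Lesion segmentation and volumetrics

Strict inequalities at both thresholds: hypoperfusion is Tmax **>** 6 s,
core is ADC **<** 620×10⁻⁶ mm²/s, both restricted to brain minus vessels.
ADC maps in the wrong unit scale (e.g. 620 instead of 620×10⁻⁶) are caught
by a plausibility guard (more than 10% of brain outside [0, 4×10⁻³] mm²/s
is an error). An externally produced core mask can be substituted for the
ADC rule, so a learned diffusion segmenter can be slotted in. Mismatch is
volume arithmetic (hypoperfused − core, clipped at zero), not a voxelwise
set difference — this matches how the trial criteria are operationalized
and is robust to imperfect co-registration. When the core is empty but
hypoperfusion exists the mismatch ratio is +∞ (maximally favourable); when
both are empty the study is flagged "no lesion" and the ratio reported
as 0. No minimum-cluster despeckling is applied by default. ADC maps on a
different grid are resampled through the affines (trilinear) with an
optional phase-correlation translation refinement; same-grid inputs pass
through bitwise-identical.

## Eligibility classification

Population gates are purely clinical: NIHSS ≥ 10 plus anterior-circulation
LVO for DAWN, NIHSS ≥ 6 plus anterior LVO for DEFUSE-3; patients failing a
gate are excluded from contingency tables. DAWN strata follow the age/NIHSS
partition (>80 & ≥10; ≤80 & 10–19; ≤80 & ≥20) with core cutoffs 21/31/51 mL
applied with strict '<' (mirroring DEFUSE-3's "core < 70 mL" phrasing);
the third stratum uses the 51 mL bound across all cores. Time-window
clocks, pre-stroke mRS and other non-imaging criteria are out of scope.
All cutoffs are exposed in `RunConfig`.

## Agreement statistics

Lin's CCC uses 1/n moment estimators (so perfect agreement is exactly 1)
with a Fisher-z confidence interval using Lin's asymptotic variance.
Bland–Altman limits use the n−1 SD and a 1.96 multiplier; the difference
direction is platform1 − platform2 with the order carried explicitly in
every report. Cohen's kappa uses the Fleiss–Cohen–Everitt asymptotic SE
with the CI truncated to [−1, 1]; for small tables (n ≲ 10 per stratum)
asymptotic intervals are known to be rough and an exact or bootstrap CI
would differ noticeably, so only the point estimate should be compared at
that scale. The qualitative magnitude scale (poor/fair/moderate/
substantial/excellent at 0.20/0.40/0.60/0.80) buckets values after
rounding to 2 decimals, since the printed band edges leave gaps such as
(0.20, 0.21) unassigned; negative coefficients are labelled poor.

## The phantom generators

`make_study` renders gamma-variate arterial kinetics (defaults: onset 10 s,
α = 3, β = 1.5 s, peak ≈ 5 concentration units — a first-pass FWHM of
~4.5 s) through exponential residues R(t) = exp(−t/MTT) region by region:
concentration is (CBF/100)·TR·(AIF ⊛ R) shifted by the arrival delay
(discretized to the TR grid), vessel voxels carry 3× the AIF, and signal is
s0·exp(−TE·C) plus seeded Gaussian noise clipped at zero. The default
acquisition (64×64×10 voxels at 3.4×3.4×5 mm, 60 frames, TR 1.5 s,
TE 40 ms, s0 = 100, noise SD 1) sits inside routine stroke DSC protocol
ranges. Gaussian rather than Rician noise is used: at bolus-tracking SNR
(~100 on the baseline) the difference is negligible outside the
near-zero-signal arterial trough. The phantom is piecewise-homogeneous
ellipsoids — it has no partial-volume gradients, susceptibility artifacts,
recirculation, or leakage, so passing tests demonstrate correctness of the
numerics, not robustness to every pathology of real acquisitions.

`make_paired_cohort` emulates two platforms measuring the same true
volumes: true core and penumbra are log-normal (positive, right-skewed, as
stroke lesion volumes are; defaults ln-mean 2.5/ln-SD 1.1 for core giving a
~12 mL median), and each platform observes truth times its own log-normal
multiplicative error. Multiplicative rather than additive-truncated error
was chosen because it keeps volumes positive by construction and admits a
closed-form concordance, CCC = (exp(s_v²)−1)/(exp(s_v²+s_e²)−1), used to
calibrate the error SD to a target CCC exactly. The mismatch-volume
agreement is *emergent* from the core and hypoperfusion error models, not
calibrated. `make_eligibility_cohort` is a target-table mode: it draws
profiles and volumes on the correct side of each criterion so the paired
verdicts realize an exact 2×2 table, with DEFUSE-3 ineligibility rotating
through the three failure modes (large core, small mismatch volume, low
ratio).

## Problem sizes and determinism

The test suite and the acceptance script run noiseless 64×64×10×60
phantoms (the package's standard phantom size), 200-replicate cohort
simulations at n = 299, and the printed 2×2 tables directly; all random
draws flow through numpy Generators seeded from explicit arguments, and the
imaging pipeline itself is deterministic (no stochastic optimization), so
repeated runs are byte-identical. Spearman rank recovery of CBF is
evaluated on a graded five-level flow phantom; with only two flow levels,
tie-corrected rank correlation is bounded at √3/2 ≈ 0.87 regardless of
estimator quality, so a two-level phantom is instead checked for perfect
group separation.

## Known limitations

No leakage (pre-bolus/Boxerman) or T1 correction; no dispersion modelling
of the AIF; fixed-threshold cSVD only; translation-only motion model;
relative (uncalibrated) CBF/CBV; asymptotic CIs only for kappa and CCC;
the diffusion core uses the ADC threshold rule rather than a learned
segmenter (the module accepts an external core mask for that purpose).
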