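# Methods

This note documents the models behind `petmbf`, the parameter choices that
matter, what the synthetic data do and do not emulate, and the numerical
conventions a user should know before trusting or extending the results.

## Kinetic model

Myocardial [¹³N]NH₃ uptake is modelled as a one-tissue compartment with a
single blood-pool spillover term:

    C_m(t) = (1 − v) · K₁ · ∫₀ᵗ C_a(u) e^(−k₂ (t−u)) du + v · C_a(t)

* `K₁` — uptake rate, identified with MBF (mL/g/min). No extraction-fraction
  or metabolite correction is applied; this is a declared simplification, so
  absolute values should be read as "model MBF".
* `k₂` — washout (1/min); defaults 0.20 at rest, 0.40 at stress.
* `v` — spillover fraction in [0, 1]; defaults 0.30 rest / 0.35 stress.

All kinetics are defined on decay-corrected concentrations. Physical decay
(half-life 9.97 min) is applied when painting count data and removed by
`decay_correct` before fitting.

The convolution is evaluated with the exact piecewise-linear closed form on
each segment (stable as k₂ → 0); a stiff ODE integration serves as the
independent oracle in the tests (agreement ≤ 1e-4 relative).

## Input function

No analytic IDIF form is standard for this protocol, so the generator uses a
gamma-variate bolus `A (t−t₀)^α e^(−(t−t₀)/β)` with α = 2, β = 6 s,
normalised so the bolus peak equals the configured dose scale, plus a
recirculation tail at 5 % of the peak ramped on with the bolus timescale and
decaying with τ = 180 s. The default dose scale (500 counts · voxel⁻¹ · s⁻¹
at the blood-pool peak) puts per-second heart counts in a range where the
0.85-NCC tracking threshold separates the tissue phase from the blood-pool
phase the way the motion-correction literature describes.

## Acquisition timing

Rest: 600 s reconstructed, injection at 10 s, 25 frames
(1×10, 12×5, 2×10, 7×30, 2×60, 1×180 s). Stress: 630 s, 26 frames — the rest
schedule behind an extra leading 30 s frame acquired before the stress
injection. The stress injection is therefore placed at 40 s: after the
leading 1×10 frame, so the 5 s frames cover the bolus exactly as at rest.
The clinical acquisition is nominally 12 + 12 min; the pipeline simulates
only the reconstruction windows, which is all the quantification sees.

## Residual activity

Tracer from the rest injection still present at stress start is modelled per
compartment as `residual_fraction` (default 0.15; the protocol literature
gives no magnitude) times the compartment's decay-corrected rest end-of-scan
concentration, decaying physically thereafter. On decay-corrected stress
curves this is an additive constant — exactly the component the
pre-injection-frame subtraction removes, which makes the correction's
round-trip property testable to numerical precision.

## Phantom and cohort

Half-ellipsoidal LV shell (outer semi-axes 26/26/36 mm, 9 mm wall) with the
cavity as blood pool, three 120° angular-sector territories (LAD/Cx/RCA) and
an ellipsoidal liver surrogate as background, on a 64³ grid of 2 mm
isotropic voxels — fine enough that the 3 mm motion-intensity bins are
meaningful, small enough for desk-scale runs.

Cohort kinetics are log-normal with marginal moments matching a normal
resting cohort (global rest MBF 1.02 ± 0.25, stress 2.65 ± 0.46 mL/g/min).
Rest and stress flows are drawn with correlation 0.7: within-patient flow
correlation is physiological, and it also keeps the CFR ≥ 2.0 inclusion
criterion (enforced by bounded redraws) from truncating the rest-flow mean,
so the post-selection cohort mean still matches the configured 1.02.
Territory-level variation adds a 5 % log-normal CV. One master seed derives
per-patient and per-phase streams by fixed offsets, so any patient
regenerates independently of cohort size.

## Motion model

Per-second rigid translation only (the correction under study addresses
rigid heart motion; contraction and non-rigid deformation are out of scope).
Profiles: `none`, `respiratory` (sinusoid), `creep` (deterministic linear
drift; displacement is accumulated-by-end-of-second, so 0.02 mm/s over the
600 s rest span ends at exactly 12 mm), and `mixed` — randomised creep +
respiration + an occasional abrupt shift. The mixed profile is calibrated so
that the fraction of stress seconds with |dz| ≥ 3 mm averages ≈ 27 %
(≈ 21 % at rest), matching the published per-phase motion prevalence the
generator targets, with ≥ 85 % of the mean displacement budget on the Z axis
and X/Y excursions well below 6 mm. Rendering applies motion by whole-voxel
rounding (2 mm quantisation) to the heart masks only; the background stays
put. Sub-voxel interpolation was deliberately avoided: it would smear
Poisson counts and the correction under study operates at discrete
resolution anyway.

## DDMC tracker

One DVH per second; REF default 9³ voxels (18 mm cube, below the ~3 cm
localisation precision of such histo-images) selected as the maximal-count
box in the averaged late window (tie-break: first box in C order); SER
default ±8 voxels per axis. The NCC score map is computed exactly
(cross-correlation numerator, integral-image window sums) and searched
exhaustively; ties break to the smallest displacement norm, then
lexicographic (z, y, x). Acceptance threshold 0.85. Untracked seconds are
re-attempted against up to two fallback REFs cut from high-count tracked
seconds near the untracked block. Because the image changes second to second
during bolus inflow, a fallback REF can match *confidently* at a spurious
offset (the cavity filling along z mimics a shift), so fallback-accepted
estimates that disagree by more than one voxel with the interpolation of the
primary-tracked trace are demoted to untracked — one of the safeguards any
per-second tracker needs in the blood-pool phase. Still-untracked seconds
keep their best estimate, stay flagged, and inherit the nearest tracked
estimate for correction. Correction applies −dz per second in whole voxels (Z only, per
the method's design); counts shifted off-grid are dropped and reported. The
estimate is anchored to the REF position, so reported displacements are
relative to the heart's location in the late stable window — the same
convention the prevalence tables inherit.

A fused `correct_z_and_bin` path sums seconds sharing a Z estimate before
shifting; it is algebraically identical to correct-then-bin (tested) and
what the study pipeline uses for speed.

## Sampling variants and ISMC

The three variants are structural emulations that differ only in sampling
geometry, never in vendor numerics:

| variant | contours from | tissue locus | blood ROI | per-frame reseg |
|---|---|---|---|---|
| fixed-boundary | all-frame sum | full wall | full cavity | no |
| mid-wall | all-frame sum | mid-wall band (±1 vox) | cavity eroded 1 | no |
| late-frame-surface | late-frame sum | mid-wall band (±1.5 vox) | cavity eroded 2 | tissue-phase frames |

Contour placement is rigid: the phantom's mask set is translated onto the
chosen summed image at the NCC-optimal integer offset (±8 voxels). With
purely rigid simulated motion, vendor segmentation error reduces to a
placement offset, which is exactly what the variants disagree about under
motion. The distinct blood-ROI erosions and band widths keep the variants
statistically distinguishable even on motion-free data (different voxel
subsets, partially independent noise) — mirroring how real packages retain
systematic differences on identical images.

ISMC is emulated as frame-by-frame rigid registration (whole voxels, three
axes, ±4 voxels) of each frame against a heart-window crop of the late
summed reference, with NCC computed on smoothed gradient-magnitude images.
The gradient channel is what makes a single reference usable across the
blood-pool/tissue contrast inversion — the same property image-based
normalised-gradient-field corrections exploit. For the late-frame-surface
variant, frames before the tissue phase are excluded (the
backward-propagating correction that stops at the blood-pool phase). ISMC's
inherent limitation relative to DDMC is intra-frame motion: a 180 s frame
with several millimetres of creep inside it cannot be fixed by one shift.

## Fitting

Weighted least squares with weights ∝ frame duration × decay factor, bounds
K₁ ∈ [0, 6], k₂ ∈ [0, 3], v ∈ [0, 1], and a fixed 5-point multi-start grid in
(K₁, k₂). The model is averaged over each frame window, and the input
function is reconstructed from its frame averages by monotone (PCHIP)
interpolation of the cumulative integral — preserving every frame integral
while giving a smooth bolus. (Naive linear interpolation of frame-midpoint
values leaks bolus activity into the pre-injection window and biases K₁ by
several percent.) At v → 1 the uptake term vanishes and K₁ is unidentified;
cost ties resolve to the smallest K₁, so pure blood-pool input degenerates
to (K₁ → 0, v → 1) rather than an arbitrary ridge point.

"Global" MBF is the voxel-count-weighted mean of territory MBF; global CFR
is the ratio of global stress to global rest MBF. CFR is undefined (flagged)
where rest MBF is zero.

## Agreement statistics

ICC(A,1) — two-way model, absolute agreement, single measurement — from the
ANOVA decomposition with the McGraw–Wong F-based 95 % CI; categories closed
on the right (≤ 0.50 poor, ≤ 0.75 moderate, ≤ 0.90 good, else excellent),
resolving the ambiguity the printed band edges leave at 0.50 and between
0.75/0.76 etc. Bland-Altman uses the fixed 1.96 multiplier for the limits of
agreement, a t-based bias CI, and the classic se(LoA) = sd·√(3/n)
approximation with t(n−1); MDC = LoA range / 2 = 1.96·sd of the differences.
Normality is Shapiro-Wilk on the differences; homoscedasticity is a slope
test of |difference| on the pair means. Zero between-subject variance and
constant differences are flagged degenerate rather than reported as numbers.

## Study design and problem sizes

The study pipeline crosses three MC arms with the three variants over a
cohort, then computes the full ICC/BA/MDC grids for each variant pair ×
{rest-MBF, stress-MBF, CFR} × {LAD, Cx, RCA, Global} × MC mode. The default
cohort is 36 (the emulated study's size); the shipped study runs and the
acceptance script use 20 patients, which the agreement grids resolve well
while keeping a full run in the minutes range on one CPU. Per-second motion
tracking on a 630 s scan takes a few seconds; one full patient
(two phases × three arms × three variants) runs in roughly ten seconds.

## What passing tests do and do not show

The generator reproduces the statistical structure the method analysis needs
— kinetic shapes, count statistics, per-second rigid Z-dominant motion,
residual stress contamination, between-variant sampling differences — but
not scanner physics: no attenuation, scatter, randoms, PSF/TOF
reconstruction, cardiac contraction or respiratory-gated structure. Passing
the directional criteria therefore shows that the *pipeline logic* (tracking,
correction, sampling, fitting, statistics) behaves as the clinical study
describes under controlled conditions; it does not validate absolute
clinical MBF accuracy. Known limitations worth keeping in mind:

* Whole-voxel (2 mm) correction quantisation leaves half-voxel ambiguities
  that can bias a single patient's MBF by several percent when the bolus
  phase straddles a rounding boundary; the effect is common to all variants
  and largely cancels in between-method differences.
* DDMC slightly *widens* rest-phase agreement spreads here (small true
  motion, so tracking jitter outweighs its benefit) — consistent with the
  near-negligible rest-phase MC effects the clinical analysis reports.
* The ISMC emulation is idealised (exhaustive search against a clean
  reference); real in-software tools differ per vendor and can behave worse.
* Printed bin percentages in the transcribed motion table are cohort
  averages of per-patient percentages, so re-deriving them from the averaged
  seconds reproduces them only to ~0.5 percentage points; the verification
  module checks them at that tolerance and the three headline percentages
  (78.8, 92.1, 72.6) exactly.
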