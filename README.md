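# petmbf

Synthetic dynamic cardiac PET pipeline for studying how rigid heart motion —
and the tools that correct it — affects the quantification of myocardial
blood flow (MBF) and coronary flow reserve (CFR), and the agreement between
different quantification methods.

## Who this is for

Researchers in quantitative nuclear cardiology who want a controlled,
ground-truth-bearing testbed for questions that clinical data cannot answer
directly: how much of the disagreement between software packages comes from
patient motion, how much a data-driven per-second motion correction (DDMC)
recovers compared with frame-level in-software correction (ISMC), and how
those effects show up in the standard agreement statistics (ICC,
Bland-Altman limits of agreement, minimal detectable change).

## What it does

The pipeline simulates a rest/stress [¹³N]NH₃ protocol end to end:

1. **Phantom & kinetics** (`petmbf.phantom`, `petmbf.kinetics`,
   `petmbf.cohort`) — a half-ellipsoidal left-ventricular shell with LAD/Cx/
   RCA territories and blood-pool cavity on a 64³ grid (2 mm voxels).
   Tracer kinetics follow a one-tissue compartment model,

   C_m(t) = (1 − v)·K₁·∫₀ᵗ C_a(u)·e^(−k₂(t−u)) du + v·C_a(t),

   with MBF ≡ K₁ (mL/g/min), washout k₂ (1/min) and blood-pool spillover
   fraction v. Cohorts are drawn with global rest MBF 1.02 ± 0.25 and stress
   MBF 2.65 ± 0.46 mL/g/min, subject to global CFR ≥ 2.0. Per-second
   histo-volumes carry physical decay (half-life 9.97 min), Poisson noise,
   rigid motion, and — in stress — residual activity from the rest injection.
2. **Motion** (`petmbf.motion`) — per-second rigid traces: respiratory
   excursion, cardiac creep, and abrupt body shifts, dominated by the
   craniocaudal (Z) axis.
3. **DDMC** (`petmbf.ddmc`) — the tracker: per-second Direct Volume
   Histograms, a heart-signature REF sub-volume from a stable late time
   point, exhaustive normalised cross-correlation (NCC) search over a
   predefined region, acceptance threshold 0.85 with fallback REFs, and
   Z-axis correction at one-second resolution.
4. **Flow quantification** (`petmbf.framing`, `petmbf.sampling`,
   `petmbf.modeling`) — the printed dynamic framing (25 frames/10 min rest,
   26 frames/10.5 min stress with a 30 s pre-injection frame), three
   software-package-style sampling variants (fixed-boundary full-wall,
   mid-wall band, late-frame-surface with per-frame re-segmentation),
   decay and residual-activity correction, frame-level ISMC registration,
   and weighted one-tissue-compartment fits.
5. **Agreement** (`petmbf.agreement`) — ICC(A,1) (two-way model, absolute
   agreement, single measurement) with F-based 95 % CI and the
   poor/moderate/good/excellent bands; Bland-Altman bias, 95 % limits of
   agreement with CIs; MDC = half the LoA range; normality and
   homoscedasticity checks.
6. **Study pipeline** (`petmbf.pipeline`, CLI `petmbf`) — cohort → three MC
   arms (NMC/ISMC/DDMC) × three variants → flow tables → ICC/BA/MDC grids
   and a motion-prevalence report.

## Worked example

```python
from petmbf.pipeline import StudyConfig, run_study

report = run_study(StudyConfig(n_patients=8, motion_profile="mixed",
                               master_seed=7))
ba = report.ba
stress = ba[ba.quantity == "stress_mbf"].pivot_table(
    index=["comparison", "region"], columns="mode", values="mdc")
print(stress.round(2).head(4))
print("cells where DDMC tightened the MDC:",
      int((stress["DDMC"] <= stress["NMC"]).sum()), "of", len(stress))
```

prints (seed 7, eight patients):

```
mode                                         DDMC  ISMC   NMC
comparison                           region
fixed-boundary vs late-frame-surface Cx      0.20  0.24  0.54
                                     Global  0.20  0.25  0.55
                                     LAD     0.21  0.28  0.56
                                     RCA     0.19  0.23  0.55
cells where DDMC tightened the MDC: 12 of 12
```

Each cell is the minimal detectable change (mL/g/min) of stress-MBF between
two sampling variants under one motion-correction mode: the smallest
between-method difference distinguishable from measurement noise. DDMC
keeping the MDC at or below the uncorrected (NMC) value in all 12
region×comparison cells is the pipeline's scaled-down replication of the
directional clinical finding that per-second motion correction improves
inter-software reproducibility of stress flow values.

The same study object carries `report.icc` (ICC grid with CIs and agreement
categories), `report.prevalence` (per-axis motion-intensity table) and
`report.flow` (per-patient values next to the simulation ground truth).

From the shell:

```bash
petmbf simulate --phase stress --profile mixed --seed 1 --out stress.nii.gz
petmbf track --series stress.nii.gz --out motion.csv --prevalence-out prev.csv
petmbf study --patients 8 --seed 7 --outdir results/
petmbf verify
```

## Scope

The pipeline is a behavioural emulation for method studies, not a scanner
simulator: no sinogram physics, attenuation, scatter or cardiac contraction,
and the three sampling variants are structural stand-ins for commercial
packages, not reimplementations. See `docs/methods.md` for the model
details, parameter choices and limitations.
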