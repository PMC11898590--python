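"""Synthetic cohort generation: acquisition configuration, ground-truth
kinetics, per-second histo-volume rendering and multi-patient sampling.

The generator emulates a rest/stress dynamic [13N]-ammonia protocol: a 600 s
rest acquisition with injection 10 s after scan start, and a 630 s stress
acquisition whose first 30 s precede the stress injection (used downstream to
quantify the residual activity left over from the rest injection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import HistoImageSeries, MotionTrace, TimeActivityCurve
from .kinetics import (NH3_HALF_LIFE_MIN, decay_factor, generate_input_function,
                       simulate_tissue_curve)
from .phantom import TERRITORIES, PhantomGeometry

# fraction of the cumulative blood-pool integral painted into the background
# compartment (slow hepatic uptake surrogate)
BACKGROUND_UPTAKE_PER_MIN = 0.25


@dataclass
class AcquisitionConfig:
    """Timing, dose and noise configuration for one acquisition phase."""

    phase: str = "rest"
    total_seconds: int = 600
    injection_time_s: float = 10.0
    stress_delay_s: float = 90.0
    isotope_half_life_min: float = NH3_HALF_LIFE_MIN
    injected_dose_scale: float = 500.0
    residual_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.phase not in ("rest", "stress"):
            raise ValueError("phase must be 'rest' or 'stress'")
        if self.total_seconds <= 0:
            raise ValueError("total_seconds must be positive")
        if self.isotope_half_life_min <= 0:
            raise ValueError("half-life must be positive")
        if self.residual_fraction < 0:
            raise ValueError("residual_fraction must be non-negative")
        if self.phase == "rest" and self.residual_fraction != 0:
            raise ValueError("rest phase carries no residual activity")


def rest_config(rng_seed: int = 0, **kw) -> AcquisitionConfig:
    defaults = dict(phase="rest", total_seconds=600, injection_time_s=10.0,
                    rng_seed=rng_seed)
    defaults.update(kw)
    return AcquisitionConfig(**defaults)


def stress_config(rng_seed: int = 0, residual_fraction: float = 0.15, **kw) -> AcquisitionConfig:
    # the stress schedule is the rest schedule behind a 30 s pre-injection
    # frame, so the injection falls at 40 s: after the leading 1x10 frame,
    # mirroring the rest phase where the bolus is covered by the 5 s frames
    defaults = dict(phase="stress", total_seconds=630, injection_time_s=40.0,
                    residual_fraction=residual_fraction, rng_seed=rng_seed)
    defaults.update(kw)
    return AcquisitionConfig(**defaults)


@dataclass
class KineticGroundTruth:
    """Per-territory true kinetic parameters for one patient."""

    K1_rest: dict[str, float]
    K1_stress: dict[str, float]
    k2_rest: dict[str, float]
    k2_stress: dict[str, float]
    spillover_rest: float
    spillover_stress: float

    def __post_init__(self) -> None:
        for d in (self.K1_rest, self.K1_stress, self.k2_rest, self.k2_stress):
            if set(d) != set(TERRITORIES):
                raise ValueError("kinetic parameters required for every territory")
            if any(v < 0 for v in d.values()):
                raise ValueError("rate constants must be non-negative")
        for v in (self.spillover_rest, self.spillover_stress):
            if not 0.0 <= v <= 1.0:
                raise ValueError("spillover fraction must lie in [0, 1]")

    @property
    def cfr_per_territory(self) -> dict[str, float]:
        return {t: self.K1_stress[t] / self.K1_rest[t] for t in TERRITORIES}

    def global_K1(self, phase: str, weights: dict[str, int] | None = None) -> float:
        vals = self.K1_rest if phase == "rest" else self.K1_stress
        if weights is None:
            return float(np.mean([vals[t] for t in TERRITORIES]))
        w = np.array([weights[t] for t in TERRITORIES], dtype=float)
        v = np.array([vals[t] for t in TERRITORIES])
        return float((w * v).sum() / w.sum())

    def global_cfr(self, weights: dict[str, int] | None = None) -> float:
        return self.global_K1("stress", weights) / self.global_K1("rest", weights)


@dataclass
class CohortVariability:
    """Population means and dispersions for ground-truth kinetics.

    Means follow a normal resting cohort: global rest MBF 1.02 +- 0.25 and
    stress MBF 2.65 +- 0.46 mL/g/min.  Patient-level values are log-normal
    with these moments; territories vary around the patient value with a small
    log-normal coefficient of variation.
    """

    K1_rest_mean: float = 1.02
    K1_rest_sd: float = 0.25
    K1_stress_mean: float = 2.65
    K1_stress_sd: float = 0.46
    k2_rest_mean: float = 0.20
    k2_stress_mean: float = 0.40
    k2_cv: float = 0.15
    territory_cv: float = 0.05
    spillover_rest_mean: float = 0.30
    spillover_stress_mean: float = 0.35
    spillover_sd: float = 0.08
    # rest/stress flows correlate within a patient; the correlation also keeps
    # the CFR >= 2 inclusion criterion from truncating the rest-flow mean
    rest_stress_corr: float = 0.7


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Draw log-normal values with the requested arithmetic mean and SD."""
    if sd <= 0:
        return np.full(size, mean) if size else mean
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def draw_ground_truth(
    rng: np.random.Generator,
    variability: CohortVariability,
    min_global_cfr: float = 2.0,
    max_retries: int = 100,
) -> KineticGroundTruth:
    """Draw one patient's kinetics, redrawing until global CFR >= 2.0."""
    def corr_lognormal_pair():
        """Correlated log-normal (rest, stress) pair with the configured
        marginal means and SDs."""
        sig2r = np.log(1 + (variability.K1_rest_sd / variability.K1_rest_mean) ** 2) \
            if variability.K1_rest_sd > 0 else 0.0
        sig2s = np.log(1 + (variability.K1_stress_sd / variability.K1_stress_mean) ** 2) \
            if variability.K1_stress_sd > 0 else 0.0
        zr, zs = rng.standard_normal(2)
        rho = variability.rest_stress_corr
        zs = rho * zr + np.sqrt(max(0.0, 1 - rho**2)) * zs
        k1r = variability.K1_rest_mean * np.exp(np.sqrt(sig2r) * zr - sig2r / 2)
        k1s = variability.K1_stress_mean * np.exp(np.sqrt(sig2s) * zs - sig2s / 2)
        return float(k1r), float(k1s)

    for _ in range(max_retries):
        k1r, k1s = corr_lognormal_pair()
        tf = {t: float(_lognormal(rng, 1.0, variability.territory_cv)) for t in TERRITORIES}
        ts = {t: float(_lognormal(rng, 1.0, variability.territory_cv)) for t in TERRITORIES}
        gt = KineticGroundTruth(
            K1_rest={t: k1r * tf[t] for t in TERRITORIES},
            K1_stress={t: k1s * ts[t] for t in TERRITORIES},
            k2_rest={t: float(_lognormal(rng, variability.k2_rest_mean,
                                         variability.k2_cv * variability.k2_rest_mean))
                     for t in TERRITORIES},
            k2_stress={t: float(_lognormal(rng, variability.k2_stress_mean,
                                           variability.k2_cv * variability.k2_stress_mean))
                       for t in TERRITORIES},
            spillover_rest=float(np.clip(
                rng.normal(variability.spillover_rest_mean, variability.spillover_sd), 0.0, 1.0)),
            spillover_stress=float(np.clip(
                rng.normal(variability.spillover_stress_mean, variability.spillover_sd), 0.0, 1.0)),
        )
        if gt.global_cfr() >= min_global_cfr:
            return gt
    raise RuntimeError(
        f"could not satisfy global CFR >= {min_global_cfr} in {max_retries} draws; "
        "check that the stress mean exceeds the rest mean"
    )


@dataclass
class Patient:
    patient_id: int
    ground_truth: KineticGroundTruth
    rest_seed: int
    stress_seed: int


def generate_cohort(
    n_patients: int,
    variability: CohortVariability | None = None,
    rng_seed: int = 0,
    min_global_cfr: float = 2.0,
) -> list[Patient]:
    """Sample a cohort of ground-truth patients.

    Per-patient parameter and per-phase rendering seeds are derived from the
    master seed by fixed offsets, so any patient can be regenerated
    independently of cohort size.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    variability = variability or CohortVariability()
    patients = []
    for i in range(n_patients):
        prng = np.random.default_rng((rng_seed * 100003 + i * 977) % (2**31 - 1))
        gt = draw_ground_truth(prng, variability, min_global_cfr=min_global_cfr)
        patients.append(Patient(
            patient_id=i,
            ground_truth=gt,
            rest_seed=(rng_seed * 100003 + i * 977 + 1) % (2**31 - 1),
            stress_seed=(rng_seed * 100003 + i * 977 + 2) % (2**31 - 1),
        ))
    return patients


def phase_curves(
    geometry: PhantomGeometry,
    gt: KineticGroundTruth,
    config: AcquisitionConfig,
) -> tuple[TimeActivityCurve, dict[str, TimeActivityCurve]]:
    """Per-second IDIF and per-territory tissue curves for one phase."""
    times = np.arange(config.total_seconds) + 0.5
    idif = generate_input_function(config, times)
    if config.phase == "rest":
        k1, k2, v = gt.K1_rest, gt.k2_rest, gt.spillover_rest
    else:
        k1, k2, v = gt.K1_stress, gt.k2_stress, gt.spillover_stress
    tissue = {t: simulate_tissue_curve(idif, k1[t], k2[t], v, label=t) for t in TERRITORIES}
    return idif, tissue


def background_curve(idif: TimeActivityCurve) -> TimeActivityCurve:
    """Slowly accumulating background (liver surrogate) concentration."""
    from .kinetics import _conv_exp_piecewise_linear
    conv = _conv_exp_piecewise_linear(idif.times, idif.values, 0.5 / 60.0)
    return idif.with_values(BACKGROUND_UPTAKE_PER_MIN / 60.0 * conv, label="background")


def residual_concentrations(
    gt: KineticGroundTruth,
    rest_cfg: AcquisitionConfig,
    stress_cfg: AcquisitionConfig,
    geometry: PhantomGeometry,
) -> dict[str, float]:
    """Decay-corrected residual concentrations at stress scan start.

    The rest tracer remaining when the stress acquisition begins is modelled
    as ``residual_fraction`` of each compartment's rest end-of-scan
    decay-corrected concentration; it then follows physical decay only, so it
    appears as an additive constant in decay-corrected stress curves.
    """
    idif, tissue = phase_curves(geometry, gt, rest_cfg)
    bg = background_curve(idif)
    f = stress_cfg.residual_fraction
    out = {"blood": f * float(idif.values[-1]), "background": f * float(bg.values[-1])}
    for t in TERRITORIES:
        out[t] = f * float(tissue[t].values[-1])
    return out


def render_histo_series(
    geometry: PhantomGeometry,
    idif: TimeActivityCurve,
    tissue_curves: dict[str, TimeActivityCurve],
    trace: MotionTrace,
    config: AcquisitionConfig,
    noise: str = "poisson",
    background: TimeActivityCurve | None = None,
    residual: dict[str, float] | None = None,
) -> HistoImageSeries:
    """Paint per-second activity into the (shifted) phantom masks.

    Each second's volume holds the compartment concentrations scaled by the
    physical decay factor, with the heart masks translated by the trace's
    whole-voxel-rounded displacement (the background stays put, emulating
    organ-independent heart motion), and optional Poisson noise.  When a
    ``residual`` map is given (stress phase), a physically decaying constant
    is added per compartment.
    """
    n = int(config.total_seconds)
    if len(trace) != n or len(idif) != n:
        raise ValueError("trace and curves must cover every acquisition second")
    for t in TERRITORIES:
        if len(tissue_curves[t]) != n:
            raise ValueError("trace and curves must cover every acquisition second")
    if noise not in ("poisson", "none"):
        raise ValueError("noise must be 'poisson' or 'none'")

    shape = geometry.grid_shape
    nvox = int(np.prod(shape))
    dec = decay_factor(idif.times, config.isotope_half_life_min)
    background = background if background is not None else background_curve(idif)
    residual = residual or {}

    # compartment -> (flat voxel indices, per-second decayed concentration)
    compartments: list[tuple[np.ndarray, np.ndarray, bool]] = []

    def conc(curve_vals: np.ndarray, key: str) -> np.ndarray:
        return (curve_vals + residual.get(key, 0.0)) * dec

    flat = lambda mask: np.flatnonzero(mask.ravel())
    # background first: a shifted heart may overlap the static background, in
    # which case the heart's counts take precedence
    compartments.append((flat(geometry.background_mask),
                         conc(background.values, "background"), False))
    compartments.append((flat(geometry.blood_pool_mask), conc(idif.values, "blood"), True))
    for t in TERRITORIES:
        compartments.append((flat(geometry.territory_mask(t)),
                             conc(tissue_curves[t].values, t), True))

    disp_vox = np.round(trace.displacement_mm() / geometry.voxel_size_mm).astype(int)
    rng = np.random.default_rng(config.rng_seed)
    series = np.zeros((n,) + shape, dtype=np.float32)
    series_flat = series.reshape(n, nvox)
    strides = np.array([shape[1] * shape[2], shape[2], 1])

    # group seconds by identical voxel shift so shifted indices are built once
    uniq, inverse = np.unique(disp_vox, axis=0, return_inverse=True)
    coords_cache = {}
    for gi, shift in enumerate(uniq):
        secs = np.flatnonzero(inverse == gi)
        for ci, (idx, values, moves) in enumerate(compartments):
            if moves and np.any(shift != 0):
                if ci not in coords_cache:
                    coords_cache[ci] = np.stack(np.unravel_index(idx, shape), axis=1)
                coords = coords_cache[ci] + shift
                inside = np.all((coords >= 0) & (coords < np.array(shape)), axis=1)
                tgt = (coords[inside] * strides).sum(axis=1)
            else:
                tgt = idx
                inside = None
            lam = values[secs][:, None] * np.ones(tgt.size)[None, :]
            if noise == "poisson":
                vals = rng.poisson(lam).astype(np.float32)
            else:
                vals = lam.astype(np.float32)
            series_flat[np.ix_(secs, tgt)] = vals
    return HistoImageSeries(volumes=series, second_index=trace.seconds.copy(),
                            voxel_size_mm=geometry.voxel_size_mm)
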