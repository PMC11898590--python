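"""Desk-scale study orchestration.

Reproduces the study design on synthetic data: cohort generation, three
motion-correction arms (NMC / ISMC / DDMC) crossed with three sampling
variants, kinetic quantification, and the agreement battery (ICC grid,
Bland-Altman grid, motion prevalence, MDC aggregation).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (PairedMeasurements, aggregate_mdc, bland_altman,
                        icc_absolute_single)
from .cohort import (Patient, generate_cohort, phase_curves, render_histo_series,
                     residual_concentrations, rest_config, stress_config)
from .containers import DynamicFrameSeries
from .ddmc import (MotionEstimate, SearchRegion, correct_z_and_bin,
                   motion_prevalence, select_ref, track)
from .framing import build_framing, bin_frames
from .kinetics import decay_correct
from .modeling import compute_flow_result, fit_1tcm
from .motion import make_motion_trace
from .phantom import TERRITORIES, PhantomGeometry, build_phantom
from .sampling import (VARIANT_NAMES, extract_tacs, ismc_frame_registration,
                       residual_activity_correction, sampling_variants)

MC_MODES = ("NMC", "ISMC", "DDMC")
REGIONS = TERRITORIES + ("Global",)
QUANTITIES = ("rest_mbf", "stress_mbf", "cfr")
TISSUE_PHASE_START_S = 150.0


@dataclass
class StudyConfig:
    n_patients: int = 20
    motion_profile: str = "mixed"
    variants: tuple[str, ...] = VARIANT_NAMES
    mc_modes: tuple[str, ...] = MC_MODES
    master_seed: int = 0
    residual_fraction: float = 0.15
    noise: str = "poisson"
    report_precision: int = 2

    def __post_init__(self) -> None:
        if not self.variants or not self.mc_modes:
            raise ValueError("at least one variant and one MC mode are required")
        if "NMC" not in self.mc_modes:
            raise ValueError("NMC must be included as the reference MC mode")
        unknown = set(self.variants) - set(VARIANT_NAMES)
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")


@dataclass
class StudyReport:
    flow: pd.DataFrame
    truth: pd.DataFrame
    prevalence: pd.DataFrame
    icc: pd.DataFrame
    ba: pd.DataFrame
    aggregation: dict
    metadata: dict = field(default_factory=dict)


def _ref_window(total_seconds: int) -> tuple[int, int]:
    return total_seconds - 100, total_seconds - 40


def _phase_frames(
    geometry: PhantomGeometry,
    patient: Patient,
    phase: str,
    config: StudyConfig,
) -> tuple[dict[str, DynamicFrameSeries], MotionEstimate | None, object]:
    """Render one phase and produce frames per requested MC arm."""
    if phase == "rest":
        cfg = rest_config(rng_seed=patient.rest_seed)
        residual = None
    else:
        cfg = stress_config(rng_seed=patient.stress_seed,
                            residual_fraction=config.residual_fraction)
        residual = residual_concentrations(
            patient.ground_truth, rest_config(rng_seed=patient.rest_seed), cfg, geometry
        ) if config.residual_fraction > 0 else None
    idif, tissue = phase_curves(geometry, patient.ground_truth, cfg)
    trace = make_motion_trace(cfg, config.motion_profile)
    series = render_histo_series(geometry, idif, tissue, trace, cfg,
                                 noise=config.noise, residual=residual)
    schedule = build_framing(phase)
    frames: dict[str, DynamicFrameSeries] = {"NMC": bin_frames(series, schedule)}
    estimate = None
    if "DDMC" in config.mc_modes:
        ref = select_ref(series, _ref_window(cfg.total_seconds),
                         uptake_start_s=TISSUE_PHASE_START_S)
        estimate = track(series, ref, SearchRegion())
        frames["DDMC"], _ = correct_z_and_bin(series, estimate,
                                              schedule.frame_starts,
                                              schedule.frame_ends)
    if "ISMC" in config.mc_modes:
        frames["ISMC"], _, _ = ismc_frame_registration(frames["NMC"])
        # the late-frame-surface package's correction propagates backward and
        # stops at the blood-pool phase, so its blood frames stay unshifted
        frames["ISMC-late"], _, _ = ismc_frame_registration(
            frames["NMC"], exclude_before_s=TISSUE_PHASE_START_S)
    return frames, estimate, cfg


def _fit_phase(frames: DynamicFrameSeries, geometry: PhantomGeometry, variant,
               phase: str, injection_time_s: float) -> dict:
    schedule = build_framing(phase)
    tacs = extract_tacs(frames, geometry, variant,
                        tissue_phase_start_s=TISSUE_PHASE_START_S)
    idif = decay_correct(tacs["idif"])
    durations = schedule.frame_ends - schedule.frame_starts
    if phase == "stress":
        idif, _ = residual_activity_correction(idif, injection_time_s)
    fits = {}
    for terr in TERRITORIES:
        tt = decay_correct(tacs["tissue"][terr])
        if phase == "stress":
            tt, _ = residual_activity_correction(tt, injection_time_s)
        fits[terr] = fit_1tcm(tt, idif, frame_durations=durations)
    return fits


def quantify_patient(
    geometry: PhantomGeometry,
    patient: Patient,
    config: StudyConfig,
) -> tuple[list[dict], dict[str, pd.DataFrame]]:
    """Full quantification of one patient: all MC arms x sampling variants."""
    weights = geometry.territory_voxel_counts()
    variants = sampling_variants()
    prevalence: dict[str, pd.DataFrame] = {}
    fits: dict[tuple[str, str, str], dict] = {}
    for phase in ("rest", "stress"):
        frames, estimate, cfg = _phase_frames(geometry, patient, phase, config)
        if estimate is not None:
            prevalence[phase] = motion_prevalence(estimate, cfg.total_seconds)
        for vname in config.variants:
            variant = variants[vname]
            for mode in config.mc_modes:
                key = "ISMC-late" if (mode == "ISMC" and variant.per_frame_reseg) \
                    else mode
                fits[(phase, vname, mode)] = _fit_phase(
                    frames[key], geometry, variant, phase, cfg.injection_time_s)
        del frames

    rows = []
    for vname in config.variants:
        for mode in config.mc_modes:
            result = compute_flow_result(fits[("rest", vname, mode)],
                                         fits[("stress", vname, mode)],
                                         weights, mc_mode=mode, variant=vname)
            for region in REGIONS:
                rows.append({
                    "patient": patient.patient_id, "variant": vname, "mode": mode,
                    "region": region,
                    "rest_mbf": result.rest_mbf[region],
                    "stress_mbf": result.stress_mbf[region],
                    "cfr": result.cfr[region],
                    "spillover_rest": result.spillover_rest,
                    "spillover_stress": result.spillover_stress,
                    "flags": result.flags.get(region, ""),
                })
    return rows, prevalence


def truth_table(patients: list[Patient], geometry: PhantomGeometry) -> pd.DataFrame:
    weights = geometry.territory_voxel_counts()
    rows = []
    for p in patients:
        gt = p.ground_truth
        for region in REGIONS:
            if region == "Global":
                rest = gt.global_K1("rest", weights)
                stress = gt.global_K1("stress", weights)
            else:
                rest, stress = gt.K1_rest[region], gt.K1_stress[region]
            rows.append({"patient": p.patient_id, "region": region,
                         "rest_mbf": rest, "stress_mbf": stress,
                         "cfr": stress / rest})
    return pd.DataFrame(rows)


def _mean_prevalence(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Cohort-average motion-prevalence grid (phase x axis rows)."""
    rows = []
    frames = pd.concat(tables, keys=range(len(tables)), names=["scan"])
    for axis in ("X", "Y", "Z"):
        sub = frames.xs(axis, level="axis")
        row = {"axis": axis}
        for col in sub.columns:
            if col == "degenerate":
                continue
            val = sub[col].mean()
            row[col] = round(float(val), 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("axis")


def agreement_tables(flow: pd.DataFrame, config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ICC and Bland-Altman grids over variant pairs x quantity x region x mode."""
    icc_rows, ba_rows = [], []
    pairs = list(itertools.combinations(config.variants, 2))
    for (va, vb), quantity, region, mode in itertools.product(
            pairs, QUANTITIES, REGIONS, config.mc_modes):
        sub = flow[(flow["region"] == region) & (flow["mode"] == mode)]
        a = sub[sub["variant"] == va].sort_values("patient")[quantity].to_numpy()
        b = sub[sub["variant"] == vb].sort_values("patient")[quantity].to_numpy()
        comparison = f"{va} vs {vb}"
        base = {"quantity": quantity, "region": region,
                "comparison": comparison, "mode": mode, "n": len(a)}
        pm = PairedMeasurements(np.arange(len(a)), a, b, label=comparison)
        if len(a) < 3:
            icc_rows.append({**base, "icc": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "category": "degenerate-n<3",
                             "degenerate": True})
            ba_rows.append({**base, "bias": float(pm.differences.mean()),
                            "sd": np.nan, "loa_range": np.nan, "mdc": np.nan})
            continue
        icc = icc_absolute_single(pm)
        icc_rows.append({**base, "icc": icc.icc, "ci_low": icc.ci_low,
                         "ci_high": icc.ci_high, "category": icc.category,
                         "degenerate": icc.degenerate})
        ba = bland_altman(pm)
        ba_rows.append({**base, "bias": ba.bias, "sd": ba.sd,
                        "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                        "loa_range": ba.loa_range, "mdc": ba.mdc,
                        "normality_ok": ba.assumptions.normality_ok,
                        "homoscedastic_ok": ba.assumptions.homoscedastic_ok})
    return pd.DataFrame(icc_rows), pd.DataFrame(ba_rows)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full synthetic study; deterministic under the master seed."""
    geometry = build_phantom()
    patients = generate_cohort(config.n_patients, rng_seed=config.master_seed)
    all_rows: list[dict] = []
    prev_tables: list[pd.DataFrame] = []
    for patient in patients:
        rows, prevalence = quantify_patient(geometry, patient, config)
        all_rows.extend(rows)
        prev_tables.extend(prevalence.values())
    flow = pd.DataFrame(all_rows)
    truth = truth_table(patients, geometry)
    icc, ba = agreement_tables(flow, config)

    aggregation = {}
    if {"ISMC", "DDMC"} & set(config.mc_modes) and len(ba) and ba["mdc"].notna().any():
        for quantity in QUANTITIES:
            sub = ba[ba["quantity"] == quantity][["comparison", "region", "mode", "mdc"]]
            if sub["mdc"].notna().all():
                aggregation[quantity] = aggregate_mdc(sub)
    prevalence = _mean_prevalence(prev_tables) if prev_tables else pd.DataFrame()

    metadata = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "n_patients": config.n_patients,
        "motion_profile": config.motion_profile,
        "variants": list(config.variants),
        "mc_modes": list(config.mc_modes),
        "noise": config.noise,
        "residual_fraction": config.residual_fraction,
        "report_precision": config.report_precision,
    }
    return StudyReport(flow=flow, truth=truth, prevalence=prevalence,
                       icc=icc, ba=ba, aggregation=aggregation, metadata=metadata)


SUMMARY_SCHEMA = {
    "required": {
        "metadata": dict,
        "mean_mdc_reduction": dict,
        "max_mdc": dict,
    }
}


def validate_summary(summary: dict) -> None:
    """Check a written summary against the shipped schema; raises on failure."""
    for key, typ in SUMMARY_SCHEMA["required"].items():
        if key not in summary:
            raise ValueError(f"summary is missing required key {key!r}")
        if not isinstance(summary[key], typ):
            raise ValueError(f"summary key {key!r} must be of type {typ.__name__}")


def render_tables(report: StudyReport, outdir, formats=("csv", "json")) -> list:
    """Write the report grids to ``outdir`` (CSV tables + JSON summary).

    Numeric cells of the agreement grids are rounded to the configured report
    precision; the flow table keeps full precision.  Returns written paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    precision = report.metadata.get("report_precision", 2)
    if "csv" in formats:
        report.flow.to_csv(outdir / "flow_results.csv", index=False)
        written.append(outdir / "flow_results.csv")
        report.truth.to_csv(outdir / "ground_truth.csv", index=False)
        written.append(outdir / "ground_truth.csv")
        if len(report.prevalence):
            report.prevalence.to_csv(outdir / "motion_prevalence.csv")
            written.append(outdir / "motion_prevalence.csv")
        icc = report.icc.copy()
        for c in ("icc", "ci_low", "ci_high"):
            if c in icc:
                icc[c] = icc[c].round(precision)
        icc.to_csv(outdir / "icc_grid.csv", index=False)
        written.append(outdir / "icc_grid.csv")
        ba = report.ba.copy()
        num = ba.select_dtypes(include=[float]).columns
        ba[num] = ba[num].round(precision)
        ba.to_csv(outdir / "ba_grid.csv", index=False)
        written.append(outdir / "ba_grid.csv")
    if "json" in formats:
        summary = {
            "metadata": report.metadata,
            "mean_mdc_reduction": {
                q: {m: round(float(v), precision)
                    for m, v in agg["mean_reduction"].items()}
                for q, agg in report.aggregation.items()
            },
            "max_mdc": {
                q: {m: round(float(v), precision) for m, v in agg["max_mdc"].items()}
                for q, agg in report.aggregation.items()
            },
        }
        validate_summary(summary)
        path = outdir / "summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(path)
    return written
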