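"""Framing, TAC extraction variants, residual-activity correction, ISMC
frame registration and kinetic fitting."""

import numpy as np
import pytest

from petmbf.cohort import (generate_cohort, phase_curves, render_histo_series,
                           residual_concentrations, rest_config, stress_config)
from petmbf.containers import TimeActivityCurve
from petmbf.framing import bin_frames, build_framing
from petmbf.kinetics import decay_correct, generate_input_function, simulate_tissue_curve
from petmbf.modeling import compute_flow_result, fit_1tcm
from petmbf.motion import make_motion_trace
from petmbf.phantom import TERRITORIES
from petmbf.sampling import (extract_tacs, ismc_frame_registration,
                             residual_activity_correction, sampling_variants)
from tests.conftest import small_series


class TestFraming:
    def test_rest_schedule(self):
        s = build_framing("rest")
        assert s.n_frames == 25
        assert s.total_seconds == 600
        assert s.total_seconds / 60.0 == 10.0
        assert s.durations_s[:3] == (10, 5, 5)
        assert s.durations_s[-1] == 180

    def test_stress_schedule(self):
        s = build_framing("stress")
        assert s.n_frames == 26
        assert s.total_seconds == 630
        assert s.total_seconds / 60.0 == 10.5
        assert s.durations_s[0] == 30  # pre-injection residual frame

    def test_frame_count_arithmetic(self):
        assert 1 + 12 + 2 + 7 + 2 + 1 == 25

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            build_framing("recovery")


class TestBinFrames:
    def test_all_ones_ten_second_frame(self):
        series = small_series(np.ones((600, 4, 4, 4), dtype=np.float32))
        frames = bin_frames(series, build_framing("rest"))
        np.testing.assert_allclose(frames.volumes[0], 10.0)

    def test_total_counts_conserved_and_matches_sum_oracle(self):
        rng = np.random.default_rng(0)
        series = small_series(rng.poisson(3.0, (630, 5, 5, 5)).astype(np.float32))
        schedule = build_framing("stress")
        frames = bin_frames(series, schedule)
        assert frames.volumes.sum() == pytest.approx(series.total_counts())
        for i, (lo, hi) in enumerate(zip(schedule.frame_starts.astype(int),
                                         schedule.frame_ends.astype(int))):
            np.testing.assert_allclose(frames.volumes[i],
                                       series.volumes[lo:hi].sum(axis=0))

    def test_span_mismatch_rejected(self):
        series = small_series(np.ones((100, 4, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="span"):
            bin_frames(series, build_framing("rest"))


@pytest.fixture(scope="module")
def motion_free_rest_frames():
    from petmbf.phantom import build_phantom

    geometry = build_phantom()
    patient = generate_cohort(1, rng_seed=8)[0]
    cfg = rest_config(rng_seed=8)
    idif, tissue = phase_curves(geometry, patient.ground_truth, cfg)
    series = render_histo_series(geometry, idif, tissue,
                                 make_motion_trace(cfg, "none"), cfg, noise="none")
    return geometry, patient, cfg, bin_frames(series, build_framing("rest"))


class TestExtractTacs:
    def test_uniform_myocardium_gives_identical_tissue_tacs(self, geometry):
        # identical constant activity everywhere in the myocardium: all three
        # sampling loci must return the same tissue TAC
        vol = np.zeros(geometry.grid_shape, dtype=np.float32)
        vol[geometry.myocardium_mask] = 7.0
        series = small_series(np.stack([vol] * 600))
        frames = bin_frames(series, build_framing("rest"))
        tacs = {name: extract_tacs(frames, geometry, v)
                for name, v in sampling_variants().items()}
        for terr in TERRITORIES:
            ref = tacs["fixed-boundary"]["tissue"][terr].values
            for name in ("mid-wall", "late-frame-surface"):
                np.testing.assert_allclose(tacs[name]["tissue"][terr].values,
                                           ref, rtol=1e-6)

    def test_midwall_excludes_hot_epicardial_rim(self, geometry):
        """On a shell with a hotter epicardial rim the mid-wall TAC must be
        lower than the full-wall TAC at every frame."""
        from scipy import ndimage

        inner_dist = ndimage.distance_transform_edt(~geometry.blood_pool_mask)
        vol = np.zeros(geometry.grid_shape, dtype=np.float32)
        myo = geometry.myocardium_mask
        vol[myo] = 5.0
        rim = myo & (inner_dist > np.median(inner_dist[myo]))
        vol[rim] = 15.0
        series = small_series(np.stack([vol] * 600))
        frames = bin_frames(series, build_framing("rest"))
        full = extract_tacs(frames, geometry, sampling_variants()["fixed-boundary"])
        mid = extract_tacs(frames, geometry, sampling_variants()["mid-wall"])
        for terr in TERRITORIES:
            assert np.all(mid["tissue"][terr].values
                          < full["tissue"][terr].values)

    def test_idif_peaks_before_tissue(self, motion_free_rest_frames):
        geometry, patient, cfg, frames = motion_free_rest_frames
        tacs = extract_tacs(frames, geometry, sampling_variants()["fixed-boundary"])
        idif_peak = tacs["idif"].times[np.argmax(tacs["idif"].values)]
        for terr in TERRITORIES:
            tt = tacs["tissue"][terr]
            assert idif_peak < tt.times[np.argmax(tt.values)]

    def test_empty_summed_image_rejected(self, geometry):
        series = small_series(np.zeros((600, 64, 64, 64), dtype=np.float32))
        frames = bin_frames(series, build_framing("rest"))
        with pytest.raises(ValueError, match="empty"):
            extract_tacs(frames, geometry, sampling_variants()["fixed-boundary"])


class TestResidualCorrection:
    def _stress_tac(self, values):
        mids = build_framing("stress").midpoints
        return TimeActivityCurve(mids, values)

    def test_zero_residual_is_identity(self):
        vals = np.concatenate([[0.0], np.linspace(1, 25, 25)])
        tac = self._stress_tac(vals)
        out, n_clamped = residual_activity_correction(tac, injection_time_s=40.0)
        np.testing.assert_array_equal(out.values, vals)
        assert n_clamped == 0

    def test_constant_curve_maps_to_zero(self):
        tac = self._stress_tac(np.full(26, 4.2))
        out, n_clamped = residual_activity_correction(tac, injection_time_s=40.0)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_missing_pre_injection_frame_rejected(self):
        tac = self._stress_tac(np.arange(26, dtype=float))
        with pytest.raises(ValueError, match="pre-injection"):
            residual_activity_correction(tac, injection_time_s=10.0)

    def test_clamping_reported(self):
        vals = np.full(26, 1.0)
        vals[5] = 0.2
        out, n_clamped = residual_activity_correction(
            self._stress_tac(vals), injection_time_s=40.0)
        assert n_clamped == 1
        assert out.values[5] == 0.0

    def test_contaminated_stress_recovers_clean_tacs(self, geometry):
        """Paired simulation with and without residual rest activity: after
        decay and residual correction the contaminated TACs match the clean
        ones within 2 % RMS."""
        patient = generate_cohort(1, rng_seed=12)[0]
        schedule = build_framing("stress")
        results = {}
        for fraction in (0.0, 0.2):
            cfg = stress_config(rng_seed=12, residual_fraction=fraction)
            idif, tissue = phase_curves(geometry, patient.ground_truth, cfg)
            residual = residual_concentrations(
                patient.ground_truth, rest_config(rng_seed=12), cfg, geometry
            ) if fraction else None
            trace = make_motion_trace(cfg, "none")
            series = render_histo_series(geometry, idif, tissue, trace, cfg,
                                         noise="none", residual=residual)
            frames = bin_frames(series, schedule)
            tacs = extract_tacs(frames, geometry,
                                sampling_variants()["fixed-boundary"])
            corrected = {}
            for key, tac in [("idif", tacs["idif"])] + list(
                    tacs["tissue"].items()):
                dc = decay_correct(tac)
                cc, _ = residual_activity_correction(
                    dc, injection_time_s=cfg.injection_time_s)
                corrected[key] = cc.values
            results[fraction] = corrected
        for key in results[0.0]:
            clean, fixed = results[0.0][key], results[0.2][key]
            rms = np.sqrt(np.mean((fixed - clean) ** 2))
            assert rms <= 0.02 * np.sqrt(np.mean(clean**2))


class TestIsmcRegistration:
    def test_motion_free_frames_unshifted(self, motion_free_rest_frames):
        geometry, patient, cfg, frames = motion_free_rest_frames
        registered, shifts, flags = ismc_frame_registration(frames)
        assert not np.any(shifts)
        np.testing.assert_array_equal(registered.volumes, frames.volumes)

    def test_displaced_frame_recovered(self, motion_free_rest_frames):
        geometry, patient, cfg, frames = motion_free_rest_frames
        vols = np.array(frames.volumes)
        # a tissue-phase frame outside the late reference window, so the
        # corruption does not leak into the registration reference
        idx = int(np.flatnonzero(frames.frame_starts == 180.0)[0])
        shifted = np.zeros_like(vols[idx])
        shifted[:, :, 3:] = vols[idx][:, :, :-3]
        vols[idx] = shifted
        from petmbf.containers import DynamicFrameSeries

        corrupted = DynamicFrameSeries(vols, frames.frame_starts,
                                       frames.frame_ends, frames.voxel_size_mm)
        registered, shifts, flags = ismc_frame_registration(corrupted)
        assert tuple(shifts[idx]) == (0, 0, 3)
        np.testing.assert_allclose(registered.volumes[idx], frames.volumes[idx])

    def test_registration_never_lowers_reference_similarity(self, geometry,
                                                            patient_one):
        """Registered frames never score lower than the input frames against
        the reference on the registration's similarity channel (gradient-
        magnitude NCC) -- the optimisation guarantee on the searched grid."""
        from petmbf.ddmc import ncc
        from petmbf.sampling import _reference_template, gradient_magnitude

        cfg = rest_config(rng_seed=patient_one.rest_seed)
        idif, tissue = phase_curves(geometry, patient_one.ground_truth, cfg)
        trace = make_motion_trace(cfg, "creep", drift_rate_mm_per_s=0.015)
        series = render_histo_series(geometry, idif, tissue, trace, cfg,
                                     noise="poisson")
        frames = bin_frames(series, build_framing("rest"))
        registered, shifts, flags = ismc_frame_registration(frames)
        reference = frames.volumes[frames.frame_starts >= 300].sum(axis=0)
        tpl, corner, _, _ = _reference_template(gradient_magnitude(reference), 4)
        sl = tuple(slice(c, c + s) for c, s in zip(corner, tpl.shape))
        assert np.any(shifts != 0)  # creep is large enough to trigger shifts
        for i in range(frames.n_frames):
            if flags[i]:
                continue
            before = ncc(tpl, gradient_magnitude(frames.volumes[i])[sl])
            after = ncc(tpl, gradient_magnitude(registered.volumes[i])[sl])
            assert after >= before - 1e-6

    def test_single_frame_rejected(self, geometry):
        from petmbf.containers import DynamicFrameSeries

        one = DynamicFrameSeries(np.ones((1, 8, 8, 8)), np.array([0.0]),
                                 np.array([10.0]), 2.0)
        with pytest.raises(ValueError, match="two frames"):
            ismc_frame_registration(one)


@pytest.fixture(scope="module")
def framed_truth():
    """Analytic frame-averaged TACs for known parameters."""
    cfg = rest_config()
    schedule = build_framing("rest")
    fine = np.arange(cfg.total_seconds) + 0.5
    idif = generate_input_function(cfg, fine)
    params = (1.02, 0.3, 0.3)
    tissue = simulate_tissue_curve(idif, *params)
    starts = schedule.frame_starts.astype(int)
    durations = schedule.frame_ends - schedule.frame_starts
    fa = lambda v: np.add.reduceat(v, starts) / durations
    mids = schedule.midpoints
    return (TimeActivityCurve(mids, fa(tissue.values)),
            TimeActivityCurve(mids, fa(idif.values)), durations, params)


class TestFit1tcm:
    def test_noiseless_recovery(self, framed_truth):
        tissue, idif, durations, (k1, k2, v) = framed_truth
        fit = fit_1tcm(tissue, idif, frame_durations=durations)
        assert fit.converged
        assert fit.K1 == pytest.approx(k1, rel=1e-2)
        assert fit.k2 == pytest.approx(k2, rel=0.05)
        assert fit.spillover == pytest.approx(v, abs=0.02)

    def test_pure_idif_degenerates_to_spillover(self, framed_truth):
        _, idif, durations, _ = framed_truth
        fit = fit_1tcm(idif, idif, frame_durations=durations)
        assert fit.spillover > 0.98
        assert fit.K1 < 0.02

    def test_too_few_frames_rejected(self):
        t = np.arange(4, dtype=float) + 1
        tac = TimeActivityCurve(t, np.ones(4))
        with pytest.raises(ValueError, match="6 frames"):
            fit_1tcm(tac, tac)


class TestMotionSensitivityOrdering:
    def test_mc_arms_beat_no_correction_under_high_creep(self, geometry):
        """On a high-creep stress phantom, the median |global MBF error| with
        either frame-level (ISMC) or per-second (DDMC) correction does not
        exceed the uncorrected error, over 20 seeded replicates."""
        from petmbf.ddmc import SearchRegion, correct_z_and_bin, select_ref, track
        from petmbf.framing import bin_frames
        from petmbf.phantom import TERRITORIES

        schedule = build_framing("stress")
        variant = sampling_variants()["fixed-boundary"]
        weights = geometry.territory_voxel_counts()
        durations = schedule.frame_ends - schedule.frame_starts
        errors = {m: [] for m in ("NMC", "ISMC", "DDMC")}
        for rep in range(20):
            patient = generate_cohort(1, rng_seed=400 + rep)[0]
            gt = patient.ground_truth
            cfg = stress_config(rng_seed=patient.stress_seed)
            idif, tissue = phase_curves(geometry, gt, cfg)
            trace = make_motion_trace(cfg, "creep", drift_rate_mm_per_s=0.018)
            residual = residual_concentrations(
                gt, rest_config(rng_seed=patient.rest_seed), cfg, geometry)
            series = render_histo_series(geometry, idif, tissue, trace, cfg,
                                         noise="poisson", residual=residual)
            frames = {"NMC": bin_frames(series, schedule)}
            ref = select_ref(series, (530, 590))
            estimate = track(series, ref, SearchRegion())
            frames["DDMC"], _ = correct_z_and_bin(
                series, estimate, schedule.frame_starts, schedule.frame_ends)
            frames["ISMC"], _, _ = ismc_frame_registration(frames["NMC"])
            truth = gt.global_K1("stress", weights)
            for mode, fr in frames.items():
                tacs = extract_tacs(fr, geometry, variant)
                idif_dc = decay_correct(tacs["idif"])
                idif_rc, _ = residual_activity_correction(
                    idif_dc, cfg.injection_time_s)
                k1 = {}
                for terr in TERRITORIES:
                    tt = decay_correct(tacs["tissue"][terr])
                    tt, _ = residual_activity_correction(tt, cfg.injection_time_s)
                    k1[terr] = fit_1tcm(tt, idif_rc,
                                        frame_durations=durations).K1
                glob = sum(k1[t] * weights[t] for t in TERRITORIES) \
                    / sum(weights.values())
                errors[mode].append(abs(glob - truth))
        med = {m: float(np.median(v)) for m, v in errors.items()}
        assert med["NMC"] >= med["ISMC"], med
        assert med["NMC"] >= med["DDMC"], med


class TestFlowResult:
    def _fits(self, k1s):
        from petmbf.modeling import KineticFit

        return {t: KineticFit(K1=k, k2=0.2, spillover=0.3, rss=0.0,
                              converged=True) for t, k in zip(TERRITORIES, k1s)}

    def test_equal_rest_stress_gives_unit_cfr(self):
        weights = {t: 100 for t in TERRITORIES}
        res = compute_flow_result(self._fits([1.0, 1.0, 1.0]),
                                  self._fits([1.0, 1.0, 1.0]), weights)
        assert all(v == 1.0 for v in res.cfr.values())

    def test_regional_cfr_ratios(self):
        weights = {t: 100 for t in TERRITORIES}
        res = compute_flow_result(self._fits([1.0, 1.0, 1.0]),
                                  self._fits([2.0, 3.0, 2.5]), weights)
        assert [res.cfr[t] for t in TERRITORIES] == [2.0, 3.0, 2.5]

    def test_global_is_weighted_mean(self):
        res_eq = compute_flow_result(self._fits([1.0, 2.0, 3.0]),
                                     self._fits([2.0, 4.0, 6.0]),
                                     {t: 50 for t in TERRITORIES})
        assert res_eq.rest_mbf["Global"] == pytest.approx(2.0)
        res_w = compute_flow_result(self._fits([1.0, 2.0, 3.0]),
                                    self._fits([2.0, 4.0, 6.0]),
                                    {"LAD": 100, "Cx": 0, "RCA": 0})
        assert res_w.rest_mbf["Global"] == pytest.approx(1.0)

    def test_zero_rest_flow_flags_undefined_cfr(self):
        res = compute_flow_result(self._fits([0.0, 1.0, 1.0]),
                                  self._fits([2.0, 2.0, 2.0]),
                                  {t: 100 for t in TERRITORIES})
        assert np.isnan(res.cfr["LAD"])
        assert res.flags["LAD"] == "cfr-undefined"
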