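"""Data-driven motion correction (DDMC).

The tracker bins acquisition data into one-second 3D histo-volumes (a "Direct
Volume Histogram" series), cuts a heart-signature sub-volume (REF) from a
stable late time point, and localises that signature in every second's volume
by exhaustive normalised cross-correlation (NCC) over a predefined search
region (SER).  Seconds whose best NCC falls below the acceptance threshold
(default 0.85) are re-attempted against fallback REFs cut from nearby
well-tracked seconds; seconds that still fail stay flagged untracked.
Correction applies only the craniocaudal (Z) component at one-second
resolution, the axis where high-intensity cardiac motion concentrates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import HistoImageSeries, MotionTrace


@dataclass
class RefSignature:
    """Heart-signature sub-volume cut from one DVH."""

    sub_volume: np.ndarray
    anchor_second: int
    anchor_offset_voxels: tuple[int, int, int]

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sub_volume) < 0):
            raise ValueError("REF counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.sub_volume.shape


@dataclass
class SearchRegion:
    """Maximum tested displacement from the REF anchor, per axis (voxels)."""

    half_extent_voxels: tuple[int, int, int] = (8, 8, 8)

    def __post_init__(self) -> None:
        if any(e < 1 for e in self.half_extent_voxels):
            raise ValueError("search extents must be at least 1 voxel")


@dataclass
class MotionEstimate:
    """Tracker output: per-second best offset, NCC score and tracked flag.

    ``ref_index`` records which signature accepted each second: 0 for the
    primary REF, 1.. for fallback REFs, -1 for finally untracked seconds.
    """

    seconds: np.ndarray
    offset_voxels: np.ndarray      # (n, 3) displacement relative to the anchor
    ncc_scores: np.ndarray
    tracked: np.ndarray
    threshold: float
    voxel_size_mm: float
    ref_index: np.ndarray | None = None

    @property
    def offset_mm(self) -> np.ndarray:
        return self.offset_voxels * self.voxel_size_mm

    def to_trace(self) -> MotionTrace:
        mm = self.offset_mm
        return MotionTrace(seconds=self.seconds, dx_mm=mm[:, 0], dy_mm=mm[:, 1],
                           dz_mm=mm[:, 2], tracked=self.tracked)

    def to_frame(self) -> pd.DataFrame:
        mm = self.offset_mm
        return pd.DataFrame({
            "second": self.seconds, "dx_mm": mm[:, 0], "dy_mm": mm[:, 1],
            "dz_mm": mm[:, 2], "ncc": self.ncc_scores, "tracked": self.tracked,
        })


def build_dvh_series(
    data,
    bin_seconds: float = 1.0,
    total_seconds: int | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    voxel_size_mm: float = 2.0,
) -> HistoImageSeries:
    """Bin input into a per-second DVH series.

    Accepts an existing :class:`HistoImageSeries` (returned unchanged), a 4-D
    array of per-second volumes, or an event list of rows
    ``(t_seconds, ix, iy, iz)`` which is histogrammed into per-second volumes.
    """
    if bin_seconds != 1.0:
        raise ValueError("DVH binning is defined at one-second resolution")
    if isinstance(data, HistoImageSeries):
        return data
    arr = np.asarray(data)
    if arr.size == 0:
        raise ValueError("empty input")
    if arr.ndim == 4:
        return HistoImageSeries(volumes=arr, second_index=np.arange(arr.shape[0]),
                                voxel_size_mm=voxel_size_mm)
    if arr.ndim == 2 and arr.shape[1] == 4:
        if grid_shape is None:
            raise ValueError("grid_shape required for event-list input")
        t = np.floor(arr[:, 0]).astype(int)
        n = int(total_seconds) if total_seconds is not None else int(t.max()) + 1
        vols = np.zeros((n,) + tuple(grid_shape), dtype=np.float32)
        idx = arr[:, 1:4].astype(int)
        np.add.at(vols, (t, idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
        return HistoImageSeries(volumes=vols, second_index=np.arange(n),
                                voxel_size_mm=voxel_size_mm)
    raise ValueError("unsupported input for DVH binning")


def _box_sums(volume: np.ndarray, box: tuple[int, int, int]) -> np.ndarray:
    """Exact sums of every box-shaped sub-volume via an integral image."""
    ii = volume.astype(np.float64)
    for ax in range(3):
        ii = np.cumsum(ii, axis=ax)
    ii = np.pad(ii, [(1, 0)] * 3)
    bx, by, bz = box
    nx, ny, nz = volume.shape
    ox, oy, oz = nx - bx + 1, ny - by + 1, nz - bz + 1

    def c(dx, dy, dz):
        return ii[dx:dx + ox, dy:dy + oy, dz:dz + oz]

    return (c(bx, by, bz) - c(0, by, bz) - c(bx, 0, bz) - c(bx, by, 0)
            + c(0, 0, bz) + c(0, by, 0) + c(bx, 0, 0) - c(0, 0, 0))


def select_ref(
    series: HistoImageSeries,
    window: tuple[int, int],
    ref_shape: tuple[int, int, int] = (9, 9, 9),
    uptake_start_s: float | None = None,
) -> RefSignature:
    """Cut the REF signature from the averaged late stable window.

    Returns the ``ref_shape`` box maximising contained counts in the mean DVH
    over ``window`` (half-open second range).  Ties break to the first box in
    C order, so a uniform volume yields the corner box.  A window overlapping
    the blood-pool period (before ``uptake_start_s``) triggers a warning, not
    an error.
    """
    lo, hi = window
    if not (0 <= lo < hi <= series.n_seconds):
        raise ValueError("window must lie within the acquisition")
    if any(r >= g for r, g in zip(ref_shape, series.grid_shape)):
        raise ValueError("REF must be strictly smaller than the DVH grid on every axis")
    if uptake_start_s is not None and lo < uptake_start_s:
        warnings.warn("REF window overlaps the blood-pool period; tracking may be "
                      "unreliable", stacklevel=2)
    mean_vol = series.volumes[lo:hi].mean(axis=0)
    sums = _box_sums(mean_vol, ref_shape)
    corner = np.unravel_index(int(np.argmax(sums)), sums.shape)
    anchor = lo + (hi - lo) // 2
    sub = series.volumes[anchor][tuple(slice(c, c + r) for c, r in zip(corner, ref_shape))]
    return RefSignature(sub_volume=np.array(sub, dtype=np.float64),
                        anchor_second=int(anchor),
                        anchor_offset_voxels=tuple(int(c) for c in corner))


def ncc(ref: np.ndarray, candidate: np.ndarray, with_flag: bool = False):
    """Normalised cross-correlation of two equally shaped arrays.

    ``sum((a - mean a)(b - mean b)) / sqrt(sum (a - mean a)^2 sum (b - mean b)^2)``,
    in [-1, 1].  A zero-variance input yields the defined score 0 (degenerate);
    pass ``with_flag=True`` to also receive the degeneracy flag.
    """
    a = np.asarray(ref, dtype=np.float64)
    b = np.asarray(candidate, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("ref and candidate must have identical shapes")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da * da).sum() * (db * db).sum())
    if denom == 0.0:
        return (0.0, True) if with_flag else 0.0
    score = float(np.clip((da * db).sum() / denom, -1.0, 1.0))
    return (score, False) if with_flag else score


def _window_sums(region: np.ndarray, box: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Box sums of the region and of its square, for every valid window."""
    return _box_sums(region, tuple(box)), _box_sums(region * region, tuple(box))


def _search_one(
    volume: np.ndarray,
    ref: np.ndarray,
    ref_norm: np.ndarray,
    ref_ss: float,
    anchor: np.ndarray,
    half_extent: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exhaustive NCC search of one volume; returns (offset_voxels, score).

    The NCC score map over all offsets in the search region is computed with
    a direct cross-correlation for the numerator and integral-image window
    sums for the denominator (algebraically identical to evaluating
    :func:`ncc` at every offset).  Tie-breaks: highest score, then smallest
    displacement norm, then lexicographic (z, y, x) order.
    """
    from scipy.signal import correlate

    shape = np.array(volume.shape)
    rs = np.array(ref.shape)
    lo = np.maximum(anchor - half_extent, 0)
    hi = np.minimum(anchor + half_extent, shape - rs)
    region = np.asarray(
        volume[tuple(slice(l, h + r) for l, h, r in zip(lo, hi, rs))], dtype=np.float64)
    n = float(rs.prod())
    num = correlate(region, ref_norm, mode="valid", method="auto")
    sums, sq = _window_sums(region, rs)
    ss = sq - sums * sums / n
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = num / np.sqrt(ss * ref_ss)
    scores = np.where((ss <= 1e-9 * sq) | (ref_ss <= 0), 0.0, scores)
    scores = np.clip(scores, -1.0, 1.0)

    best = scores.max()
    cand = np.flatnonzero(scores.ravel() >= best - 1e-12)
    pos = np.stack(np.unravel_index(cand, scores.shape), axis=1) + lo
    disp = pos - anchor
    norms = (disp * disp).sum(axis=1)
    keep = norms == norms.min()
    cand2 = cand[keep]
    disp2 = disp[keep]
    order = np.lexsort((disp2[:, 0], disp2[:, 1], disp2[:, 2]))
    pick = order[0]
    return disp2[pick], float(scores.ravel()[cand2[pick]])


def _prep_ref(ref: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean-subtracted REF kernel and its sum of squares."""
    a = np.asarray(ref, dtype=np.float64)
    norm = a - a.mean()
    return norm, float((norm * norm).sum())


def track(
    series: HistoImageSeries,
    ref: RefSignature,
    ser: SearchRegion | None = None,
    threshold: float = 0.85,
    n_fallback_refs: int = 2,
) -> MotionEstimate:
    """Localise the REF in every second's DVH by exhaustive NCC search.

    Seconds below the acceptance threshold after the primary pass are
    re-attempted with up to ``n_fallback_refs`` fallback signatures cut from
    high-count well-tracked seconds nearest (in time) to the untracked block.
    Seconds that remain below threshold keep their best-scoring estimate but
    stay flagged untracked.
    """
    ser = ser or SearchRegion()
    half = np.asarray(ser.half_extent_voxels, dtype=int)
    anchor = np.asarray(ref.anchor_offset_voxels, dtype=int)
    shape = np.array(series.grid_shape)
    rs = np.array(ref.shape)
    if np.any(anchor + rs > shape) or np.any(anchor < 0):
        raise ValueError("REF does not fit inside the DVH grid at its anchor")

    n = series.n_seconds
    offsets = np.zeros((n, 3), dtype=int)
    scores = np.full(n, -1.0)
    ref_norm, ref_ss = _prep_ref(ref.sub_volume)
    for s in range(n):
        offsets[s], scores[s] = _search_one(series.volumes[s], ref.sub_volume,
                                            ref_norm, ref_ss, anchor, half)
    tracked = scores >= threshold
    ref_index = np.where(tracked, 0, -1)

    for fb in range(n_fallback_refs):
        untracked = np.flatnonzero(~tracked)
        if untracked.size == 0 or tracked.sum() == 0:
            break
        # fallback REF: highest-count volume among the tracked seconds closest
        # in time to the centre of the untracked block
        centre = float(np.median(untracked))
        tracked_secs = np.flatnonzero(tracked)
        nearest = tracked_secs[np.argsort(np.abs(tracked_secs - centre))[:20]]
        totals = series.volumes[nearest].sum(axis=(1, 2, 3))
        s2 = int(nearest[int(np.argmax(totals))])
        base = anchor + offsets[s2]
        base = np.clip(base, 0, shape - rs)
        sub2 = np.array(series.volumes[s2][tuple(slice(b, b + r) for b, r in zip(base, rs))],
                        dtype=np.float64)
        norm2, ss2 = _prep_ref(sub2)
        if ss2 <= 0:
            continue
        for s in untracked:
            disp, sc = _search_one(series.volumes[s], sub2, norm2, ss2, base, half)
            if sc > scores[s]:
                # displacement of the heart relative to the original anchor
                offsets[s] = (base + disp) - anchor
                scores[s] = sc
                if sc >= threshold:
                    ref_index[s] = fb + 1
        tracked = tracked | (scores >= threshold)

    # blood-pool safeguard: during bolus inflow the image changes second to
    # second, and a fallback REF can match confidently at a spurious offset
    # (the cavity filling along z mimics a shift).  A fallback-accepted
    # estimate that disagrees by more than one voxel with the interpolation
    # of the primary-tracked trace is demoted to untracked; correction then
    # carries the nearest reliable estimate instead.
    primary = np.flatnonzero(ref_index == 0)
    if primary.size:
        fallback_secs = np.flatnonzero(ref_index > 0)
        if fallback_secs.size:
            interp = np.interp(fallback_secs, primary, offsets[primary, 2])
            demote = np.abs(offsets[fallback_secs, 2] - interp) > 1.0
            tracked[fallback_secs[demote]] = False
            ref_index[fallback_secs[demote]] = -1

    return MotionEstimate(seconds=series.second_index.copy(), offset_voxels=offsets,
                          ncc_scores=scores, tracked=tracked, threshold=threshold,
                          voxel_size_mm=series.voxel_size_mm, ref_index=ref_index)


def _fill_untracked_z(estimate: MotionEstimate, policy: str) -> np.ndarray:
    dz = estimate.offset_voxels[:, 2].astype(int).copy()
    untracked = ~estimate.tracked
    if not untracked.any() or policy == "raw":
        return dz
    if policy == "zero":
        dz[untracked] = 0
        return dz
    if policy != "nearest":
        raise ValueError("fill_policy must be 'nearest', 'zero' or 'raw'")
    tracked_idx = np.flatnonzero(estimate.tracked)
    if tracked_idx.size == 0:
        dz[:] = 0
        return dz
    all_idx = np.arange(dz.size)
    nearest = tracked_idx[np.argmin(np.abs(all_idx[:, None] - tracked_idx[None, :]), axis=1)]
    dz[untracked] = dz[nearest[untracked]]
    return dz


def apply_correction_z(
    series: HistoImageSeries,
    estimate: MotionEstimate,
    fill_policy: str = "nearest",
) -> tuple[HistoImageSeries, float]:
    """Undo the tracked Z displacement, second by second.

    Each second's volume is shifted by minus the estimated whole-voxel Z
    displacement; X/Y estimates are reported but never corrected.  Untracked
    seconds are filled per ``fill_policy`` (default: carry the nearest tracked
    estimate).  Counts pushed outside the grid are dropped; the dropped total
    is returned alongside the corrected series.
    """
    if len(estimate.seconds) != series.n_seconds:
        raise ValueError("estimate must cover every second of the series")
    dz = _fill_untracked_z(estimate, fill_policy)
    out = np.zeros_like(series.volumes)
    nz = series.grid_shape[2]
    dropped = 0.0
    for d_est in np.unique(dz):
        secs = np.flatnonzero(dz == d_est)
        d = int(-d_est)  # correction shift
        vols = series.volumes[secs]
        if d == 0:
            out[secs] = vols
            continue
        if abs(d) >= nz:
            dropped += float(vols.sum())
            continue
        if d > 0:
            out[secs, :, :, d:] = vols[:, :, :, :-d]
            dropped += float(vols[:, :, :, -d:].sum())
        else:
            out[secs, :, :, :d] = vols[:, :, :, -d:]
            dropped += float(vols[:, :, :, :-d].sum())
    corrected = HistoImageSeries(volumes=out, second_index=series.second_index.copy(),
                                 voxel_size_mm=series.voxel_size_mm)
    return corrected, dropped


def correct_z_and_bin(
    series: HistoImageSeries,
    estimate: MotionEstimate,
    frame_starts: np.ndarray,
    frame_ends: np.ndarray,
    fill_policy: str = "nearest",
):
    """Fused Z correction + frame binning.

    Equivalent to :func:`apply_correction_z` followed by frame summation, but
    sums the seconds sharing a Z estimate first and shifts the partial sums,
    avoiding a second full-series pass.  Returns (frame volumes, dropped
    counts).
    """
    from .containers import DynamicFrameSeries

    if len(estimate.seconds) != series.n_seconds:
        raise ValueError("estimate must cover every second of the series")
    dz = _fill_untracked_z(estimate, fill_policy)
    nz = series.grid_shape[2]
    n_frames = len(frame_starts)
    out = np.zeros((n_frames,) + series.grid_shape, dtype=series.volumes.dtype)
    dropped = 0.0
    for f in range(n_frames):
        lo, hi = int(frame_starts[f]), int(frame_ends[f])
        for d_est in np.unique(dz[lo:hi]):
            sel = np.flatnonzero(dz[lo:hi] == d_est) + lo
            part = series.volumes[sel].sum(axis=0)
            d = int(-d_est)
            if d == 0:
                out[f] += part
            elif abs(d) >= nz:
                dropped += float(part.sum())
            elif d > 0:
                out[f, :, :, d:] += part[:, :, :-d]
                dropped += float(part[:, :, -d:].sum())
            else:
                out[f, :, :, :d] += part[:, :, -d:]
                dropped += float(part[:, :, :-d].sum())
    frames = DynamicFrameSeries(volumes=out, frame_starts=np.asarray(frame_starts, float),
                                frame_ends=np.asarray(frame_ends, float),
                                voxel_size_mm=series.voxel_size_mm)
    return frames, dropped


MOTION_BINS_MM = (3.0, 6.0, 9.0)
_BIN_LABELS = ("<3 mm", "3-6 mm", "6-9 mm", ">9 mm")


def motion_prevalence(
    source: MotionEstimate | MotionTrace,
    total_seconds: int | None = None,
    bins_mm: tuple[float, float, float] = MOTION_BINS_MM,
) -> pd.DataFrame:
    """Per-axis motion-intensity prevalence table.

    For each axis: tracked seconds and tracked % of ``total_seconds``, then
    seconds and percentages per intensity bin (<3 / 3-6 / 6-9 / >9 mm by
    default), with bin percentages relative to the tracked seconds so each row
    sums to 100 within rounding.  Percentages are rounded to one decimal.  With
    zero tracked seconds the bin percentages are NaN and the row is flagged.
    """
    trace = source.to_trace() if isinstance(source, MotionEstimate) else source
    total = int(total_seconds) if total_seconds is not None else len(trace)
    edges = (0.0,) + tuple(bins_mm) + (np.inf,)
    rows = []
    for axis, disp in (("X", trace.dx_mm), ("Y", trace.dy_mm), ("Z", trace.dz_mm)):
        d = np.abs(disp[trace.tracked])
        nt = int(trace.tracked.sum())
        row = {"axis": axis, "tracked_sec": nt,
               "tracked_pct": round(100.0 * nt / total, 1),
               "degenerate": nt == 0}
        for i, lab in enumerate(_BIN_LABELS):
            cnt = int(((d >= edges[i]) & (d < edges[i + 1])).sum())
            row[f"{lab}_sec"] = cnt
            row[f"{lab}_pct"] = round(100.0 * cnt / nt, 1) if nt else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("axis")
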