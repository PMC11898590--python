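"""TAC extraction under three software-package-style sampling variants,
residual-activity correction, and frame-level in-software motion correction
(ISMC) emulation.

The three variants are structural emulations of how commercial packages
sample the dynamic data -- they differ only in contour source and sampling
locus, never in vendor numerics:

* ``fixed-boundary``: fixed LV contours placed on the summed image of *all*
  frames; full-wall sampling.
* ``mid-wall``: contours from the all-frame sum; sampling restricted to a
  mid-wall band midway between the endo- and epicardial surfaces.
* ``late-frame-surface``: contours placed on the summed *late* (tissue-phase)
  frames, mid-wall sampling, and per-frame re-placement of the contours on
  each tissue-phase frame.

Contour placement is rigid: the phantom's mask set is translated onto the
target image at the integer offset maximising normalised cross-correlation,
which is the package's stand-in for vendor LV segmentation under purely rigid
simulated motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import DynamicFrameSeries, TimeActivityCurve
from .ddmc import _prep_ref, _search_one
from .phantom import TERRITORIES, PhantomGeometry

VARIANT_NAMES = ("fixed-boundary", "mid-wall", "late-frame-surface")


@dataclass(frozen=True)
class SamplingVariant:
    """One software-package-style sampling configuration.

    Besides contour source and wall locus, each variant samples the blood
    pool differently (``idif_erosion`` voxels of cavity erosion) and, for
    mid-wall loci, uses its own band half-width -- mirroring how commercial
    packages keep distinct segmentation geometry even on identical images.
    """

    name: str
    contour_source: str        # 'all' | 'late'
    locus: str                 # 'full' | 'midwall'
    per_frame_reseg: bool
    idif_erosion: int = 0
    band_halfwidth_vox: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"variant must be one of {VARIANT_NAMES}")
        if self.contour_source not in ("all", "late"):
            raise ValueError("contour_source must be 'all' or 'late'")
        if self.locus not in ("full", "midwall"):
            raise ValueError("locus must be 'full' or 'midwall'")


def sampling_variants() -> dict[str, SamplingVariant]:
    """The three named variant configurations."""
    return {
        "fixed-boundary": SamplingVariant("fixed-boundary", "all", "full", False,
                                          idif_erosion=0),
        "mid-wall": SamplingVariant("mid-wall", "all", "midwall", False,
                                    idif_erosion=1, band_halfwidth_vox=1.0),
        "late-frame-surface": SamplingVariant("late-frame-surface", "late", "midwall",
                                              True, idif_erosion=2,
                                              band_halfwidth_vox=1.5),
    }


def midwall_mask(geometry: PhantomGeometry, halfwidth_vox: float = 1.0) -> np.ndarray:
    """Mid-wall band: shell voxels equidistant (within ``halfwidth_vox``) from
    the endocardial and epicardial surfaces."""
    cache = getattr(geometry, "_midwall_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(geometry, "_midwall_cache", cache)
    if halfwidth_vox not in cache:
        myo = geometry.myocardium_mask
        inner = geometry.blood_pool_mask
        outside = ~(myo | inner)
        d_in = ndimage.distance_transform_edt(~inner)
        d_out = ndimage.distance_transform_edt(~outside)
        band = myo & (np.abs(d_in - d_out) <= halfwidth_vox)
        if not band.any():  # extremely thin wall: fall back to the full shell
            band = myo
        cache[halfwidth_vox] = band
    return cache[halfwidth_vox]


def blood_sampling_mask(geometry: PhantomGeometry, erosion_vox: int = 0) -> np.ndarray:
    """Blood-pool sampling region: the cavity, optionally eroded."""
    if erosion_vox <= 0:
        return geometry.blood_pool_mask
    cache = getattr(geometry, "_blood_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(geometry, "_blood_cache", cache)
    if erosion_vox not in cache:
        eroded = ndimage.binary_erosion(geometry.blood_pool_mask,
                                        iterations=erosion_vox)
        cache[erosion_vox] = eroded if eroded.any() else geometry.blood_pool_mask
    return cache[erosion_vox]


def _heart_template(geometry: PhantomGeometry, source: str):
    """Synthetic placement template cropped to the heart bounding box."""
    cache = getattr(geometry, "_template_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(geometry, "_template_cache", cache)
    if source not in cache:
        tpl = np.zeros(geometry.grid_shape, dtype=np.float64)
        tpl[geometry.myocardium_mask] = 1.0
        tpl[geometry.blood_pool_mask] = 0.5 if source == "all" else 0.2
        sl = ndimage.find_objects(geometry.heart_mask.astype(np.int8))[0]
        cache[source] = (tpl[sl], np.array([s.start for s in sl]))
    return cache[source]


def locate_contours(
    image: np.ndarray,
    geometry: PhantomGeometry,
    source: str = "all",
    search_vox: int = 8,
    init_offset: np.ndarray | None = None,
) -> np.ndarray:
    """Best whole-voxel offset placing the heart template on ``image``.

    ``init_offset`` recentres the search (used for per-frame re-segmentation,
    where a small search around the late-frame placement suffices).
    """
    tpl, corner = _heart_template(geometry, source)
    init = np.zeros(3, dtype=int) if init_offset is None else np.asarray(init_offset, int)
    norm, ss = _prep_ref(tpl)
    anchor = np.clip(corner + init, 0, np.array(image.shape) - np.array(tpl.shape))
    disp, _ = _search_one(np.asarray(image, dtype=np.float64), tpl, norm, ss,
                          anchor, np.full(3, search_vox))
    return disp + (anchor - corner)


def _shift_mask(mask: np.ndarray, offset: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    src = []
    dst = []
    for ax, d in enumerate(offset):
        n = mask.shape[ax]
        d = int(d)
        if abs(d) >= n:
            return out
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _region_means(frames: DynamicFrameSeries, mask: np.ndarray) -> np.ndarray:
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty sampling region after contour placement")
    return frames.volumes[:, mask].sum(axis=1) / n / frames.durations


def extract_tacs(
    frames: DynamicFrameSeries,
    geometry: PhantomGeometry,
    variant: SamplingVariant,
    late_start_s: float = 300.0,
    tissue_phase_start_s: float = 150.0,
    search_vox: int = 8,
) -> dict:
    """IDIF and per-territory tissue TACs for one sampling variant.

    Returns ``{"idif": TimeActivityCurve, "tissue": {territory: TAC},
    "offset_voxels": placement offset}``.  TAC times are frame midpoints and
    values are mean region concentrations (counts per voxel per second).
    """
    vols = frames.volumes
    if float(vols.sum()) == 0.0:
        raise ValueError("summed image is empty; cannot derive contours")
    if variant.contour_source == "late":
        sel = frames.frame_starts >= late_start_s
        if not sel.any():
            sel = np.ones(frames.n_frames, dtype=bool)
        summed = vols[sel].sum(axis=0)
    else:
        summed = vols.sum(axis=0)
    offset = locate_contours(summed, geometry, variant.contour_source, search_vox)

    tissue_base = midwall_mask(geometry, variant.band_halfwidth_vox) \
        if variant.locus == "midwall" else geometry.myocardium_mask
    blood = blood_sampling_mask(geometry, variant.idif_erosion)

    mids = frames.midpoints
    idif_vals = _region_means(frames, _shift_mask(blood, offset))

    tissue: dict[str, TimeActivityCurve] = {}
    per_frame_offsets = np.tile(offset, (frames.n_frames, 1))
    if variant.per_frame_reseg:
        for i in range(frames.n_frames):
            if frames.frame_starts[i] >= tissue_phase_start_s:
                per_frame_offsets[i] = locate_contours(
                    vols[i], geometry, variant.contour_source,
                    search_vox=min(search_vox, 4), init_offset=offset)
    for terr in TERRITORIES:
        base = tissue_base & geometry.territory_mask(terr)
        if variant.per_frame_reseg:
            vals = np.empty(frames.n_frames)
            for i in range(frames.n_frames):
                m = _shift_mask(base, per_frame_offsets[i])
                n = int(m.sum())
                if n == 0:
                    raise ValueError("empty sampling region after contour placement")
                vals[i] = vols[i][m].sum() / n / frames.durations[i]
        else:
            vals = _region_means(frames, _shift_mask(base, offset))
        tissue[terr] = TimeActivityCurve(mids, vals, label=terr)

    return {"idif": TimeActivityCurve(mids, idif_vals, label="IDIF"),
            "tissue": tissue, "offset_voxels": offset}


def residual_activity_correction(
    tac: TimeActivityCurve,
    injection_time_s: float = 30.0,
) -> tuple[TimeActivityCurve, int]:
    """Subtract the pre-injection residual from a decay-corrected stress TAC.

    The first frame must precede the stress injection; that frame's
    decay-corrected concentration (a constant, since the residual follows
    physical decay only) is subtracted from every frame.  Negative results are
    clamped to zero; the number of clamped points is returned.
    """
    if tac.times[0] >= injection_time_s:
        raise ValueError("first frame must precede the injection (missing "
                         "pre-injection frame)")
    residual = float(tac.values[0])
    corrected = tac.values - residual
    n_clamped = int((corrected < 0).sum())
    return tac.with_values(np.clip(corrected, 0.0, None)), n_clamped


def _reference_template(reference: np.ndarray, margin_vox: int):
    """Heart-window crop of a reference image: brightest-decile bounding box
    with a margin."""
    reference = np.asarray(reference, dtype=np.float64)
    thr = np.quantile(reference[reference > 0], 0.9) if (reference > 0).any() else 0.0
    objs = ndimage.find_objects(((reference >= thr) & (reference > 0)).astype(np.int8))
    if not objs or objs[0] is None:
        raise ValueError("reference image carries no signal")
    sl = objs[0]
    corner = np.maximum([s.start - margin_vox for s in sl], 0)
    stop = np.minimum([s.stop + margin_vox for s in sl], reference.shape)
    tpl = reference[tuple(slice(c, e) for c, e in zip(corner, stop))]
    norm, ss = _prep_ref(tpl)
    return tpl, corner, norm, ss


def gradient_magnitude(volume: np.ndarray, sigma_vox: float = 1.0) -> np.ndarray:
    """Smoothed gradient-magnitude image used as the registration channel."""
    smooth = ndimage.gaussian_filter(np.asarray(volume, dtype=np.float64), sigma_vox)
    gx, gy, gz = np.gradient(smooth)
    return np.sqrt(gx * gx + gy * gy + gz * gz)


def ismc_frame_registration(
    frames: DynamicFrameSeries,
    reference: np.ndarray | None = None,
    search_vox: int = 4,
    late_start_s: float = 300.0,
    exclude_before_s: float | None = None,
    template_margin_vox: int = 4,
) -> tuple[DynamicFrameSeries, np.ndarray, np.ndarray]:
    """Frame-by-frame rigid registration, emulating in-software motion
    correction.

    Each frame is shifted by whole voxels on all three axes to maximise the
    NCC between gradient-magnitude images of the frame and of a heart-window
    crop of the late summed reference.  The gradient channel makes the
    similarity robust to the contrast inversion between the blood-pool and
    tissue phases (bolus frames share the endocardial edge with the tissue
    reference even though their intensities anticorrelate) -- the same idea
    that image-based normalised-gradient-field corrections rely on.  Frames
    starting before ``exclude_before_s`` are left untouched (the
    backward-propagating correction that stops at the blood-pool phase), as
    are degenerate zero-variance frames.

    Returns (registered frames, per-frame shifts (F, 3), flags); flags marks
    frames that were skipped or degenerate.
    """
    if frames.n_frames < 2:
        raise ValueError("at least two frames are required")
    if reference is None:
        sel = frames.frame_starts >= late_start_s
        if not sel.any():
            sel = np.ones(frames.n_frames, dtype=bool)
        reference = frames.volumes[sel].sum(axis=0)
    tpl, corner, norm, ss = _reference_template(
        gradient_magnitude(reference), template_margin_vox)

    shifts = np.zeros((frames.n_frames, 3), dtype=int)
    flags = np.zeros(frames.n_frames, dtype=bool)
    out = np.array(frames.volumes)
    for i in range(frames.n_frames):
        if exclude_before_s is not None and frames.frame_starts[i] < exclude_before_s:
            flags[i] = True
            continue
        vol = np.asarray(frames.volumes[i], dtype=np.float64)
        if float(vol.std()) == 0.0:
            flags[i] = True
            continue
        disp, _ = _search_one(gradient_magnitude(vol), tpl, norm, ss, corner,
                              np.full(3, search_vox))
        shifts[i] = disp
        if np.any(disp != 0):
            out[i] = _shift_mask(frames.volumes[i], -disp)
    registered = DynamicFrameSeries(volumes=out, frame_starts=frames.frame_starts.copy(),
                                    frame_ends=frames.frame_ends.copy(),
                                    voxel_size_mm=frames.voxel_size_mm,
                                    decay_corrected=frames.decay_corrected)
    return registered, shifts, flags
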