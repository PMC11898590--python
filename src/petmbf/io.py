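"""Optional import/export: NIfTI volumes, CSV motion vectors, YAML study
configuration."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .containers import HistoImageSeries
from .pipeline import StudyConfig


def save_series_nifti(series: HistoImageSeries, path) -> None:
    """Write a histo-volume series as one 4D NIfTI file (x, y, z, t)."""
    data = np.moveaxis(series.volumes, 0, -1)
    affine = np.diag([series.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms((series.voxel_size_mm,) * 3 + (1.0,))
    nib.save(img, str(path))


def load_series_nifti(path) -> HistoImageSeries:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if data.ndim != 4:
        raise ValueError("expected a 4D NIfTI volume series")
    vols = np.moveaxis(data, -1, 0)
    voxel = float(img.header.get_zooms()[0])
    return HistoImageSeries(volumes=vols, second_index=np.arange(vols.shape[0]),
                            voxel_size_mm=voxel)


def save_motion_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def load_study_config(path) -> StudyConfig:
    """Read a study configuration from a YAML file.

    Recognised keys mirror :class:`~petmbf.pipeline.StudyConfig` fields;
    unknown keys are rejected to catch typos.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = set(StudyConfig.__dataclass_fields__)
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("variants", "mc_modes"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return StudyConfig(**raw)
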