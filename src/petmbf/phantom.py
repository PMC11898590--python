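"""Left-ventricle digital phantom: half-ellipsoidal myocardial shell, blood
pool cavity, a background (liver-surrogate) compartment and the three
coronary-territory labels (LAD / Cx / RCA) as 120-degree angular sectors
around the LV long axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TERRITORIES = ("LAD", "Cx", "RCA")


@dataclass
class PhantomGeometry:
    """Voxelised LV phantom geometry.

    ``territory_labels`` is an integer volume with 0 = not myocardium and
    1..3 = index into :data:`TERRITORIES`.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    myocardium_mask: np.ndarray
    blood_pool_mask: np.ndarray
    background_mask: np.ndarray
    territory_labels: np.ndarray

    def __post_init__(self) -> None:
        for m in (self.myocardium_mask, self.blood_pool_mask, self.background_mask):
            if m.shape != tuple(self.grid_shape):
                raise ValueError("mask shape must equal grid_shape")
        overlap = (self.myocardium_mask.astype(int) + self.blood_pool_mask.astype(int)
                   + self.background_mask.astype(int))
        if overlap.max() > 1:
            raise ValueError("compartment masks must be pairwise disjoint")
        labelled = self.territory_labels > 0
        if not np.array_equal(labelled, self.myocardium_mask):
            raise ValueError("every myocardial voxel needs exactly one territory label")

    def territory_mask(self, territory: str) -> np.ndarray:
        return self.territory_labels == (TERRITORIES.index(territory) + 1)

    def territory_voxel_counts(self) -> dict[str, int]:
        return {t: int(self.territory_mask(t).sum()) for t in TERRITORIES}

    @property
    def heart_mask(self) -> np.ndarray:
        return self.myocardium_mask | self.blood_pool_mask


def build_phantom(
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_mm: float = 2.0,
    outer_semi_axes_mm: tuple[float, float, float] = (26.0, 26.0, 36.0),
    wall_thickness_mm: float = 9.0,
    center_vox: tuple[float, float, float] | None = None,
) -> PhantomGeometry:
    """Construct the default LV phantom.

    The myocardium is the shell between two co-centred half-ellipsoids kept on
    the apical side of the equatorial plane (a half-ellipsoidal cup); the
    blood pool fills the inner cavity.  A separate ellipsoidal blob below and
    lateral to the heart stands in for hepatic background activity.  Wall
    thickness must span at least two voxels so that a mid-wall sampling band
    exists.
    """
    if wall_thickness_mm < 2 * voxel_size_mm:
        raise ValueError("shell thickness must be at least 2 voxels")
    nx, ny, nz = grid_shape
    if center_vox is None:
        center_vox = (nx / 2.0, ny / 2.0, nz / 2.0 + 4.0)
    cx, cy, cz = center_vox
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    xm = (x - cx) * voxel_size_mm
    ym = (y - cy) * voxel_size_mm
    zm = (z - cz) * voxel_size_mm

    ax, ay, az = outer_semi_axes_mm
    bx, by, bz = (ax - wall_thickness_mm, ay - wall_thickness_mm, az - wall_thickness_mm)
    outer = (xm / ax) ** 2 + (ym / ay) ** 2 + (zm / az) ** 2 <= 1.0
    inner = (xm / bx) ** 2 + (ym / by) ** 2 + (zm / bz) ** 2 <= 1.0
    apical = zm <= 0.0  # keep the apex-side half; the base plane caps the cup

    myocardium = outer & ~inner & apical
    blood = inner & apical

    angle = np.degrees(np.arctan2(ym, xm))
    labels = np.zeros(grid_shape, dtype=np.int8)
    lad = (angle >= -60.0) & (angle < 60.0)
    cxs = (angle >= 60.0) & (angle < 180.0)
    labels[myocardium & lad] = 1
    labels[myocardium & cxs] = 2
    labels[myocardium & ~lad & ~cxs] = 3

    # liver surrogate: ellipsoid offset inferiorly/laterally, clipped to grid
    lx, ly, lz = cx + 18.0, cy + 6.0, cz - 22.0
    liver = (((x - lx) * voxel_size_mm / 22.0) ** 2
             + ((y - ly) * voxel_size_mm / 18.0) ** 2
             + ((z - lz) * voxel_size_mm / 14.0) ** 2) <= 1.0
    background = liver & ~outer

    return PhantomGeometry(
        grid_shape=tuple(grid_shape),
        voxel_size_mm=float(voxel_size_mm),
        myocardium_mask=myocardium,
        blood_pool_mask=blood,
        background_mask=background,
        territory_labels=labels,
    )
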