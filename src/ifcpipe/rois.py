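"""Spherical seed regions in the four subcortical-cerebellar systems.

Seeds are defined by an MNI centre coordinate and a radius (6 mm by
default) and resolved to voxel index sets on a :class:`~ifcpipe.grids.Grid`.
The default table covers the four modulatory systems studied throughout the
package -- striatum, medial temporal lobe (MTL), amygdala, and cerebellum --
with four seeds each (left/right pairs of two subregions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Grid

SYSTEMS = ("striatum", "mtl", "amygdala", "cerebellum")


@dataclass(frozen=True)
class RoiSpec:
    """Named spherical seed in world (MNI millimetre) coordinates."""

    name: str
    system: str
    hemisphere: str  # "L" or "R"
    center_mm: tuple[float, float, float]
    radius_mm: float = 6.0

    def __post_init__(self):
        if self.system not in SYSTEMS:
            raise ValueError(
                f"unknown system {self.system!r}; expected one of {SYSTEMS}"
            )
        if self.radius_mm < 0:
            raise ValueError("radius must be non-negative")


@dataclass(frozen=True)
class RoiMask:
    """A seed resolved to flat voxel indices on a specific grid."""

    spec: RoiSpec
    indices: np.ndarray = field(repr=False)  # flat C-order voxel indices
    grid: Grid = field(repr=False)

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    def as_bool(self) -> np.ndarray:
        out = np.zeros(self.grid.n_voxels, dtype=bool)
        out[self.indices] = True
        return out


def default_roi_specs(radius_mm: float = 6.0) -> list[RoiSpec]:
    """The 16-seed table used by default: 4 systems x 2 subregions x 2 hemispheres.

    Striatal, cerebellar, and MTL centres are literature coordinates for
    ventral/dorsal striatum, Crus 1/2, and hippocampus/parahippocampus.
    The amygdala seeds (basolateral and centromedial subdivisions) are
    spherical synthetic stand-ins for probabilistic cytoarchitectonic
    masks, placed at representative centres of gravity.
    """
    rows = [
        # (subregion, system, (x, y, z) for right hemisphere)
        ("striatum_ventral", "striatum", (12.0, 9.0, -9.0)),
        ("striatum_dorsal", "striatum", (24.0, 12.0, 0.0)),
        ("cerebellum_crus1", "cerebellum", (12.0, -80.0, -24.0)),
        ("cerebellum_crus2", "cerebellum", (22.0, -86.0, -40.0)),
        ("mtl_hippocampus", "mtl", (24.0, -18.0, -18.0)),
        ("mtl_parahippocampus", "mtl", (26.0, -40.0, -12.0)),
        ("amygdala_basolateral", "amygdala", (28.0, -2.0, -22.0)),
        ("amygdala_centromedial", "amygdala", (24.0, -10.0, -14.0)),
    ]
    specs: list[RoiSpec] = []
    for base, system, (x, y, z) in rows:
        for hemi, sx in (("L", -1.0), ("R", 1.0)):
            specs.append(
                RoiSpec(
                    name=f"{base}_{hemi}",
                    system=system,
                    hemisphere=hemi,
                    center_mm=(sx * x, y, z),
                    radius_mm=radius_mm,
                )
            )
    # keep deterministic, readable order: by system then name
    specs.sort(key=lambda s: (SYSTEMS.index(s.system), s.name))
    return specs


def make_roi_masks(roi_specs: list[RoiSpec], grid: Grid) -> list[RoiMask]:
    """Resolve spherical seeds to voxel masks.

    A voxel belongs to a seed when its centre lies within ``radius_mm`` of
    the seed centre in world coordinates.

    Raises
    ------
    ValueError
        If a seed centre falls outside the grid, or if a sphere contains no
        voxel centre at all.
    """
    centers = grid.voxel_centers()
    masks = []
    for spec in roi_specs:
        if not grid.contains_world(np.asarray(spec.center_mm))[0]:
            raise ValueError(f"ROI {spec.name!r}: centre {spec.center_mm} outside grid")
        d2 = ((centers - np.asarray(spec.center_mm)) ** 2).sum(axis=1)
        idx = np.flatnonzero(d2 <= spec.radius_mm**2 + 1e-9)
        if idx.size == 0:
            raise ValueError(
                f"ROI {spec.name!r}: sphere of radius {spec.radius_mm} mm at "
                f"{spec.center_mm} misses all voxel centres"
            )
        masks.append(RoiMask(spec=spec, indices=idx, grid=grid))
    return masks
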