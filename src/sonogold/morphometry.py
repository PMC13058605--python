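"""Voxel morphometry of refractive-index tomograms for sonoporation readout.

Optical diffraction tomography yields a 3-D refractive-index (RI) volume per
cell.  Voxels are classified into compartments by RI band (membrane
1.33-1.34, nucleus 1.35-1.36, lipid droplets > 1.37; remaining cell voxels
are cytoplasm).  Sonoporation transiently riddles the plasma membrane with
pores, raising the membrane surface area at near-constant cell volume, so
the surface-area-to-volume ratio (1/um) is used as the morphometric
indicator of membrane permeabilization.

Surface area is estimated by marching-cubes iso-surface triangulation at the
0.5 level of the binary mask.  Counting exposed voxel faces instead would
overestimate a sphere's area by ~50% (a staircase artifact) and is only kept
as a negative control in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import measure

from .kinetics import GroupComparison, compare_groups

__all__ = [
    "VoxelVolume",
    "RIBands",
    "MorphometryRecord",
    "classify_ri",
    "measure_cell",
    "av_ratio_study",
]


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D voxel array, either refractive-index-valued or binary.

    ``voxel_size`` is the isotropic edge length in micrometres, or a
    3-tuple for anisotropic grids.
    """

    values: np.ndarray
    voxel_size: float | tuple[float, float, float]
    cell_id: str = ""
    group_min: float = 0.0
    time_h: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.values)
        if a.ndim != 3:
            raise ValueError("values must be 3-D")
        object.__setattr__(self, "values", a)
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValueError("voxel_size must be positive")

    @property
    def spacing(self) -> tuple[float, float, float]:
        v = self.voxel_size
        return (v, v, v) if np.isscalar(v) else tuple(v)

    @property
    def is_binary(self) -> bool:
        return self.values.dtype == bool or set(np.unique(self.values)) <= {0, 1}


@dataclass(frozen=True)
class RIBands:
    """RI intervals for compartment classification (closed intervals; lipid open-ended)."""

    membrane: tuple[float, float] = (1.33, 1.34)
    nucleus: tuple[float, float] = (1.35, 1.36)
    lipid_min: float = 1.37
    #: Voxels above this RI (or inside any named band) count as cell support.
    cell_support_ri: float = 1.335


@dataclass(frozen=True)
class MorphometryRecord:
    """Surface area (um^2), volume (um^3) and their ratio (1/um) for one cell."""

    surface_area: float
    volume: float
    av_ratio: float
    method: str = "marching_cubes"
    cell_id: str = ""
    group_min: float = 0.0
    time_h: float = 0.0


def classify_ri(vol: VoxelVolume, bands: RIBands = RIBands()) -> dict[str, np.ndarray]:
    """Per-compartment binary masks from an RI volume.

    Returns disjoint masks for ``membrane``, ``nucleus``, ``lipid`` and
    ``cytoplasm`` (cell support not captured by a named band).
    """
    if vol.is_binary:
        raise TypeError("RI classification needs refractive-index values, got a binary mask")
    v = vol.values.astype(float)
    membrane = (v >= bands.membrane[0]) & (v <= bands.membrane[1])
    nucleus = (v >= bands.nucleus[0]) & (v <= bands.nucleus[1])
    lipid = v > bands.lipid_min
    named = membrane | nucleus | lipid
    support = (v > bands.cell_support_ri) | named
    cytoplasm = support & ~named
    return {"membrane": membrane, "nucleus": nucleus, "lipid": lipid,
            "cytoplasm": cytoplasm}


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask, connectivity=1)
    if labels.max() <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    warnings.warn("mask is disconnected; using largest component", stacklevel=3)
    return labels == int(np.argmax(counts))


def measure_cell(vol: VoxelVolume) -> MorphometryRecord:
    """Volume, triangulated surface area and A/V ratio of a binary mask.

    Volume is voxel count times voxel volume; surface area is the summed
    triangle area of the marching-cubes iso-surface at level 0.5.  The binary
    mask is zero-padded (so boundary-touching surfaces are closed) and
    smoothed with a 1-voxel Gaussian before triangulation: iso-surfacing a
    raw 0/1 field inflates a digitized sphere's area by ~9%, while the
    smoothed field recovers it to ~0.3% across radii 5-20 um at 0.25 um
    voxels.
    """
    if not vol.is_binary:
        raise TypeError("measure_cell expects a binary mask; threshold RI volumes first")
    mask = vol.values.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    mask = _largest_component(mask)
    spacing = vol.spacing
    voxel_volume = float(np.prod(spacing))
    volume = float(mask.sum()) * voxel_volume
    padded = gaussian_filter(np.pad(mask, 2).astype(np.float32), sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    return MorphometryRecord(
        surface_area=area, volume=volume, av_ratio=area / volume,
        method="marching_cubes", cell_id=vol.cell_id,
        group_min=vol.group_min, time_h=vol.time_h,
    )


def voxel_face_area(vol: VoxelVolume) -> float:
    """Naive exposed-voxel-face surface area (um^2).

    Systematically overestimates smooth surfaces; provided as a negative
    control for the marching-cubes estimator.
    """
    mask = vol.values.astype(bool)
    sx, sy, sz = vol.spacing
    face = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    total = 0.0
    for axis in range(3):
        padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = np.abs(np.diff(padded.astype(np.int8), axis=axis))
        total += float(diff.sum()) * face[axis]
    return total


def av_ratio_study(
    records_by_group_time: dict[tuple[float, float], list[MorphometryRecord]],
    control_group: float = 0.0,
) -> tuple[dict[float, GroupComparison], pd.DataFrame]:
    """Per-timepoint group comparison of A/V ratios plus percent increases.

    Keys of ``records_by_group_time`` are ``(group_min, time_h)``.  Returns a
    dict of per-timepoint ANOVA/Tukey results and a table of each irradiated
    group's mean-ratio percent increase over the control group.
    """
    times = sorted({t for _, t in records_by_group_time})
    groups = sorted({g for g, _ in records_by_group_time})
    if control_group not in groups or len(groups) < 2:
        raise ValueError("need a control group and >= 1 irradiated group")
    comparisons: dict[float, GroupComparison] = {}
    rows = []
    for t in times:
        ratios = {
            g: np.array([r.av_ratio for r in records_by_group_time[(g, t)]])
            for g in groups if (g, t) in records_by_group_time
        }
        comparisons[t] = compare_groups(ratios)
        ctrl = ratios[control_group].mean()
        for g in groups:
            if g == control_group or g not in ratios:
                continue
            rows.append({
                "time_h": t,
                "group_min": g,
                "control_mean": ctrl,
                "group_mean": ratios[g].mean(),
                "percent_increase": 100.0 * (ratios[g].mean() - ctrl) / ctrl,
            })
    return comparisons, pd.DataFrame(rows)
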