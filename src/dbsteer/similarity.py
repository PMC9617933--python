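"""Similarity metrics between stimulation settings, activated volumes and scores.

Setting similarity is the amplitude ratio times one minus the normalized
Euclidean distance of the two signed fractionalization vectors (E1..E8
plus the IPG case, distance divided by sqrt(8) so that a full bipolar
swap normalizes to 1).  Volume similarity is the Jaccard index of
voxelized activated volumes; score similarity maps the Euclidean distance
of two 0-4 score lists onto [0, 1].

The activated-volume model here is a deliberately simple stand-in (union
of current-scaled spheres around the active electrode centroids, minus a
thin encapsulation shell along the lead axis); it is NOT the published
finite-element model, so absolute volumes and Jaccard values are not
comparable with clinically reported ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from dbsteer.lead import (
    DEFAULT_GEOMETRY,
    LeadGeometry,
    StimSetting,
    setting_to_vector,
)

_SQRT8 = math.sqrt(8.0)


@dataclass(frozen=True)
class VoxelVTA:
    """A voxelized activated volume on a global grid aligned at the origin."""

    voxel_size_mm: float
    voxels: frozenset[tuple[int, int, int]]

    @property
    def volume_mm3(self) -> float:
        return len(self.voxels) * self.voxel_size_mm**3


@dataclass(frozen=True)
class SimilarityReport:
    """Bundle of all pairwise similarity metrics for one hemisphere."""

    amp_rat: float
    norm_elec_conf_dist: float
    set_sim: float
    jac_idx: float | None = None
    scr_sim: float | None = None

    def to_dict(self) -> dict:
        return {
            "AmpRat": self.amp_rat,
            "NormElcConfDist": self.norm_elec_conf_dist,
            "SetSim": self.set_sim,
            "JacIdx": self.jac_idx,
            "ScrSim": self.scr_sim,
        }


def amp_ratio(a1: float, a2: float) -> float:
    """min/max ratio of two stimulation amplitudes, in (0, 1]."""
    if a1 <= 0.0 or a2 <= 0.0:
        raise ValueError("amplitude ratio requires two positive amplitudes")
    return min(a1, a2) / max(a1, a2)


def norm_elec_conf_dist(v1, v2) -> float:
    """Euclidean distance of two signed fraction vectors, scaled by sqrt(8).

    Vectors cover the 8 lead electrodes plus the IPG case; with cathodes
    summing to -1 and anodes to +1 the scaling maps a full bipolar swap
    (e.g. E1 -100%/case +100% against case -100%/E1 +100%) to exactly 1.
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != (9,) or b.shape != (9,):
        raise ValueError("fraction vectors must have 9 entries (E1..E8 + case)")
    return float(np.linalg.norm(a - b) / _SQRT8)


def setting_similarity(s1: StimSetting, s2: StimSetting) -> float:
    """AmpRat * (1 - NormElcConfDist) for two settings, in [0, 1]."""
    return amp_ratio(s1.amplitude, s2.amplitude) * (
        1.0 - norm_elec_conf_dist(setting_to_vector(s1), setting_to_vector(s2))
    )


def score_similarity(scores1, scores2) -> float:
    """1 - EuclideanDistance / sqrt(16 N) over two aligned 0-4 score lists."""
    a = np.asarray(scores1, dtype=float)
    b = np.asarray(scores2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("score lists must be equal-length and non-empty")
    return float(1.0 - np.linalg.norm(a - b) / math.sqrt(16.0 * a.size))


# ---------------------------------------------------------------------------
# Simplified activated-volume stand-in
# ---------------------------------------------------------------------------


def _electrode_position(
    electrode: int, geometry: LeadGeometry
) -> tuple[float, float, float]:
    level = geometry.electrode_levels[electrode]
    z = level * geometry.level_spacing_mm
    angle = geometry.electrode_angle(electrode)
    if angle is None:
        return 0.0, 0.0, z
    rad = math.radians(angle)
    r = geometry.lead_radius_mm
    return r * math.cos(rad), r * math.sin(rad), z


def vta_model(
    setting: StimSetting,
    geometry: LeadGeometry = DEFAULT_GEOMETRY,
    voxel_size_mm: float = 0.25,
    k_mm_per_sqrt_ma: float = 1.3,
    encapsulation_mm: float = 0.1,
) -> VoxelVTA:
    """Voxelized activated volume for a setting (simplified stand-in model).

    Each active lead electrode (non-zero fraction, case excluded)
    contributes a sphere of radius ``k * sqrt(|fraction| * amplitude)``
    centered on its contact centroid; voxels within the encapsulation
    radius of the lead axis are excluded.  Zero amplitude yields an empty
    volume.
    """
    if setting.amplitude < 0.0:
        raise ValueError("amplitude must be >= 0")
    if setting.amplitude == 0.0:
        return VoxelVTA(voxel_size_mm, frozenset())
    spheres = []
    for e in range(8):
        frac = abs(setting.fractions[e])
        if frac <= 0.0:
            continue
        radius = k_mm_per_sqrt_ma * math.sqrt(frac * setting.amplitude)
        spheres.append((_electrode_position(e, geometry), radius))
    if not spheres:
        return VoxelVTA(voxel_size_mm, frozenset())
    lo = np.min([[c - r for c in ctr] for ctr, r in spheres], axis=0)
    hi = np.max([[c + r for c in ctr] for ctr, r in spheres], axis=0)
    i0 = np.floor(lo / voxel_size_mm).astype(int) - 1
    i1 = np.ceil(hi / voxel_size_mm).astype(int) + 1
    ix = np.arange(i0[0], i1[0] + 1)
    iy = np.arange(i0[1], i1[1] + 1)
    iz = np.arange(i0[2], i1[2] + 1)
    gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
    # Voxel centers on a global grid so volumes from different settings align.
    cx = (gx + 0.5) * voxel_size_mm
    cy = (gy + 0.5) * voxel_size_mm
    cz = (gz + 0.5) * voxel_size_mm
    inside = np.zeros(cx.shape, dtype=bool)
    for (x, y, z), r in spheres:
        inside |= (cx - x) ** 2 + (cy - y) ** 2 + (cz - z) ** 2 <= r**2
    inside &= cx**2 + cy**2 > encapsulation_mm**2
    voxels = frozenset(
        zip(gx[inside].tolist(), gy[inside].tolist(), gz[inside].tolist())
    )
    return VoxelVTA(voxel_size_mm, voxels)


def jaccard_index(v1: VoxelVTA, v2: VoxelVTA) -> float:
    """Intersection-over-union of two voxel sets on the same grid."""
    if not math.isclose(v1.voxel_size_mm, v2.voxel_size_mm):
        raise ValueError("voxel grids do not match")
    union = v1.voxels | v2.voxels
    if not union:
        raise ValueError("both volumes are empty")
    return len(v1.voxels & v2.voxels) / len(union)


def compare_settings(
    s1: StimSetting,
    s2: StimSetting,
    scores1=None,
    scores2=None,
    geometry: LeadGeometry = DEFAULT_GEOMETRY,
    with_vta: bool = True,
    voxel_size_mm: float = 0.25,
) -> SimilarityReport:
    """Compute the full similarity report between two settings."""
    dist = norm_elec_conf_dist(setting_to_vector(s1), setting_to_vector(s2))
    rat = amp_ratio(s1.amplitude, s2.amplitude)
    jac = None
    if with_vta:
        jac = jaccard_index(
            vta_model(s1, geometry, voxel_size_mm),
            vta_model(s2, geometry, voxel_size_mm),
        )
    scr = None
    if scores1 is not None and scores2 is not None:
        scr = score_similarity(scores1, scores2)
    return SimilarityReport(
        amp_rat=rat,
        norm_elec_conf_dist=dist,
        set_sim=rat * (1.0 - dist),
        jac_idx=jac,
        scr_sim=scr,
    )
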