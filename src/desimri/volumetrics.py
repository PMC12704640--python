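"""From reconstructed 3D label masks to physical CSF volumes.

Volumes are voxel counts times the voxel volume on the scan's native grid
(in-plane pixel spacing times slice thickness).  Small connected components
(default below 50 mm^3, 26-connectivity) are removed first — mis-segmented
specks would otherwise inflate the thin sulcal compartments.  The superior
sulcal volume is restricted to the dihedral wedge opening superiorly from
the AC-PC line, and all volumetry is restricted to the AC-PC slab unless
``slab_only=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .acpc import LandmarkSet, WedgeSpec, wedge_sector_mask
from .image_io import SliceImage2D
from .masks import MultiLabelMask

#: default minimum component size retained, mm^3
DEFAULT_MIN_COMPONENT_MM3 = 50.0
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VolumeReport:
    left_sylvian_mm3: float
    right_sylvian_mm3: float
    sylvian_total_mm3: float
    suprasylvian_total_mm3: float
    superior_wedge_mm3: float
    n_components_removed: dict
    slab_extent_mm: float

    def __post_init__(self):
        vols = (self.left_sylvian_mm3, self.right_sylvian_mm3,
                self.sylvian_total_mm3, self.suprasylvian_total_mm3,
                self.superior_wedge_mm3)
        if any(v < 0 for v in vols):
            raise ValueError("volumes must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def mask_volume_mm3(mask: np.ndarray, spacing) -> float:
    """Voxel count times voxel volume."""
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    return float(np.count_nonzero(mask) * np.prod(spacing))


def remove_small_components(mask3d: np.ndarray, min_mm3: float, spacing):
    """Drop 26-connected components smaller than ``min_mm3``.

    Returns (filtered mask, number of components removed).  Never adds
    voxels and is idempotent.
    """
    mask3d = np.asarray(mask3d, dtype=bool)
    if not mask3d.any() or min_mm3 <= 0:
        return mask3d.copy(), 0
    voxvol = float(np.prod(np.asarray(spacing, dtype=float)))
    labels, n = ndimage.label(mask3d, structure=_STRUCT_26)
    if n == 0:
        return mask3d.copy(), 0
    sizes = np.bincount(labels.ravel())[1:] * voxvol
    keep = np.flatnonzero(sizes >= min_mm3) + 1
    out = np.isin(labels, keep)
    return out, int(n - keep.size)


def sylvian_volume(seg: MultiLabelMask, min_mm3: float = DEFAULT_MIN_COMPONENT_MM3):
    """(left, right, total) Sylvian fissure volume in mm^3.

    Each side is filtered for small components independently before
    conversion; total = left + right.
    """
    left, n_l = remove_small_components(seg.get("left_sylvian"), min_mm3, seg.spacing)
    right, n_r = remove_small_components(seg.get("right_sylvian"), min_mm3, seg.spacing)
    lv = mask_volume_mm3(left, seg.spacing)
    rv = mask_volume_mm3(right, seg.spacing)
    return lv, rv, lv + rv, {"left_sylvian": n_l, "right_sylvian": n_r}


def _slab_plane_indices(seg: MultiLabelMask, lm: LandmarkSet):
    sy = seg.spacing[1]
    oy = seg.origin[1]
    j_ac = int(round((lm.ac[1] - oy) / sy))
    j_pc = int(round((lm.pc[1] - oy) / sy))
    lo, hi = min(j_ac, j_pc), max(j_ac, j_pc)
    ny = seg.grid_shape[1]
    if not (0 <= lo and hi < ny):
        raise ValueError("AC/PC planes fall outside the segmentation grid")
    return lo, hi


def superior_sulci_volume(seg: MultiLabelMask, lm: LandmarkSet,
                          spec: WedgeSpec = None,
                          min_mm3: float = DEFAULT_MIN_COMPONENT_MM3,
                          slab_only: bool = True,
                          _prefiltered: np.ndarray = None):
    """Suprasylvian volume inside the superior dihedral wedge, mm^3.

    The mask must be in the AC-PC-aligned frame (so the wedge apex in every
    coronal plane is the (x, z) position of the AC).  A voxel counts iff its
    centre lies within the in-plane angular sector of the wedge.
    """
    spec = spec or WedgeSpec()
    if seg.origin is None:
        raise ValueError("segmentation mask carries no grid origin")
    if abs(lm.ac[0] - lm.pc[0]) > 1e-6 or abs(lm.ac[2] - lm.pc[2]) > 1e-6:
        raise ValueError("landmarks are not in the AC-PC-aligned frame")
    supra = _prefiltered
    if supra is None:
        supra, _ = remove_small_components(seg.get("suprasylvian"), min_mm3,
                                           seg.spacing)
    apex = (float(lm.ac[0]), float(lm.ac[2]))
    sx, sy, sz = seg.spacing
    ox, oy, oz = seg.origin
    if slab_only:
        lo, hi = _slab_plane_indices(seg, lm)
    else:
        lo, hi = 0, seg.grid_shape[1] - 1
    # the sector mask is identical for every coronal plane
    template = SliceImage2D(supra[:, lo, :], pixel_spacing=(sx, sz),
                            origin_inplane=(ox, oz))
    sector = wedge_sector_mask(template, apex, spec)
    count = int(sum(np.count_nonzero(supra[:, j, :] & sector)
                    for j in range(lo, hi + 1)))
    return count * sx * sy * sz


def compute_volume_report(seg: MultiLabelMask, lm: LandmarkSet,
                          wedge: WedgeSpec = None,
                          min_mm3: float = DEFAULT_MIN_COMPONENT_MM3,
                          slab_only: bool = True) -> VolumeReport:
    """Full volumetric summary of one segmented, AC-PC-aligned scan."""
    wedge = wedge or WedgeSpec()
    seg_slab = seg
    if slab_only and seg.origin is not None:
        lo, hi = _slab_plane_indices(seg, lm)
        ch = np.zeros_like(seg.channels)
        ch[:, :, lo:hi + 1, :] = seg.channels[:, :, lo:hi + 1, :]
        seg_slab = MultiLabelMask(ch, spacing=seg.spacing, origin=seg.origin,
                                  names=seg.names)
    lv, rv, total, removed = sylvian_volume(seg_slab, min_mm3)
    supra_f, n_s = remove_small_components(seg_slab.get("suprasylvian"),
                                           min_mm3, seg_slab.spacing)
    removed["suprasylvian"] = n_s
    supra_total = mask_volume_mm3(supra_f, seg_slab.spacing)
    wedge_vol = superior_sulci_volume(seg_slab, lm, wedge, min_mm3,
                                      slab_only=slab_only, _prefiltered=supra_f)
    return VolumeReport(
        left_sylvian_mm3=lv,
        right_sylvian_mm3=rv,
        sylvian_total_mm3=total,
        suprasylvian_total_mm3=supra_total,
        superior_wedge_mm3=wedge_vol,
        n_components_removed=removed,
        slab_extent_mm=float(abs(lm.ac[1] - lm.pc[1])),
    )
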