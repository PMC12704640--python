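"""AC-PC coordinate frame, rigid realignment, coronal slicing and the wedge.

The anterior and posterior commissures (AC, PC) define the standard axis for
head realignment.  The pipeline accepts their coordinates as input (mm, RAS,
in the physical space of the NIfTI affine); an automatic detector can be
plugged in upstream.  In the aligned frame the AC sits at the origin and the
AC->PC direction points along -y (posterior), so every coronal grid plane is
perpendicular to the AC-PC axis.

The superior sulcal region of interest is a dihedral wedge: the region
between two half-planes sharing the AC-PC line as their edge, opening
superiorly with a configurable total aperture (default 30 degrees, i.e.
+/-15 degrees about the vertical).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import SliceImage2D, VolumeImage


@dataclass
class LandmarkSet:
    """AC and PC positions in mm (RAS)."""

    ac: np.ndarray
    pc: np.ndarray

    def __post_init__(self):
        self.ac = np.asarray(self.ac, dtype=float).reshape(3)
        self.pc = np.asarray(self.pc, dtype=float).reshape(3)
        d = float(np.linalg.norm(self.ac - self.pc))
        if d == 0:
            raise ValueError("AC and PC coincide")
        if not (10.0 <= d <= 50.0):
            warnings.warn(
                f"AC-PC distance {d:.1f} mm is outside the plausible 10-50 mm range"
            )
        if self.ac[1] <= self.pc[1]:
            raise ValueError(
                "AC must be anterior to PC in RAS (ac_y > pc_y); "
                "check the landmark order"
            )

    @property
    def distance_mm(self) -> float:
        return float(np.linalg.norm(self.ac - self.pc))

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(ac=d["ac"], pc=d["pc"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"ac": list(self.ac), "pc": list(self.pc)}, fh, indent=2)


@dataclass
class RigidTransform:
    """Proper rigid map p -> R p + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must have determinant +1 (no reflection)")

    def apply(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (self.rotation @ pts.T).T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


@dataclass
class WedgeSpec:
    """Superior dihedral wedge: apex edge on the AC-PC line, opening up (+z).

    ``opening_angle_deg`` is the FULL aperture; membership uses the half
    angle about the superior direction.
    """

    opening_angle_deg: float = 30.0

    def __post_init__(self):
        if not (0.0 < self.opening_angle_deg < 180.0):
            raise ValueError("opening angle must lie in (0, 180) degrees")

    @property
    def half_angle_deg(self) -> float:
        return self.opening_angle_deg / 2.0


def pitch_angle(lm: LandmarkSet) -> float:
    """Signed head pitch in degrees.

    The angle, in the midsagittal (y-z) plane, between the AC->PC direction
    and the posterior (-y) axis; positive when PC drops below AC (nose-up
    pitch of the AC-PC line).  Range (-90, 90).
    """
    d = lm.pc - lm.ac
    return float(np.degrees(np.arctan2(-d[2], -d[1])))


def acpc_transform(lm: LandmarkSet) -> RigidTransform:
    """Rigid transform taking AC to the origin and AC->PC onto -y.

    Two landmarks leave the roll degree of freedom undetermined; the minimal
    rotation (about the axis perpendicular to both the current and target
    directions) is used, which keeps the scanner left-right axis as close to
    itself as the alignment allows.
    """
    u = (lm.pc - lm.ac) / lm.distance_mm
    target = np.array([0.0, -1.0, 0.0])
    c = float(np.clip(u @ target, -1.0, 1.0))
    axis = np.cross(u, target)
    s = float(np.linalg.norm(axis))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else None
        if R is None:
            raise ValueError("AC->PC direction is anti-parallel to the target axis")
    else:
        axis = axis / s
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
    return RigidTransform(R, -R @ lm.ac)


def resample_to_acpc(vol: VolumeImage, lm: LandmarkSet,
                     interpolation: str = "linear"):
    """Rigidly resample a RAS volume into the AC-PC-aligned frame.

    Returns the resampled volume and the landmarks expressed in the aligned
    frame (AC at the origin, PC on the -y axis, pitch 0).  Spacing is
    preserved; the output grid is the axis-aligned bounding box of the
    transformed input.  ``interpolation`` is 'linear' for intensity volumes
    or 'nearest' for label volumes.
    """
    if vol.orientation != "RAS":
        raise ValueError("resample_to_acpc expects a RAS volume")
    for name, p in (("AC", lm.ac), ("PC", lm.pc)):
        idx = vol.mm_to_index(p)
        if np.any(idx < -0.5) or np.any(idx > np.array(vol.voxels.shape) - 0.5):
            raise ValueError(f"{name} landmark lies outside the volume grid")
    xf = acpc_transform(lm)
    spacing = vol.spacing
    # transformed corners of the input grid -> output bounding box
    n = np.array(vol.voxels.shape)
    corners = np.array([[i, j, k] for i in (0, n[0] - 1)
                        for j in (0, n[1] - 1) for k in (0, n[2] - 1)], float)
    corners_mm = xf.apply(vol.index_to_mm(corners))
    lo = corners_mm.min(axis=0)
    hi = corners_mm.max(axis=0)
    out_shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    out_affine = np.eye(4)
    out_affine[:3, :3] = np.diag(spacing)
    # snap the origin to a multiple of the spacing so 0 mm falls exactly on
    # a grid plane (the AC then lands on a coronal plane)
    origin = spacing * np.floor(lo / spacing)
    out_affine[:3, 3] = origin
    # output index -> input index map for ndimage.affine_transform
    inv = xf.inverse()
    A_in_inv = np.linalg.inv(vol.affine[:3, :3])
    M = A_in_inv @ inv.rotation @ np.diag(spacing)
    off = A_in_inv @ (inv.rotation @ origin + inv.translation - vol.affine[:3, 3])
    order = {"linear": 1, "nearest": 0}[interpolation]
    out = ndimage.affine_transform(
        vol.voxels.astype(np.float32 if order else vol.voxels.dtype),
        M, offset=off, output_shape=tuple(out_shape), order=order,
        mode="constant", cval=0.0, prefilter=False)
    lm_out = LandmarkSet(ac=xf.apply(lm.ac), pc=xf.apply(lm.pc))
    return VolumeImage(out, out_affine), lm_out


def coronal_slices_between(vol_aligned: VolumeImage, lm: LandmarkSet):
    """Every coronal grid plane between PC and AC, posterior to anterior.

    The volume must already be AC-PC aligned (pitch 0 within 0.1 degrees).
    Each landmark snaps to its nearest grid plane; both endpoint planes are
    included.  Each slice carries its plane index and in-plane (x, z)
    spacing and origin.
    """
    if abs(pitch_angle(lm)) > 0.1:
        raise ValueError("volume/landmarks are not AC-PC aligned (pitch != 0)")
    sy = float(vol_aligned.spacing[1])
    oy = float(vol_aligned.origin[1])
    j_ac = int(round((lm.ac[1] - oy) / sy))
    j_pc = int(round((lm.pc[1] - oy) / sy))
    if j_ac == j_pc:
        raise ValueError("AC and PC fall on the same coronal grid plane")
    ny = vol_aligned.voxels.shape[1]
    if not (0 <= j_ac < ny and 0 <= j_pc < ny):
        raise ValueError("AC/PC planes fall outside the volume grid")
    sx, _, sz = (float(s) for s in vol_aligned.spacing)
    ox, _, oz = (float(o) for o in vol_aligned.origin)
    slices = []
    for j in range(min(j_pc, j_ac), max(j_pc, j_ac) + 1):
        slices.append(SliceImage2D(
            pixels=vol_aligned.voxels[:, j, :],
            pixel_spacing=(sx, sz),
            slice_position=j,
            origin_inplane=(ox, oz),
        ))
    return slices


def wedge_sector_mask(slc: SliceImage2D, apex, spec: WedgeSpec) -> np.ndarray:
    """Boolean in-plane mask of the superior wedge sector.

    A pixel is included iff its centre lies within the angular sector with
    apex at ``apex`` (in-plane mm, (x, z)), bisector pointing superior (+z)
    and half-angle ``spec.half_angle_deg``.  The sector is radially
    unbounded within the slice.
    """
    apex = np.asarray(apex, dtype=float).reshape(2)
    h, w = slc.pixels.shape
    x = slc.origin_inplane[0] + np.arange(h) * slc.pixel_spacing[0]
    z = slc.origin_inplane[1] + np.arange(w) * slc.pixel_spacing[1]
    if not (x[0] - 0.5 * slc.pixel_spacing[0] <= apex[0] <= x[-1] + 0.5 * slc.pixel_spacing[0]
            and z[0] - 0.5 * slc.pixel_spacing[1] <= apex[1] <= z[-1] + 0.5 * slc.pixel_spacing[1]):
        raise ValueError("wedge apex lies outside the slice bounds")
    dx = (x - apex[0])[:, None]
    dz = (z - apex[1])[None, :]
    ang = np.degrees(np.arctan2(np.abs(dx), dz))  # 0 at +z, 180 at -z
    return ang <= spec.half_angle_deg
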