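"""Synthetic head phantoms with analytically known sulcal CSF volumes.

The phantom emulates the morphology the index targets: an ellipsoidal brain
carrying bilateral Sylvian-fissure CSF clefts (tilted rectangular slabs on
each lateral surface), radial high-convexity sulcal slits fanning out from
the AC-PC axis near the vertex, and optional ventricles.  A single
``desh_severity`` dial in [0, 1] simultaneously enlarges the Sylvian clefts
(linear dimensions scale with ``1 + s``) and tightens the convexity slits
(width scales with ``1 - s/2``), so the ground-truth index

    DESI(s) = V_sylvian(s) / V_superior_wedge(s)

is a strictly increasing, closed-form function of severity.

Every compartment is a half-open box or tilted slab whose edges avoid voxel
centres at the default spacing, so voxel-centre counts converge to the
analytic volumes as the grid is refined.  The convexity slits are placed
strictly inside the default 30-degree superior wedge, and two lateral
distractor slits strictly outside it, so the wedge-restricted superior
volume is exactly the summed volume of the inner slits.

Intensities follow a T1-like contrast (CSF dark): parenchyma 100, CSF 30,
background 5 (arbitrary units), plus Gaussian noise and an optional smooth
multiplicative bias field.  This is a contrast model, not an MRI physics
simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage

from .acpc import LandmarkSet
from .image_io import SliceImage2D, VolumeImage
from .masks import MultiLabelMask

PARENCHYMA_INTENSITY = 100.0
CSF_INTENSITY = 30.0
BACKGROUND_INTENSITY = 5.0


@dataclass
class PhantomSpec:
    """Geometry, contrast and severity parameters of one phantom subject."""

    brain_semi_axes: tuple = (65.0, 80.0, 60.0)   # mm, (x, y, z)
    spacing: tuple = (1.0, 1.0, 1.0)              # mm
    margin_mm: float = 6.0                        # air margin around the brain
    # landmarks at fixed fractional positions inside the brain ellipsoid;
    # the y fractions put the AC-PC slab off voxel centres at 1 mm spacing
    ac_frac: tuple = (0.0, 0.15375, -0.155)
    pc_frac: tuple = (0.0, -0.15875, -0.155)
    # Sylvian clefts: tilted rectangular slabs, one per hemisphere
    sylvian_width_mm: float = 8.0                 # base cleft opening (x)
    sylvian_height_mm: float = 20.0               # base cleft depth (z)
    sylvian_center_x_mm: float = 40.2
    sylvian_center_z_offset_mm: float = 8.0       # above the AC-PC plane
    sylvian_tilt_deg: float = 8.0                 # in-plane tilt, mirrored L/R
    # high-convexity sulci: radial slits about the AC-PC axis near the vertex
    n_convexity_sulci: int = 4
    slit_width_mm: float = 3.0                    # base slit width
    slit_r0_mm: float = 38.0                      # radial extent from the axis
    slit_r1_mm: float = 62.0
    convexity_span_deg: float = 11.0              # slits placed in +/- span
    n_lateral_slits: int = 2                      # distractors outside wedge
    lateral_slit_angle_deg: float = 24.0
    ventricle_scale: float = 1.0                  # 0 disables ventricles
    desh_severity: float = 0.0
    noise_sd: float = 4.0                         # intensity units
    bias_amplitude: float = 0.0                   # fractional, e.g. 0.2
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.desh_severity <= 1.0):
            raise ValueError("desh_severity must lie in [0, 1]")
        for v in (*self.brain_semi_axes, *self.spacing, self.sylvian_width_mm,
                  self.sylvian_height_mm, self.slit_r0_mm, self.slit_r1_mm):
            if v <= 0:
                raise ValueError("geometric parameters must be positive")
        if self.slit_width_mm < 0 or self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("widths, noise and bias amplitude must be >= 0")
        if self.slit_r1_mm <= self.slit_r0_mm:
            raise ValueError("slit_r1_mm must exceed slit_r0_mm")

    # --- severity-coupled effective dimensions -------------------------------
    @property
    def sylvian_scale(self) -> float:
        return 1.0 + self.desh_severity

    @property
    def slit_scale(self) -> float:
        return 1.0 - 0.5 * self.desh_severity

    @property
    def effective_sylvian_width(self) -> float:
        return self.sylvian_width_mm * self.sylvian_scale

    @property
    def effective_sylvian_height(self) -> float:
        return self.sylvian_height_mm * self.sylvian_scale

    @property
    def effective_slit_width(self) -> float:
        return self.slit_width_mm * self.slit_scale

    # --- landmark / slab geometry -------------------------------------------
    @property
    def landmarks(self) -> LandmarkSet:
        a = np.asarray(self.brain_semi_axes)
        return LandmarkSet(ac=np.asarray(self.ac_frac) * a,
                           pc=np.asarray(self.pc_frac) * a)

    @property
    def slab_y(self) -> tuple:
        """(pc_y, ac_y) in mm; all compartments span y in [pc_y, ac_y)."""
        lm = self.landmarks
        return float(lm.pc[1]), float(lm.ac[1])

    @property
    def slab_length_mm(self) -> float:
        lo, hi = self.slab_y
        return hi - lo

    @property
    def apex_xz(self) -> tuple:
        """In-plane (x, z) of the AC-PC axis, the wedge apex."""
        lm = self.landmarks
        return float(lm.ac[0]), float(lm.ac[2])

    def convexity_angles_deg(self) -> np.ndarray:
        """Angular positions of the inner (wedge-interior) slits."""
        n = self.n_convexity_sulci
        if n == 0:
            return np.array([])
        if n == 1:
            return np.array([0.0])
        return np.linspace(-self.convexity_span_deg, self.convexity_span_deg, n)

    def grid(self):
        """Symmetric voxel grid covering the brain plus margin."""
        semi = np.asarray(self.brain_semi_axes)
        sp = np.asarray(self.spacing)
        half = np.ceil((semi + self.margin_mm) / sp).astype(int)
        n = 2 * half + 1
        origin = -half * sp
        return n, origin

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for k in ("brain_semi_axes", "spacing", "ac_frac", "pc_frac"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground truth for one generated phantom."""

    landmarks: LandmarkSet
    analytic_sylvian_mm3: float
    analytic_superior_sulci_mm3: float
    analytic_suprasylvian_total_mm3: float
    analytic_desi: float                 # nan when undefined
    desi_defined: bool
    label_mask: MultiLabelMask = field(default=None, repr=False)


def analytic_truth(spec: PhantomSpec) -> PhantomTruth:
    """Closed-form compartment volumes; no voxelization involved.

    Sylvian volume: two tilted rectangular slabs, w*h per coronal plane times
    the slab length.  Superior (wedge) volume: the inner radial slits, each
    w*(r1-r0) per plane; the lateral distractor slits add to the total
    suprasylvian volume but lie outside the wedge by construction.
    """
    L = spec.slab_length_mm
    syl = 2.0 * spec.effective_sylvian_width * spec.effective_sylvian_height * L
    slit_each = spec.effective_slit_width * (spec.slit_r1_mm - spec.slit_r0_mm) * L
    wedge = spec.n_convexity_sulci * slit_each
    supra_total = (spec.n_convexity_sulci + spec.n_lateral_slits) * slit_each
    defined = wedge > 0
    desi = syl / wedge if defined else float("nan")
    return PhantomTruth(
        landmarks=spec.landmarks,
        analytic_sylvian_mm3=syl,
        analytic_superior_sulci_mm3=wedge,
        analytic_suprasylvian_total_mm3=supra_total,
        analytic_desi=desi,
        desi_defined=defined,
    )


# --- compartment membership on broadcastable mm coordinates ------------------

def _sylvian_membership(spec: PhantomSpec, X, Y, Z, side: int):
    """side=+1 right hemisphere (x>0), -1 left."""
    y0, y1 = spec.slab_y
    cx = side * spec.sylvian_center_x_mm
    cz = spec.landmarks.ac[2] + spec.sylvian_center_z_offset_mm
    t = math.radians(side * spec.sylvian_tilt_deg)
    u = (X - cx) * math.cos(t) - (Z - cz) * math.sin(t)
    v = (X - cx) * math.sin(t) + (Z - cz) * math.cos(t)
    w = spec.effective_sylvian_width
    h = spec.effective_sylvian_height
    return ((-w / 2 <= u) & (u < w / 2) & (-h / 2 <= v) & (v < h / 2)
            & (y0 <= Y) & (Y < y1))


def _slit_membership(spec: PhantomSpec, X, Y, Z, angle_deg: float):
    """Radial slit at the given angle from vertical, about the AC-PC axis."""
    y0, y1 = spec.slab_y
    x0, z0 = spec.apex_xz
    a = math.radians(angle_deg)
    u = (X - x0) * math.cos(a) - (Z - z0) * math.sin(a)   # across the slit
    v = (X - x0) * math.sin(a) + (Z - z0) * math.cos(a)   # radial
    w = spec.effective_slit_width
    if w <= 0:
        return np.zeros(np.broadcast_shapes(np.shape(X), np.shape(Y), np.shape(Z)),
                        dtype=bool)
    return ((-w / 2 <= u) & (u < w / 2)
            & (spec.slit_r0_mm <= v) & (v < spec.slit_r1_mm)
            & (y0 <= Y) & (Y < y1))


def _ventricle_membership(spec: PhantomSpec, X, Y, Z):
    if spec.ventricle_scale <= 0:
        return np.zeros(np.broadcast_shapes(np.shape(X), np.shape(Y), np.shape(Z)),
                        dtype=bool)
    va, vb, vc = 7.0, 22.0, 8.0
    s = spec.ventricle_scale
    out = None
    for side in (-1, 1):
        m = (((X - side * 14.0) / (va * s)) ** 2 + ((Y - 0.0) / (vb * s)) ** 2
             + ((Z - 2.0) / (vc * s)) ** 2) <= 1.0
        out = m if out is None else (out | m)
    return out


def _evaluate(spec: PhantomSpec, X, Y, Z):
    """Clean intensity and label image on broadcastable mm coordinates."""
    a = np.asarray(spec.brain_semi_axes)
    brain = (X / a[0]) ** 2 + (Y / a[1]) ** 2 + (Z / a[2]) ** 2 <= 1.0
    left = _sylvian_membership(spec, X, Y, Z, side=-1)
    right = _sylvian_membership(spec, X, Y, Z, side=+1)
    supra = np.zeros_like(left)
    for ang in spec.convexity_angles_deg():
        supra |= _slit_membership(spec, X, Y, Z, ang)
    for k in range(spec.n_lateral_slits):
        side = -1 if k % 2 else 1
        supra |= _slit_membership(spec, X, Y, Z,
                                  side * spec.lateral_slit_angle_deg)
    vent = _ventricle_membership(spec, X, Y, Z)

    labels = np.zeros(brain.shape, dtype=np.uint8)
    labels[left] = 1
    labels[right] = 2
    labels[supra & ~left & ~right] = 3

    csf = left | right | supra | vent
    intensity = np.full(brain.shape, BACKGROUND_INTENSITY, dtype=np.float32)
    intensity[brain] = PARENCHYMA_INTENSITY
    intensity[csf] = CSF_INTENSITY
    return intensity, labels


def _bias_field(shape, amplitude: float, rng) -> np.ndarray:
    """Smooth multiplicative field 1 +/- amplitude from a coarse random grid."""
    coarse = rng.standard_normal((3,) * len(shape))
    zoom = [s / 3 for s in shape]
    f = ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
    f = f[tuple(slice(0, s) for s in shape)]
    peak = np.max(np.abs(f))
    if peak > 0:
        f = f / peak
    return 1.0 + amplitude * f


def generate_phantom(spec: PhantomSpec):
    """Voxelize a phantom: (intensity volume, ground truth).

    Deterministic given ``spec.seed``.  Voxel membership is by voxel centre
    on a grid symmetric about the head centre, so mirrored compartments
    voxelize identically on both sides.
    """
    n, origin = spec.grid()
    sp = np.asarray(spec.spacing)
    x = (origin[0] + np.arange(n[0]) * sp[0])[:, None, None]
    y = (origin[1] + np.arange(n[1]) * sp[1])[None, :, None]
    z = (origin[2] + np.arange(n[2]) * sp[2])[None, None, :]
    intensity, labels = _evaluate(spec, x, y, z)

    rng = np.random.default_rng(spec.seed)
    if spec.bias_amplitude > 0:
        intensity = intensity * _bias_field(intensity.shape,
                                            spec.bias_amplitude, rng)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd,
                                           intensity.size).reshape(intensity.shape)
    intensity = np.maximum(intensity, 0.0).astype(np.float32)

    affine = np.eye(4)
    affine[:3, :3] = np.diag(sp)
    affine[:3, 3] = origin
    vol = VolumeImage(intensity, affine)
    truth = analytic_truth(spec)
    truth.label_mask = MultiLabelMask.from_labels(
        labels, spacing=tuple(sp), origin=tuple(origin))
    return vol, truth


def phantom_slice(spec: PhantomSpec, y_mm: float, rng=None):
    """One clean-geometry coronal slice with its ground-truth mask.

    Evaluates the phantom directly on the (x, z) plane at ``y_mm`` —
    no 3D voxelization — and applies noise/bias in-plane.
    """
    n, origin = spec.grid()
    sp = np.asarray(spec.spacing)
    x = (origin[0] + np.arange(n[0]) * sp[0])[:, None]
    z = (origin[2] + np.arange(n[2]) * sp[2])[None, :]
    intensity, labels = _evaluate(spec, x, float(y_mm), z)
    if rng is not None:
        if spec.bias_amplitude > 0:
            intensity = intensity * _bias_field(intensity.shape,
                                                spec.bias_amplitude, rng)
        if spec.noise_sd > 0:
            intensity = intensity + rng.normal(
                0.0, spec.noise_sd, intensity.size).reshape(intensity.shape)
    j = int(round((y_mm - origin[1]) / sp[1]))
    slc = SliceImage2D(np.maximum(intensity, 0.0).astype(np.float32),
                       pixel_spacing=(sp[0], sp[2]), slice_position=j,
                       origin_inplane=(origin[0], origin[2]))
    mask = MultiLabelMask.from_labels(labels, spacing=(sp[0], sp[2]),
                                      origin=(origin[0], origin[2]))
    return slc, mask


def make_training_set(specs, slices_per_phantom: int = 2, seed: int = 0):
    """Sample paired (slice, mask) training data from a list of phantoms.

    Coronal planes are drawn uniformly (without replacement where possible)
    from each phantom's AC-PC slab; each pair keeps its subject index so
    train/validation splits can be made at the subject level.

    Returns a list of ``{"slice", "mask", "subject"}`` records.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one phantom spec")
    rng = np.random.default_rng(seed)
    records = []
    for subject, spec in enumerate(specs):
        n, origin = spec.grid()
        sy = spec.spacing[1]
        y0, y1 = spec.slab_y
        planes = origin[1] + np.arange(n[1]) * sy
        candidates = planes[(planes >= y0) & (planes < y1)]
        if candidates.size == 0:
            raise ValueError("empty AC-PC slab for phantom spec")
        k = min(slices_per_phantom, candidates.size)
        chosen = rng.choice(candidates, size=k,
                            replace=slices_per_phantom > candidates.size)
        for y in np.sort(chosen):
            slc, mask = phantom_slice(spec, float(y), rng=rng)
            records.append({"slice": slc, "mask": mask, "subject": subject})
    return records


def subject_split(records, train_fraction: float = 0.8, seed: int = 0):
    """Split records into subject-disjoint train/validation partitions."""
    subjects = sorted({r["subject"] for r in records})
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    n_train = max(1, int(round(train_fraction * len(subjects))))
    if len(subjects) > 1:
        n_train = min(n_train, len(subjects) - 1)
    train_subj = {subjects[i] for i in perm[:n_train]}
    train = [r for r in records if r["subject"] in train_subj]
    val = [r for r in records if r["subject"] not in train_subj]
    return train, val


def pitch_phantom(vol: VolumeImage, lm: LandmarkSet, degrees: float,
                  interpolation: str = "linear"):
    """Rotate a volume (and its landmarks) about the left-right axis.

    Emulates a head scanned with nose-up/nose-down pitch: the data are
    resampled on the same axis-aligned grid (so the result stays RAS) and
    the landmark coordinates are rotated identically, about the AC.  Use
    ``interpolation='nearest'`` for label volumes.
    """
    a = math.radians(degrees)
    R = np.array([[1, 0, 0],
                  [0, math.cos(a), -math.sin(a)],
                  [0, math.sin(a), math.cos(a)]])
    c = np.asarray(lm.ac, dtype=float)
    A = vol.affine[:3, :3]
    t = vol.affine[:3, 3]
    Ainv = np.linalg.inv(A)
    # output voxel o -> input voxel i: undo the rotation about c
    M = Ainv @ R.T @ A
    off = Ainv @ (R.T @ (t - c) + c - t)
    order = {"linear": 1, "nearest": 0}[interpolation]
    data = ndimage.affine_transform(
        vol.voxels.astype(np.float32 if order else vol.voxels.dtype),
        M, offset=off, order=order, mode="constant", cval=0.0, prefilter=False)
    lm_rot = LandmarkSet(ac=R @ (lm.ac - c) + c, pc=R @ (lm.pc - c) + c)
    return VolumeImage(data, vol.affine.copy()), lm_rot


def severity_grid_specs(severities, base: PhantomSpec = None, seed: int = 0):
    """Phantom specs differing only in severity (and seed)."""
    base = base or PhantomSpec()
    return [replace(base, desh_severity=float(s), seed=seed + i)
            for i, s in enumerate(severities)]
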