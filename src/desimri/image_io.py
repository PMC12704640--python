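"""Volumetric image I/O, RAS enforcement and intensity preprocessing.

NIfTI reading and writing go through nibabel.  All physical coordinates in
this package are millimetres in the RAS convention (x increases to the
subject's right, y anterior, z superior); :func:`reorient_to_ras` brings any
axis-aligned volume into that frame by axis permutation and flips only, so
voxel values are rearranged but never resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from skimage.transform import resize as _sk_resize


@dataclass
class VolumeImage:
    """A 3D scalar grid with its physical placement.

    ``voxels[i, j, k]`` sits at physical position ``affine @ (i, j, k, 1)``.
    A voxel occupies the cube centred on its grid point; membership tests
    throughout the package use the voxel centre.
    """

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.voxels.ndim}D data; "
                "4D inputs (e.g. time series) are not supported"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")
        if np.any(self.spacing <= 0) or not np.all(np.isfinite(self.spacing)):
            raise ValueError("voxel spacing must be positive and finite")

    @property
    def spacing(self) -> np.ndarray:
        """mm per voxel step along each grid axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        """Physical position (mm) of voxel (0, 0, 0)."""
        return self.affine[:3, 3].copy()

    @property
    def orientation(self) -> str:
        """Axis-code triple, e.g. 'RAS' or 'LPS'."""
        return "".join(nib.orientations.aff2axcodes(self.affine))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def index_to_mm(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return (self.affine[:3, :3] @ idx.T).T + self.affine[:3, 3]

    def mm_to_index(self, mm) -> np.ndarray:
        mm = np.asarray(mm, dtype=float)
        inv = np.linalg.inv(self.affine[:3, :3])
        return (inv @ (mm - self.affine[:3, 3]).T).T


@dataclass
class SliceImage2D:
    """One coronal slice of an AC-PC-aligned volume.

    Pixel axis 0 runs along x (right), axis 1 along z (superior).
    ``resize_record`` is populated by :func:`resize_to_model` and maps the
    model grid back to the native grid.
    """

    pixels: np.ndarray
    pixel_spacing: tuple
    slice_position: int = 0
    origin_inplane: tuple = (0.0, 0.0)
    resize_record: dict = field(default=None)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be 2D")
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing must be positive")
        self.origin_inplane = tuple(float(v) for v in self.origin_inplane)


def read_volume(path) -> VolumeImage:
    """Read a 3D NIfTI image; header geometry is kept, nothing is resampled."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 3 else data
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D image, found {data.ndim} dimensions"
        )
    return VolumeImage(voxels=data, affine=np.asarray(img.affine))


def write_volume(vol: VolumeImage, path) -> None:
    """Write a volume as NIfTI-1; integer arrays are stored as integer types."""
    data = vol.voxels
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def reorient_to_ras(vol: VolumeImage, tol: float = 1e-3) -> VolumeImage:
    """Permute/flip grid axes so the volume is in RAS.

    Pure axis rearrangement: the multiset of voxel values and each voxel's
    physical position are unchanged.  Oblique volumes (direction cosines not
    aligned with the physical axes beyond ``tol``) are rejected — rigidly
    resample those first (see :func:`desimri.acpc.resample_to_acpc`).
    """
    R = vol.affine[:3, :3] / vol.spacing
    if np.max(np.abs(np.abs(R) - np.round(np.abs(R)))) > tol:
        raise ValueError(
            "volume is oblique (direction cosines are not axis-aligned); "
            "rigidly resample to an axis-aligned grid before RAS reorientation"
        )
    ornt = nib.orientations.io_orientation(vol.affine)
    target = nib.orientations.axcodes2ornt(("R", "A", "S"))
    xform = nib.orientations.ornt_transform(ornt, target)
    data = nib.orientations.apply_orientation(vol.voxels, xform)
    affine = vol.affine @ nib.orientations.inv_ornt_aff(xform, vol.voxels.shape)
    return VolumeImage(voxels=data, affine=affine)


def correct_bias_field(vol: VolumeImage, smoothness: int = 3,
                       shrink_factor: int = 4) -> VolumeImage:
    """Estimate and divide out a smooth multiplicative intensity field (N4).

    Delegates to the N4 bias-field algorithm (SimpleITK).  ``smoothness`` is
    the number of multi-resolution fitting levels of the B-spline field —
    more levels allow a less smooth field.  The contract is corrective, not
    generative: within any uniform-tissue region the coefficient of variation
    must not increase.
    """
    if np.any(vol.voxels < 0):
        raise ValueError("bias correction expects nonnegative intensities")
    if not np.any(vol.voxels > 0):
        raise ValueError("cannot bias-correct an all-zero volume")
    arr = np.ascontiguousarray(vol.voxels.astype(np.float32))
    img = sitk.GetImageFromArray(np.transpose(arr, (2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    shrink = [max(1, int(shrink_factor))] * 3
    small = sitk.Shrink(img, shrink)
    mask = sitk.Cast(small > 0, sitk.sitkUInt8)
    corr = sitk.N4BiasFieldCorrectionImageFilter()
    corr.SetMaximumNumberOfIterations([30] * max(1, int(smoothness)))
    corr.Execute(small, mask)
    log_field = sitk.GetArrayFromImage(corr.GetLogBiasFieldAsImage(img))
    field = np.exp(np.transpose(log_field, (2, 1, 0)))
    out = arr / np.maximum(field, 1e-6)
    return VolumeImage(voxels=out.astype(vol.voxels.dtype, copy=False)
                       if np.issubdtype(vol.voxels.dtype, np.floating) else out,
                       affine=vol.affine.copy())


def zscore_normalize(slc: SliceImage2D) -> SliceImage2D:
    """Standardize a slice to zero mean, unit variance.

    Invariant under affine intensity changes a*x + b (a > 0).  A constant
    slice (blank edge of the slab) yields all zeros with a warning rather
    than aborting the run.
    """
    px = slc.pixels.astype(np.float64)
    sd = px.std()
    if sd == 0:
        warnings.warn("constant slice: z-score normalization returns zeros")
        out = np.zeros_like(px)
    else:
        out = (px - px.mean()) / sd
    return SliceImage2D(out, slc.pixel_spacing, slc.slice_position,
                        slc.origin_inplane, slc.resize_record)


def resize_to_model(slc: SliceImage2D, size: int = 224) -> SliceImage2D:
    """Resize a native slice to the square model grid (default 224x224).

    Intensities are linearly interpolated; the record stores the native
    dimensions and per-axis scale factors so masks predicted on the model
    grid can be mapped back with :func:`map_mask_to_native`.
    """
    h, w = slc.pixels.shape
    if h < 2 or w < 2:
        raise ValueError("cannot resize a degenerate (single-pixel-axis) slice")
    out = _sk_resize(slc.pixels.astype(np.float64), (size, size), order=1,
                     preserve_range=True, anti_aliasing=(h > size or w > size))
    record = {
        "native_shape": (h, w),
        "model_shape": (size, size),
        "scale": (h / size, w / size),
    }
    return SliceImage2D(out, slc.pixel_spacing, slc.slice_position,
                        slc.origin_inplane, record)


def map_mask_to_native(mask224: np.ndarray, record: dict) -> np.ndarray:
    """Map model-grid mask channels back to the native slice grid.

    Nearest-neighbour mapping so masks stay binary and the label set is
    preserved.  ``mask224`` is ``(C, s, s)`` or ``(s, s)`` boolean.
    """
    mask224 = np.asarray(mask224)
    squeeze = mask224.ndim == 2
    if squeeze:
        mask224 = mask224[None]
    if tuple(mask224.shape[1:]) != tuple(record["model_shape"]):
        raise ValueError("mask shape does not match the resize record")
    h, w = record["native_shape"]
    out = np.empty((mask224.shape[0], h, w), dtype=bool)
    # nearest-neighbour index map, consistent with skimage's grid convention
    ii = np.clip(((np.arange(h) + 0.5) * record["model_shape"][0] / h - 0.5)
                 .round().astype(int), 0, record["model_shape"][0] - 1)
    jj = np.clip(((np.arange(w) + 0.5) * record["model_shape"][1] / w - 0.5)
                 .round().astype(int), 0, record["model_shape"][1] - 1)
    for c in range(mask224.shape[0]):
        out[c] = mask224[c][np.ix_(ii, jj)]
    return out[0] if squeeze else out
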