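"""On-the-fly training augmentation for slice/mask pairs.

Geometric transforms (random rotation up to +/-15 degrees, random zoom-crop
to 80-100% of the original field of view) are applied identically to the
image (linear interpolation) and every mask channel (nearest neighbour), so
the pair stays aligned.  Photometric transforms (Gaussian blur, additive
noise, coarse dropout) touch the image only.  All randomness comes from the
caller's generator, so a fixed RNG state reproduces the augmentation
exactly, and zero magnitudes give the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class AugmentConfig:
    rotation_deg: float = 15.0          # rotation drawn from +/- this bound
    scale_min: float = 0.80             # zoom-crop keeps this..scale_max of FOV
    scale_max: float = 1.00
    coarse_dropout: bool = True
    blur: bool = True
    noise: bool = True
    mirror: bool = True                 # random L/R flip, swapping the paired
    mirror_swap: tuple = (0, 1)         # (left, right) mask channels
    blur_sigma_max: float = 1.2         # px
    noise_sd_max: float = 0.10          # on standardized intensities
    dropout_max_holes: int = 4
    dropout_max_frac: float = 0.12      # hole side as fraction of image side

    def __post_init__(self):
        self.mirror_swap = tuple(self.mirror_swap)
        if self.rotation_deg < 0:
            raise ValueError("rotation bound must be >= 0")
        if not (0 < self.scale_min <= self.scale_max <= 1.0):
            raise ValueError("scale range must satisfy 0 < min <= max <= 1")


def _geometric(image, mask, angle_deg, scale, order_img=1):
    """Shared rotation + zoom-crop about the image centre."""
    h, w = image.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    a = np.radians(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    # output->input map: crop to `scale` of the FOV then rotate
    m = rot * scale
    off = c - m @ c
    img_out = ndimage.affine_transform(image, m, offset=off, order=order_img,
                                       mode="nearest")
    mask_out = np.stack([
        ndimage.affine_transform(ch.astype(np.float32), m, offset=off,
                                 order=0, mode="constant", cval=0.0) > 0.5
        for ch in mask])
    return img_out, mask_out


def augment(image: np.ndarray, mask: np.ndarray, cfg: AugmentConfig, rng):
    """Augment one (image, mask-channels) pair; returns new arrays.

    ``image`` is (H, W); ``mask`` is (C, H, W) boolean.  The same geometric
    transform is applied to both; photometric ops apply to the image only.
    """
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask).astype(bool)
    if mask.shape[1:] != image.shape:
        raise ValueError("image and mask grids differ")

    if cfg.mirror and rng.random() < 0.5:
        # anatomy is mirror-symmetric across the midline: flip the x axis
        # and swap the side-paired label channels so both sides see the
        # same training statistics
        image = image[::-1, :]
        mask = mask[:, ::-1, :].copy()
        a, b = cfg.mirror_swap
        if max(a, b) < mask.shape[0]:
            mask[[a, b]] = mask[[b, a]]

    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg) if cfg.rotation_deg else 0.0
    scale = rng.uniform(cfg.scale_min, cfg.scale_max)
    if angle != 0.0 or scale != 1.0:
        image, mask = _geometric(image, mask, angle, scale)
    else:
        image, mask = image.copy(), mask.copy()

    if cfg.blur:
        sigma = rng.uniform(0.0, cfg.blur_sigma_max)
        if sigma > 1e-3:
            image = ndimage.gaussian_filter(image, sigma)
    if cfg.noise:
        sd = rng.uniform(0.0, cfg.noise_sd_max)
        if sd > 0:
            image = image + rng.normal(0.0, sd, image.shape).astype(np.float32)
    if cfg.coarse_dropout:
        n_holes = rng.integers(0, cfg.dropout_max_holes + 1)
        h, w = image.shape
        for _ in range(n_holes):
            hh = max(1, int(rng.uniform(0.02, cfg.dropout_max_frac) * h))
            ww = max(1, int(rng.uniform(0.02, cfg.dropout_max_frac) * w))
            r = rng.integers(0, h - hh + 1)
            c = rng.integers(0, w - ww + 1)
            image[r:r + hh, c:c + ww] = 0.0
    return image.astype(np.float32), mask
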