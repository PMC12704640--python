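"""Trainable multi-label sulcal segmenter with an sklearn-style front end.

The model is a small 2D encoder-decoder (skip connections, four per-pixel
logits: left Sylvian, right Sylvian, suprasylvian, auxiliary background)
run on coronal slices resized to a square model grid (default 224x224) and
standardized to zero mean / unit variance.  Channel-wise sigmoids give
independent probability maps, thresholded at p >= 0.5 (ties are
foreground).  Training minimizes a composite soft-Dice + Hausdorff-
surrogate loss with AdamW (weight decay 0.02), on-the-fly augmentation and
a subject-level 80/20 train/validation split; the best-validation weights
are kept.

Two encoder presets are provided: ``small-random``, a narrow randomly
initialized network suitable for CPU-scale training, and
``efficientnet-b0-style``, a much wider variant of the same topology for
use when compute allows.  No pretrained weights are required by either.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ..acpc import coronal_slices_between
from ..image_io import SliceImage2D, map_mask_to_native, resize_to_model, zscore_normalize
from ..masks import LABEL_NAMES, MultiLabelMask
from .augment import AugmentConfig, augment
from .losses import composite_loss_and_grad, soft_dice_loss
from .nn import AdamW, UNet2D, sigmoid

PRESET_WIDTHS = {"small-random": 6, "efficientnet-b0-style": 24}


@dataclass
class SegmentationConfig:
    """All knobs of the segmenter, with the published defaults."""

    input_size: int = 224
    out_channels: int = 4
    prob_threshold: float = 0.5
    dice_weight: float = 1.0
    hausdorff_weight: float = 0.5
    learning_rate: float = 5e-3
    weight_decay: float = 0.02
    max_epochs: int = 100
    batch_size: int = 4
    patience: int = 5
    encoder_preset: str = "small-random"
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    split_fraction: float = 0.80
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must lie in (0, 1)")
        if self.max_epochs > 100:
            raise ValueError("max_epochs is capped at 100")
        if self.encoder_preset not in PRESET_WIDTHS:
            raise ValueError(f"unknown encoder preset {self.encoder_preset!r}")
        if self.input_size % 4:
            raise ValueError("input_size must be divisible by 4")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        d = dict(d)
        aug = d.pop("augmentation", None)
        cfg = cls(**d)
        if aug is not None:
            cfg.augmentation = AugmentConfig(**aug)
        return cfg


def build_model(cfg: SegmentationConfig) -> UNet2D:
    """Construct the encoder-decoder for a config (deterministic per seed).

    The input carries the intensity plane plus two normalized coordinate
    planes.  Convolutions are translation-equivariant, so without an
    absolute position signal a compact network cannot tell the left from
    the right Sylvian channel; the coordinate planes provide it (the same
    role a very deep encoder's global receptive field plays).
    """
    return UNet2D(in_channels=3, out_channels=cfg.out_channels,
                  base_width=PRESET_WIDTHS[cfg.encoder_preset], seed=cfg.seed,
                  slim_level1=cfg.encoder_preset == "small-random")


def with_coord_channels(img: np.ndarray) -> np.ndarray:
    """Stack (intensity, x_norm, z_norm) planes; coords span [-1, 1]."""
    h, w = img.shape
    xx = np.linspace(-1.0, 1.0, h, dtype=np.float32)[:, None] * np.ones((1, w), np.float32)
    zz = np.ones((h, 1), np.float32) * np.linspace(-1.0, 1.0, w, dtype=np.float32)[None, :]
    return np.stack([img.astype(np.float32), xx, zz])


# --- data preparation --------------------------------------------------------

def _resize_mask_channels(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour resize of (C, H, W) boolean channels to size x size."""
    c, h, w = mask.shape
    ii = np.clip(((np.arange(size) + 0.5) * h / size - 0.5).round().astype(int), 0, h - 1)
    jj = np.clip(((np.arange(size) + 0.5) * w / size - 0.5).round().astype(int), 0, w - 1)
    return mask[:, ii][:, :, jj]


def prepare_pair(slc, mask, cfg: SegmentationConfig):
    """Resize + standardize a native (slice, mask) pair onto the model grid."""
    if isinstance(slc, SliceImage2D):
        prepped = zscore_normalize(resize_to_model(slc, cfg.input_size))
        img = prepped.pixels.astype(np.float32)
    else:
        img = np.asarray(slc, dtype=np.float32)
        if img.shape != (cfg.input_size, cfg.input_size):
            raise ValueError("bare arrays must already be on the model grid")
    if mask is None:
        return img, None
    ch = mask.channels if isinstance(mask, MultiLabelMask) else np.asarray(mask)
    ch = ch.astype(bool)
    if ch.shape[0] != cfg.out_channels:
        raise ValueError("mask channel count does not match out_channels")
    if ch.shape[1:] != (cfg.input_size, cfg.input_size):
        ch = _resize_mask_channels(ch, cfg.input_size)
    return img, ch


def _as_pairs(data):
    """Normalize training data to (slice, mask, subject) triples."""
    out = []
    for i, item in enumerate(data):
        if isinstance(item, dict):
            out.append((item["slice"], item["mask"], item.get("subject", i)))
        else:
            slc, mask = item
            out.append((slc, mask, i))
    return out


# --- training ----------------------------------------------------------------

def _forward_probs(model, imgs, batch_size=8):
    probs = []
    for i in range(0, len(imgs), batch_size):
        x = np.stack([with_coord_channels(im) for im in imgs[i:i + batch_size]])
        probs.append(sigmoid(model.forward(x)))
    return np.concatenate(probs) if probs else np.empty((0,))


def _val_metrics(model, imgs, masks, cfg):
    p = _forward_probs(model, imgs, cfg.batch_size * 2)
    t = np.stack(masks)
    loss, dice_l, hd_l, _ = composite_loss_and_grad(
        np.log(np.clip(p, 1e-6, 1 - 1e-6) / np.clip(1 - p, 1e-6, 1)),
        t, cfg.dice_weight, cfg.hausdorff_weight, cfg.prob_threshold)
    per_label = {}
    for c, name in enumerate(LABEL_NAMES[:p.shape[1]]):
        per_label[f"val_dice_{name}"] = 1.0 - soft_dice_loss(p[:, c:c + 1], t[:, c:c + 1])
    return loss, per_label


def train_model(model: UNet2D, train_pairs, val_pairs, cfg: SegmentationConfig,
                verbose: bool = False, stop_at_val_dice: float = None,
                stop_channels=("left_sylvian", "right_sylvian")):
    """Train on (slice, mask) pairs; returns (model, history).

    ``train_pairs``/``val_pairs`` are sequences of ``(slice, mask)`` tuples
    or ``{"slice", "mask", "subject"}`` records; the two sets must come
    from disjoint subjects (asserted when subject ids are present).
    History is a DataFrame with per-epoch train/validation loss and
    per-label validation soft Dice.  The weights of the best validation
    epoch are restored before returning.
    """
    train_pairs, val_pairs = _as_pairs(train_pairs), _as_pairs(val_pairs)
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must be nonempty")
    tr_subj = {s for _, _, s in train_pairs}
    va_subj = {s for _, _, s in val_pairs}
    if tr_subj & va_subj:
        raise ValueError("train/validation subjects overlap (split leakage)")

    tr = [prepare_pair(s, m, cfg) for s, m, _ in train_pairs]
    va = [prepare_pair(s, m, cfg) for s, m, _ in val_pairs]
    va_imgs = [im for im, _ in va]
    va_masks = [mk for _, mk in va]

    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.params(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)
    # linear warmup over the first epoch: Adam's earliest steps are full-size
    # regardless of gradient scale and can drive every sigmoid channel into
    # the saturated-empty regime before any feature has formed
    warmup_iters = max(1, (len(tr) + cfg.batch_size - 1) // cfg.batch_size)
    step_no = 0
    history = []
    best = (np.inf, model.get_weights())
    stale = 0
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(tr))
        tr_loss = 0.0
        nb = 0
        for start in range(0, len(tr), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xs, ts = [], []
            for i in idx:
                img, msk = tr[i]
                img_a, msk_a = augment(img, msk, cfg.augmentation, rng)
                xs.append(img_a)
                ts.append(msk_a)
            x = np.stack([with_coord_channels(im) for im in xs])
            t = np.stack(ts)
            logits = model.forward(x)
            total, _, _, dlog = composite_loss_and_grad(
                logits, t, cfg.dice_weight, cfg.hausdorff_weight,
                cfg.prob_threshold)
            model.zero_grad()
            model.backward(dlog)
            step_no += 1
            opt.lr = cfg.learning_rate * min(1.0, step_no / warmup_iters)
            opt.step()
            tr_loss += total
            nb += 1
        val_loss, per_label = _val_metrics(model, va_imgs, va_masks, cfg)
        row = {"epoch": epoch, "train_loss": tr_loss / max(nb, 1),
               "val_loss": val_loss, **per_label}
        history.append(row)
        if verbose:
            print("epoch {epoch:3d} train {train_loss:.4f} val {val_loss:.4f} "
                  "dice L {val_dice_left_sylvian:.3f} R {val_dice_right_sylvian:.3f} "
                  "S {val_dice_suprasylvian:.3f}".format(**row), flush=True)
        if val_loss < best[0] - 1e-5:
            best = (val_loss, model.get_weights())
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
        if stop_at_val_dice is not None and all(
                row[f"val_dice_{ch}"] >= stop_at_val_dice
                for ch in stop_channels):
            # converged for the monitored channels; keep the current weights,
            # which achieved the target, rather than an earlier best-loss state
            best = (val_loss, model.get_weights())
            break
    model.set_weights(best[1])
    return model, pd.DataFrame(history)


# --- inference ---------------------------------------------------------------

def predict_slice(model: UNet2D, slc, cfg: SegmentationConfig) -> MultiLabelMask:
    """Segment one prepared slice; per-channel threshold at p >= prob_threshold.

    The returned mask lives on the model grid and includes the auxiliary
    background channel, which downstream volumetry ignores.
    """
    img, _ = prepare_pair(slc, None, cfg)
    probs = sigmoid(model.forward(with_coord_channels(img)[None]))[0]
    mask = probs >= cfg.prob_threshold
    spacing = slc.pixel_spacing if isinstance(slc, SliceImage2D) else (1.0, 1.0)
    return MultiLabelMask(mask, spacing=spacing)


def segment_volume(model: UNet2D, vol_aligned, lm, cfg: SegmentationConfig,
                   batch_size: int = 8) -> MultiLabelMask:
    """Segment every AC-PC slab slice and stack the results into 3D masks.

    Each slice is resized to the model grid, standardized, segmented, and
    mapped back to the native grid (nearest neighbour); planes outside the
    slab stay empty.  The output is registered to ``vol_aligned``.
    """
    slices = coronal_slices_between(vol_aligned, lm)
    nx, ny, nz = vol_aligned.voxels.shape
    out = np.zeros((cfg.out_channels, nx, ny, nz), dtype=bool)
    prepped = []
    for slc in slices:
        rs = resize_to_model(slc, cfg.input_size)
        prepped.append((zscore_normalize(rs).pixels.astype(np.float32),
                        rs.resize_record, slc.slice_position))
    for i in range(0, len(prepped), batch_size):
        chunk = prepped[i:i + batch_size]
        x = np.stack([with_coord_channels(im) for im, _, _ in chunk])
        probs = sigmoid(model.forward(x))
        for (im, record, j), pr in zip(chunk, probs):
            native = map_mask_to_native(pr >= cfg.prob_threshold, record)
            out[:, :, j, :] = native
    return MultiLabelMask(out, spacing=tuple(vol_aligned.spacing),
                          origin=tuple(vol_aligned.origin))


# --- checkpoints -------------------------------------------------------------

def save_checkpoint(model: UNet2D, cfg: SegmentationConfig, path) -> None:
    """Persist weights + config; loadable with :func:`load_checkpoint`."""
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, config=json.dumps(cfg.to_dict()), **arrays)


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as data:
        cfg = SegmentationConfig.from_dict(json.loads(str(data["config"])))
        model = build_model(cfg)
        n = len(model.get_weights())
        model.set_weights([data[f"w{i}"] for i in range(n)])
    return model, cfg


# --- sklearn front end -------------------------------------------------------

class SulcalSegmenter(BaseEstimator):
    """Sklearn-style wrapper around the slice segmenter.

    ``fit`` takes training records (``{"slice", "mask", "subject"}`` dicts
    or (slice, mask) tuples) and performs the subject-level 80/20 split
    internally unless a validation set is supplied.  Fitted attributes:
    ``model_``, ``history_``, ``n_parameters_``, ``best_val_loss_``.
    """

    def __init__(self, input_size=224, prob_threshold=0.5, dice_weight=1.0,
                 hausdorff_weight=0.5, learning_rate=5e-3, weight_decay=0.02,
                 max_epochs=100, batch_size=4, patience=5,
                 encoder_preset="small-random", rotation_deg=15.0,
                 scale_min=0.80, scale_max=1.00, coarse_dropout=True,
                 blur=True, noise=True, split_fraction=0.80, random_state=0):
        self.input_size = input_size
        self.prob_threshold = prob_threshold
        self.dice_weight = dice_weight
        self.hausdorff_weight = hausdorff_weight
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.encoder_preset = encoder_preset
        self.rotation_deg = rotation_deg
        self.scale_min = scale_min
        self.scale_max = scale_max
        self.coarse_dropout = coarse_dropout
        self.blur = blur
        self.noise = noise
        self.split_fraction = split_fraction
        self.random_state = random_state

    def _config(self) -> SegmentationConfig:
        return SegmentationConfig(
            input_size=self.input_size, prob_threshold=self.prob_threshold,
            dice_weight=self.dice_weight, hausdorff_weight=self.hausdorff_weight,
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            max_epochs=self.max_epochs, batch_size=self.batch_size,
            patience=self.patience, encoder_preset=self.encoder_preset,
            augmentation=AugmentConfig(
                rotation_deg=self.rotation_deg, scale_min=self.scale_min,
                scale_max=self.scale_max, coarse_dropout=self.coarse_dropout,
                blur=self.blur, noise=self.noise),
            split_fraction=self.split_fraction, seed=self.random_state)

    def fit(self, X, y=None, validation=None):
        from ..phantom import subject_split

        cfg = self._config()
        if validation is None:
            records = [it if isinstance(it, dict)
                       else {"slice": it[0], "mask": it[1], "subject": i}
                       for i, it in enumerate(X)]
            train, val = subject_split(records, cfg.split_fraction, cfg.seed)
        else:
            train, val = X, validation
        model = build_model(cfg)
        self.model_, self.history_ = train_model(model, train, val, cfg)
        self.n_parameters_ = self.model_.n_parameters
        self.best_val_loss_ = float(self.history_["val_loss"].min())
        return self

    def predict(self, X):
        """Thresholded multi-label masks for a sequence of slices."""
        check_is_fitted(self, "model_")
        cfg = self._config()
        return [predict_slice(self.model_, slc, cfg) for slc in X]

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        cfg = self._config()
        out = []
        for slc in X:
            img, _ = prepare_pair(slc, None, cfg)
            out.append(sigmoid(self.model_.forward(with_coord_channels(img)[None]))[0])
        return out
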