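"""Multi-label CSF masks.

A segmentation carries four independent boolean channels: left Sylvian
fissure, right Sylvian fissure, suprasylvian sulci, and an auxiliary
background channel that is trained like the others but dropped from all
downstream volumetry.  Channels are independent (multi-label): a channel may
be empty and, for imperfect predictions, channels may overlap.  Label-coded
images on disk use 0 background, 1 left Sylvian, 2 right Sylvian,
3 suprasylvian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABEL_NAMES = ("left_sylvian", "right_sylvian", "suprasylvian", "background_aux")
#: label-image integer codes for the three anatomical channels
LABEL_CODES = {"left_sylvian": 1, "right_sylvian": 2, "suprasylvian": 3}


@dataclass
class MultiLabelMask:
    """Per-label boolean grids (2D per slice, or 3D reconstructed).

    Parameters
    ----------
    channels
        Boolean array of shape ``(n_channels, *grid_shape)``; channel order
        follows :data:`LABEL_NAMES`.
    spacing
        Physical size of one grid cell in mm, one entry per grid axis.
    origin
        Physical coordinate (mm) of grid index ``(0, ..., 0)``.
    """

    channels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = None
    names: tuple = field(default=LABEL_NAMES)

    def __post_init__(self):
        self.channels = np.asarray(self.channels).astype(bool)
        if self.channels.ndim < 3:
            raise ValueError("channels must be (n_channels, *grid_shape)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.origin is not None:
            self.origin = tuple(float(o) for o in self.origin)
        self.names = tuple(self.names)[: self.channels.shape[0]]

    @property
    def grid_shape(self):
        return self.channels.shape[1:]

    def get(self, name: str) -> np.ndarray:
        return self.channels[self.names.index(name)]

    @classmethod
    def from_labels(cls, labels: np.ndarray, spacing=(1.0, 1.0, 1.0), origin=None,
                    background_aux: bool = True) -> "MultiLabelMask":
        """Expand an integer label image into per-channel boolean grids."""
        labels = np.asarray(labels)
        chans = [labels == LABEL_CODES[n] for n in LABEL_NAMES[:3]]
        if background_aux:
            chans.append(labels == 0)
        return cls(np.stack(chans), spacing=spacing, origin=origin)

    def to_labels(self) -> np.ndarray:
        """Collapse the three anatomical channels to a label-coded image.

        On overlap the lowest label code wins; the auxiliary background
        channel is ignored.
        """
        out = np.zeros(self.grid_shape, dtype=np.uint8)
        for name in reversed(LABEL_NAMES[:3]):
            out[self.channels[self.names.index(name)]] = LABEL_CODES[name]
        return out
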