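"""Stage 1: coarse localization of the target organ.

A VGG-style 3D encoder–decoder (four stride-2 downsampling steps, three
upsampling steps of factors 2, 2 and 4) maps a normalized volume to a
per-voxel candidate probability. Post-processing binarizes at 0.5, removes
satellite components, takes the bounding box of the surviving component and
crops + pads the original-resolution volume to the segmentation input size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import generate_binary_structure, label

from .nn import (
    Conv3d,
    ConvTranspose3d,
    Model3D,
    ReLU,
    Sigmoid,
    TrainConfig,
    dice_loss,
    fit,
)
from .volume import (
    BinaryMask,
    BoundingBox,
    PadRecord,
    Volume,
    crop,
    pad_to,
    resample,
    resample_mask,
)

__all__ = [
    "LocalizerSpec",
    "TrainConfig",
    "LocalizerNet",
    "LocalizationError",
    "LocalizationResult",
    "build_localizer",
    "dice_loss",
    "train_localizer",
    "binarize_candidates",
    "remove_satellites",
    "bounding_box_of",
    "localize",
]


@dataclass(frozen=True)
class LocalizerSpec:
    """Architecture contract: 4 downsampling steps halving the grid, channel
    progression 1->32->64->128->256, and 3 upsampling steps (2, 2, 4) so the
    output grid equals the input grid."""

    input_shape: tuple[int, int, int] = (96, 96, 128)
    channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    upsample_factors: tuple[int, int, int] = (2, 2, 4)

    def __post_init__(self):
        if len(self.channels) != 4:
            raise ValueError("channel progression must list 4 encoder widths")
        factor = 2 ** len(self.channels)
        if int(np.prod(self.upsample_factors)) != factor:
            raise ValueError("upsample factors must multiply to 2^n_downsamples")
        for n in self.input_shape:
            if n % factor:
                raise ValueError(
                    f"input extents must be divisible by {factor}, got {self.input_shape}"
                )


class LocalizerNet(Model3D):
    """Encoder of stride-2 convolutions; decoder of transposed convolutions
    (the last with factor 4) ending in a sigmoid probability map."""

    def __init__(self, spec: LocalizerSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.channels
        self.enc = []
        cin = 1
        for c in ch:
            self.enc.append((Conv3d(cin, c, rng, k=3, stride=2), ReLU()))
            cin = c
        f1, f2, f3 = spec.upsample_factors
        self.dec = [
            (ConvTranspose3d(ch[3], ch[2], rng, k=f1), ReLU()),
            (ConvTranspose3d(ch[2], ch[1], rng, k=f2), ReLU()),
            (ConvTranspose3d(ch[1], 1, rng, k=f3), Sigmoid()),
        ]
        # start the sigmoid output near the foreground prior of a very small
        # target (<0.5% of the volume) rather than at 0.5
        self.dec[-1][0].b.value[:] = -3.0
        self.layers = [l for pair in self.enc + self.dec for l in pair]

    def spec_dict(self):
        return {
            "kind": "localizer",
            "input_shape": list(self.spec.input_shape),
            "channels": list(self.spec.channels),
            "upsample_factors": list(self.spec.upsample_factors),
        }

    @classmethod
    def load(cls, path: str | Path) -> "LocalizerNet":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["spec"]))
        spec = LocalizerSpec(
            tuple(meta["input_shape"]),
            tuple(meta["channels"]),
            tuple(meta["upsample_factors"]),
        )
        model = cls(spec)
        model._load_weights_npz(path)
        return model

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for conv, act in self.enc:
            x = act.forward(conv.forward(x, train), train)
        for up, act in self.dec:
            x = act.forward(up.forward(x, train), train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for up, act in reversed(self.dec):
            gy = up.backward(act.backward(gy))
        for conv, act in reversed(self.enc):
            gy = conv.backward(act.backward(gy))
        return gy

    def feature_shapes(self, input_shape=None):
        """Spatial shape + channel walk of an actual forward pass."""
        shape = tuple(input_shape or self.spec.input_shape)
        x = np.zeros((1, *shape), dtype=np.float32)
        walk = [x.shape[1:] + (1,)]
        for conv, act in self.enc:
            x = act.forward(conv.forward(x))
            walk.append(x.shape[1:] + (x.shape[0],))
        for up, act in self.dec:
            x = act.forward(up.forward(x))
            walk.append(x.shape[1:] + (x.shape[0],))
        return walk


def build_localizer(spec: LocalizerSpec | None = None, seed: int = 0) -> LocalizerNet:
    return LocalizerNet(spec or LocalizerSpec(), seed=seed)


def train_localizer(model: LocalizerNet, cohort, val_cohort, config: TrainConfig):
    """Adam + mean Dice loss at batch size 1; returns (model, history) with the
    model holding the best-validation parameter state."""
    history = fit(model, cohort, val_cohort, config)
    return model, history


# ---------------------------------------------------------------------------
# Post-processing chain


def binarize_candidates(prob: np.ndarray, tau: float = 0.5) -> BinaryMask:
    """Candidate regions are voxels with probability strictly above ``tau``."""
    prob = np.asarray(prob)
    return BinaryMask((prob > tau).astype(np.uint8))


def remove_satellites(mask: BinaryMask, connectivity: int = 6) -> BinaryMask:
    """Keep only the largest connected component (satellite clusters deleted).

    Ties go to the component whose first voxel appears earliest in
    row-column-slice scan order. Empty input stays empty.
    """
    struct = {6: generate_binary_structure(3, 1),
              18: generate_binary_structure(3, 2),
              26: generate_binary_structure(3, 3)}[connectivity]
    labels, n_comp = label(mask.voxels, structure=struct)
    if n_comp <= 1:
        return BinaryMask(mask.voxels.copy())
    counts = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(counts)) + 1  # label order == scan order of discovery
    return BinaryMask((labels == keep).astype(np.uint8))


def bounding_box_of(mask: BinaryMask, margin_voxels: int = 0) -> BoundingBox:
    """Tightest axis-aligned box around the foreground, expanded by a margin
    and clamped to the grid."""
    coords = np.argwhere(mask.voxels)
    if coords.size == 0:
        raise ValueError("bounding_box_of: empty mask")
    box = BoundingBox(tuple(coords.min(axis=0)), tuple(coords.max(axis=0)))
    if margin_voxels:
        box = box.expand(margin_voxels, mask.shape)
    return box


class LocalizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LocalizationResult:
    localized: Volume
    box: BoundingBox
    candidates: BinaryMask  # satellite-filtered, on the original grid
    pad_record: PadRecord
    probability: np.ndarray = field(repr=False, default=None)


def _shrink_box_to(box: BoundingBox, max_shape, grid_shape) -> BoundingBox:
    """Symmetrically shrink a box so it fits max_shape (degenerate safety net
    for candidate regions larger than the segmentation input grid)."""
    lo, hi = list(box.lo), list(box.hi)
    for ax, m in enumerate(max_shape):
        excess = (hi[ax] - lo[ax] + 1) - m
        if excess > 0:
            lo[ax] += excess // 2
            hi[ax] -= excess - excess // 2
    return BoundingBox(tuple(lo), tuple(hi))


def localize(
    model: LocalizerNet,
    volume: Volume,
    seg_input_shape: tuple[int, int, int],
    margin_voxels: int = 0,
    mask_outside: bool = True,
    connectivity: int = 6,
) -> LocalizationResult:
    """Full stage-1 chain on a normalized volume.

    Predict on the (resampled) localizer grid, binarize at 0.5, bring the
    candidate mask back to the original grid (nearest-neighbour, so labels
    stay binary), delete satellites, box the surviving component, crop the
    original-resolution volume and pad to ``seg_input_shape``. Intensities
    inside the candidate regions are never altered; with ``mask_outside``
    voxels inside the box but outside the candidates are set to 0.
    """
    loc_shape = model.spec.input_shape
    x = volume if volume.shape == loc_shape else resample(volume, loc_shape)
    prob = model.predict(x.voxels)
    cand_small = binarize_candidates(prob, 0.5)
    cand = (
        cand_small
        if cand_small.shape == volume.shape
        else resample_mask(cand_small, volume.shape)
    )
    cand = remove_satellites(cand, connectivity=connectivity)
    if cand.count() == 0:
        raise LocalizationError("localization failed: no candidate region above 0.5")
    box = bounding_box_of(cand, margin_voxels=margin_voxels)
    box = _shrink_box_to(box, seg_input_shape, volume.shape)
    localized = crop(volume, box)
    if mask_outside:
        inside = crop(cand, box).voxels.astype(bool)
        vox = localized.voxels.copy()
        vox[~inside] = 0.0
        localized = Volume(vox, localized.spacing)
    padded, record = pad_to(localized, seg_input_shape, 0.0)
    return LocalizationResult(padded, box, cand, record, prob)
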