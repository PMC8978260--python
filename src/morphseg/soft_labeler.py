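"""Stage 2: per-voxel soft labels from a deepened 3D U-net.

The encoder performs four stride-2 convolutions (channels 1->32->64->128->256),
the decoder four transposed-convolution upsampling steps with skip
concatenation at each shared resolution, ending in a sigmoid probability map
congruent to the input. One level deeper than the classic three-level U-net,
to match the deepest-feature contract (e.g. 9x13x8x256 for a 144x208x128
input).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import (
    Conv3d,
    ConvTranspose3d,
    Model3D,
    ReLU,
    Sigmoid,
    TrainConfig,
    fit,
)
from .volume import Volume

__all__ = [
    "UNetSpec",
    "UNet3D",
    "build_unet",
    "train_unet",
    "predict_soft_labels",
]


@dataclass(frozen=True)
class UNetSpec:
    input_shape: tuple[int, int, int] = (144, 208, 128)
    channels: tuple[int, ...] = (32, 64, 128, 256)
    n_levels: int = 4

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if len(self.channels) < self.n_levels:
            raise ValueError("need one channel width per level")
        factor = 2**self.n_levels
        for n in self.input_shape:
            if n % factor:
                raise ValueError(
                    f"input extents must be divisible by {factor}, got {self.input_shape}"
                )


class UNet3D(Model3D):
    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.channels[: spec.n_levels]
        self.enc = []
        cin = 1
        for c in ch:
            self.enc.append((Conv3d(cin, c, rng, k=3, stride=2), ReLU()))
            cin = c
        # decoder: upsample, concat the encoder feature at that resolution,
        # fuse with a pointwise convolution (spatial mixing lives in the
        # strided encoder and the transposed-conv upsampling)
        self.dec = []
        for lvl in range(spec.n_levels - 1, 0, -1):
            up = ConvTranspose3d(ch[lvl], ch[lvl - 1], rng, k=2)
            merge = Conv3d(2 * ch[lvl - 1], ch[lvl - 1], rng, k=1, stride=1)
            self.dec.append((up, ReLU(), merge, ReLU()))
        c_head = max(2, ch[0] // 2)
        self.head_up = ConvTranspose3d(ch[0], c_head, rng, k=2)
        self.head_act = ReLU()
        self.head_conv = Conv3d(c_head, 1, rng, k=1, stride=1)
        # start the sigmoid output near the small-foreground prior
        self.head_conv.b.value[:] = -3.0
        self.head_out = Sigmoid()
        self.layers = (
            [l for pair in self.enc for l in pair]
            + [l for quad in self.dec for l in quad]
            + [self.head_up, self.head_act, self.head_conv, self.head_out]
        )

    def spec_dict(self):
        return {
            "kind": "unet",
            "input_shape": list(self.spec.input_shape),
            "channels": list(self.spec.channels),
            "n_levels": self.spec.n_levels,
        }

    @classmethod
    def load(cls, path: str | Path) -> "UNet3D":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["spec"]))
        spec = UNetSpec(
            tuple(meta["input_shape"]), tuple(meta["channels"]), meta["n_levels"]
        )
        model = cls(spec)
        model._load_weights_npz(path)
        return model

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        for conv, act in self.enc:
            x = act.forward(conv.forward(x, train), train)
            skips.append(x)
        for (up, act1, merge, act2), skip in zip(self.dec, reversed(skips[:-1])):
            x = act1.forward(up.forward(x, train), train)
            x = np.concatenate([x, skip], axis=0)
            x = act2.forward(merge.forward(x, train), train)
        x = self.head_act.forward(self.head_up.forward(x, train), train)
        x = self.head_conv.forward(x, train)
        return self.head_out.forward(x, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = self.head_conv.backward(self.head_out.backward(gy))
        gy = self.head_up.backward(self.head_act.backward(gy))
        # walk decoder stages in reverse, splitting the concat gradient;
        # dec[i] consumed the encoder feature of level len(enc)-2-i
        skip_by_level = {}
        for i in range(len(self.dec) - 1, -1, -1):
            up, act1, merge, act2 = self.dec[i]
            g = merge.backward(act2.backward(gy))
            c_up = up.cout
            g_up, g_skip = g[:c_up], g[c_up:]
            skip_by_level[len(self.enc) - 2 - i] = g_skip
            gy = up.backward(act1.backward(g_up))
        for lvl in range(len(self.enc) - 1, -1, -1):
            conv, act = self.enc[lvl]
            if lvl in skip_by_level:
                gy = gy + skip_by_level[lvl]
            gy = conv.backward(act.backward(gy))
        return gy

    def feature_shapes(self, input_shape=None):
        shape = tuple(input_shape or self.spec.input_shape)
        x = np.zeros((1, *shape), dtype=np.float32)
        walk = [x.shape[1:] + (1,)]
        skips = []
        for conv, act in self.enc:
            x = act.forward(conv.forward(x))
            skips.append(x)
            walk.append(x.shape[1:] + (x.shape[0],))
        for (up, act1, merge, act2), skip in zip(self.dec, reversed(skips[:-1])):
            x = act1.forward(up.forward(x))
            walk.append(x.shape[1:] + (x.shape[0],))
            x = np.concatenate([x, skip], axis=0)
            x = act2.forward(merge.forward(x))
        x = self.head_act.forward(self.head_up.forward(x))
        x = self.head_out.forward(self.head_conv.forward(x))
        walk.append(x.shape[1:] + (x.shape[0],))
        return walk


def build_unet(spec: UNetSpec | None = None, seed: int = 0) -> UNet3D:
    return UNet3D(spec or UNetSpec(), seed=seed)


def train_unet(model: UNet3D, cohort, val_cohort, config: TrainConfig | None = None):
    """Train on (localized volume, congruent mask) pairs; Adam, Dice loss,
    best-validation parameter state returned."""
    config = config or TrainConfig(learning_rate=1e-5)
    history = fit(model, cohort, val_cohort, config)
    return model, history


def predict_soft_labels(model: UNet3D, localized: Volume | np.ndarray) -> np.ndarray:
    """Probability map (same grid as the localized input) for the target."""
    vox = getattr(localized, "voxels", localized)
    if vox.shape != tuple(model.spec.input_shape):
        raise ValueError(
            f"input shape {vox.shape} != model input {model.spec.input_shape}"
        )
    return model.predict(vox)
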