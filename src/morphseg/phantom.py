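"""Synthetic abdominal-like phantom cohorts.

Each phantom is a 3D intensity volume plus a crisp binary ground-truth mask
of a small, curved, elongated tubular target (head thicker than tail) —
a stand-in for a long thin retroperitoneal organ that occupies well under
0.5% of the scan volume. Distractor blobs share the target's mean intensity
to within +/-10%, borders are fuzzed by Gaussian smoothing of the intensity
(never of the mask), and additive Gaussian noise completes the picture.
Everything is driven by a single seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, generate_binary_structure, label

from .volume import BinaryMask, Volume

__all__ = ["PhantomConfig", "PhantomError", "generate_phantom", "generate_cohort"]

_BG_INTENSITY = 0.35
_TARGET_INTENSITY = 0.65


class PhantomError(RuntimeError):
    pass


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    target_fraction_range: tuple[float, float] = (0.001, 0.005)
    n_distractors: int = 6
    noise_sd: float = 0.04
    smooth_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.target_fraction_range
        if not (0 < lo <= hi <= 0.02):
            raise ValueError(
                f"target_fraction_range must lie within (0, 0.02], got {self.target_fraction_range}"
            )
        if any(n < 16 for n in self.shape):
            raise ValueError(f"each shape extent must be >= 16, got {self.shape}")
        if self.n_distractors < 0 or self.noise_sd < 0 or self.smooth_sigma < 0:
            raise ValueError("n_distractors, noise_sd, smooth_sigma must be >= 0")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _tube_count(grid, pts, radii, scale) -> np.ndarray:
    """Boolean mask of voxels within scale*radius of the sampled curve."""
    gy, gx, gz = grid
    mask = np.zeros(gy.shape, dtype=bool)
    for p, r in zip(pts, radii):
        rr = scale * r
        d2 = (gy - p[0]) ** 2 + (gx - p[1]) ** 2 + (gz - p[2]) ** 2
        mask |= d2 <= rr * rr
    return mask


def _sample_curve(shape, rng):
    """A bent centerline with tapering radius, confined to the central grid.

    The long axis follows a fixed anatomical base direction (the column
    axis) with Gaussian angular jitter — like a real organ cohort, subjects
    share an approximate lie while differing in bend, scale and position.
    """
    shape = np.asarray(shape, dtype=float)
    center = (shape - 1) / 2.0
    c = center + rng.uniform(-0.08, 0.08, size=3) * shape
    tilt = rng.normal(0.0, 0.3, size=2)
    d = _unit(np.array([tilt[0], 1.0, tilt[1]]))
    # a perpendicular direction for the bend
    perp = rng.normal(size=3)
    perp -= perp @ d * d
    perp = _unit(perp)
    length = rng.uniform(0.45, 0.62) * float(shape.min())
    bend = rng.uniform(0.06, 0.20) * length
    t = np.linspace(-0.5, 0.5, 120)
    pts = c[None, :] + np.outer(t * length, d) + np.outer(
        bend * np.sin(np.pi * (t + 0.5)), perp
    )
    # keep the curve inside a 3-voxel margin by shrinking toward its mean
    lo, hi = 3.0, shape - 4.0
    over = np.maximum(pts - hi[None, :], 0).max() + np.maximum(lo - pts, 0).max()
    if over > 0:
        mid = pts.mean(axis=0)
        shrink = max(0.4, 1.0 - over / length)
        pts = mid[None, :] + (pts - mid[None, :]) * shrink
    # bulky head tapering to a thin tail, roughly 2.3:1 in radius
    radii = 1.4 - 0.8 * (t + 0.5)
    return pts, radii


def _voxelize_target(shape, rng, fraction):
    n_vox = int(np.prod(shape))
    target_count = fraction * n_vox
    grid = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    pts, radii = _sample_curve(shape, rng)
    lo_s, hi_s = 0.3, 6.0
    # monotone bisection on the global radius scale to hit the requested count
    for _ in range(30):
        mid = 0.5 * (lo_s + hi_s)
        cnt = int(_tube_count(grid, pts, radii, mid).sum())
        if cnt < target_count:
            lo_s = mid
        else:
            hi_s = mid
    mask = _tube_count(grid, pts, radii, 0.5 * (lo_s + hi_s))
    return mask


def generate_phantom(config: PhantomConfig) -> tuple[Volume, BinaryMask]:
    """One deterministic phantom: (intensity volume, crisp 0/1 target mask).

    The target is a single 6-connected component whose voxel fraction lies in
    ``config.target_fraction_range``; generation retries with fresh geometry
    (same seeded stream) when a thin tail breaks connectivity.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(n) for n in config.shape)
    n_vox = int(np.prod(shape))
    lo_f, hi_f = config.target_fraction_range
    struct = generate_binary_structure(3, 1)  # 6-connectivity

    mask = None
    for _ in range(25):
        fraction = rng.uniform(lo_f + 0.25 * (hi_f - lo_f), hi_f - 0.1 * (hi_f - lo_f))
        cand = _voxelize_target(shape, rng, fraction)
        labels, n_comp = label(cand, structure=struct)
        if n_comp == 0:
            continue
        if n_comp > 1:  # keep the largest piece if it still fits the range
            counts = np.bincount(labels.ravel())[1:]
            cand = labels == (int(np.argmax(counts)) + 1)
        frac = cand.sum() / n_vox
        if lo_f < frac < hi_f:
            mask = cand
            break
    if mask is None:
        raise PhantomError(
            f"could not fit a target with fraction in {config.target_fraction_range} "
            f"into shape {shape}"
        )

    vol = np.full(shape, _BG_INTENSITY, dtype=np.float64)
    vol[mask] = _TARGET_INTENSITY

    # distractor blobs: intensity within +/-10% of the target mean, never
    # touching the (1-voxel dilated) target so ground truth stays unambiguous
    forbidden = binary_dilation(mask, structure=struct)
    grid = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    placed = 0
    attempts = 0
    while placed < config.n_distractors and attempts < 30 * max(1, config.n_distractors):
        attempts += 1
        c = rng.uniform(2, np.asarray(shape, dtype=float) - 3)
        radii = rng.uniform(1.5, 0.09 * min(shape), size=3) + 1.0
        d2 = sum(((g - ci) / ri) ** 2 for g, ci, ri in zip(grid, c, radii))
        blob = d2 <= 1.0
        if not blob.any() or (blob & forbidden).any():
            continue
        vol[blob] = _TARGET_INTENSITY * (1.0 + rng.uniform(-0.1, 0.1))
        placed += 1

    if config.smooth_sigma > 0:
        vol = gaussian_filter(vol, config.smooth_sigma)
    if config.noise_sd > 0:
        vol = vol + rng.normal(0.0, config.noise_sd, size=shape)
    return Volume(vol.astype(np.float32)), BinaryMask(mask.astype(np.uint8))


def generate_cohort(n: int, config: PhantomConfig) -> list[tuple[Volume, BinaryMask]]:
    """``n`` phantoms with per-subject seeds derived from ``config.seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n)
    cohort = []
    for child in children:
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        sub_cfg = PhantomConfig(
            shape=config.shape,
            target_fraction_range=config.target_fraction_range,
            n_distractors=config.n_distractors,
            noise_sd=config.noise_sd,
            smooth_sigma=config.smooth_sigma,
            seed=sub_seed,
        )
        cohort.append(generate_phantom(sub_cfg))
    return cohort
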