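"""Volumes, masks, bounding boxes and the geometric/intensity preprocessing
shared by every pipeline stage.

Axis convention: arrays are indexed ``(row, column, slice)`` — the (y, x, z)
order of the acquisition grid.  All bounding boxes are 0-based with
*inclusive* endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Volume",
    "BinaryMask",
    "BoundingBox",
    "PadRecord",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "normalize_unity",
    "crop",
    "resample",
    "resample_mask",
    "pad_to",
    "unpad",
]


@dataclass(frozen=True)
class Volume:
    """A 3D real-valued intensity grid with voxel spacing in millimetres."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected 3D volume, got {vox.ndim}D")
        if not np.all(np.isfinite(vox)):
            raise ValueError("volume intensities must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A 3D {0,1} grid, geometrically congruent to its paired :class:`Volume`."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected 3D mask, got {vox.ndim}D")
        if not np.isin(vox, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        object.__setattr__(self, "voxels", vox.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned 3D index box; per-axis inclusive (lo, hi), 0-based."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        for axis, (a, b) in enumerate(zip(lo, hi)):
            if a < 0 or a > b:
                raise ValueError(f"invalid box on axis {axis}: lo={a}, hi={b}")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l + 1 for l, h in zip(self.lo, self.hi))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))

    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def check_within(self, grid_shape: tuple[int, int, int]) -> None:
        for axis, (h, n) in enumerate(zip(self.hi, grid_shape)):
            if h >= n:
                raise ValueError(
                    f"box exceeds grid on axis {axis}: hi={h}, extent={n}"
                )

    def expand(self, margin: int, grid_shape: tuple[int, int, int]) -> "BoundingBox":
        """Expand by ``margin`` voxels per side, clamped to the grid."""
        lo = tuple(max(0, l - margin) for l in self.lo)
        hi = tuple(min(n - 1, h + margin) for h, n in zip(self.hi, grid_shape))
        return BoundingBox(lo, hi)

    def as_mask(self, grid_shape: tuple[int, int, int]) -> BinaryMask:
        self.check_within(grid_shape)
        m = np.zeros(grid_shape, dtype=np.uint8)
        m[self.slices()] = 1
        return BinaryMask(m)


@dataclass(frozen=True)
class PadRecord:
    """Per-axis (before, after) pad amounts; makes :func:`pad_to` invertible."""

    before: tuple[int, int, int]
    after: tuple[int, int, int]


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_volume(path: str | Path) -> Volume:
    data, spacing = _load_nifti(path)
    return Volume(np.asarray(data, dtype=np.float32), spacing)


def write_volume(volume: Volume, path: str | Path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    data, _ = _load_nifti(path)
    return BinaryMask(np.rint(data).astype(np.uint8))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), np.eye(4))
    nib.save(img, str(path))


def write_probability_map(prob: np.ndarray, path: str | Path) -> None:
    """Write a [0,1] map as float32 NIfTI (values below float32-tiny clamp up)."""
    arr = np.asarray(prob, dtype=np.float64)
    tiny = float(np.finfo(np.float32).tiny)
    arr = np.where((arr > 0) & (arr < tiny), tiny, arr)
    nib.save(nib.Nifti1Image(arr.astype(np.float32), np.eye(4)), str(path))


def read_probability_map(path: str | Path) -> np.ndarray:
    data, _ = _load_nifti(path)
    return np.asarray(data, dtype=np.float64)


# ---------------------------------------------------------------------------
# Intensity and geometry


def normalize_unity(volume: Volume) -> Volume:
    """Linearly rescale intensities to span [0, 1].

    A constant volume has no dynamic range; it maps to all zeros with a
    warning rather than failing, since padded regions and degenerate phantoms
    can legitimately be constant.
    """
    v = volume.voxels
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn("normalize_unity: constant volume, returning zeros")
        return Volume(np.zeros_like(v, dtype=np.float32), volume.spacing)
    out = (v - lo) / (hi - lo)
    return Volume(out.astype(np.float32, copy=False), volume.spacing)


def crop(obj: Volume | BinaryMask, box: BoundingBox):
    """Extract the sub-grid delimited by ``box``; values are copied unaltered."""
    box.check_within(obj.shape)
    sub = obj.voxels[box.slices()].copy()
    if isinstance(obj, BinaryMask):
        return BinaryMask(sub)
    return Volume(sub, obj.spacing)


def _resample_coords(in_shape, out_shape) -> np.ndarray:
    """Align-corners coordinate grid: output index i maps to i*(n_in-1)/(n_out-1)."""
    axes = []
    for n_in, n_out in zip(in_shape, out_shape):
        if n_out == 1:
            axes.append(np.array([(n_in - 1) / 2.0]))
        else:
            axes.append(np.arange(n_out) * (n_in - 1) / (n_out - 1))
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)


def resample(volume: Volume, target_shape: tuple[int, int, int]) -> Volume:
    """Trilinear resampling onto ``target_shape`` (align-corners convention)."""
    target_shape = tuple(int(n) for n in target_shape)
    if any(n <= 0 for n in target_shape):
        raise ValueError(f"target_shape must be positive, got {target_shape}")
    if target_shape == volume.shape:
        return Volume(volume.voxels.copy(), volume.spacing)
    coords = _resample_coords(volume.shape, target_shape)
    out = map_coordinates(
        volume.voxels.astype(np.float64), coords, order=1, mode="nearest"
    )
    spacing = tuple(
        s * n_in / n_out
        for s, n_in, n_out in zip(volume.spacing, volume.shape, target_shape)
    )
    return Volume(out.astype(np.float32), spacing)


def resample_mask(mask: BinaryMask, target_shape: tuple[int, int, int]) -> BinaryMask:
    """Nearest-neighbour resampling of a binary mask (labels stay binary)."""
    target_shape = tuple(int(n) for n in target_shape)
    if any(n <= 0 for n in target_shape):
        raise ValueError(f"target_shape must be positive, got {target_shape}")
    if target_shape == mask.shape:
        return BinaryMask(mask.voxels.copy())
    coords = _resample_coords(mask.shape, target_shape)
    out = map_coordinates(mask.voxels, coords, order=0, mode="nearest")
    return BinaryMask(out)


def _pad_amounts(shape, target_shape) -> tuple[tuple, tuple]:
    before, after = [], []
    for cur, tgt in zip(shape, target_shape):
        if tgt < cur:
            raise ValueError(f"target shape {target_shape} smaller than {shape}")
        diff = tgt - cur
        b = diff // 2  # extra voxel goes after the content on odd differences
        before.append(b)
        after.append(diff - b)
    return tuple(before), tuple(after)


def pad_to(obj, target_shape: tuple[int, int, int], fill_value: float = 0.0):
    """Center-pad to ``target_shape``; returns (padded, :class:`PadRecord`)."""
    before, after = _pad_amounts(obj.shape, target_shape)
    record = PadRecord(before, after)
    widths = tuple(zip(before, after))
    if isinstance(obj, BinaryMask):
        padded = np.pad(obj.voxels, widths, constant_values=int(fill_value))
        return BinaryMask(padded), record
    if isinstance(obj, Volume):
        padded = np.pad(obj.voxels, widths, constant_values=fill_value)
        return Volume(padded, obj.spacing), record
    padded = np.pad(np.asarray(obj), widths, constant_values=fill_value)
    return padded, record


def unpad(obj, record: PadRecord):
    """Invert :func:`pad_to` using its record."""
    arr = obj.voxels if isinstance(obj, (Volume, BinaryMask)) else np.asarray(obj)
    sl = tuple(
        slice(b, n - a if a else n)
        for b, a, n in zip(record.before, record.after, arr.shape)
    )
    sub = arr[sl].copy()
    if isinstance(obj, BinaryMask):
        return BinaryMask(sub)
    if isinstance(obj, Volume):
        return Volume(sub, obj.spacing)
    return sub
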