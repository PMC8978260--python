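"""Segmentation and localization metrics, and the fold-split machinery.

DSC = 2|X∩Y| / (|X| + |Y|); localization TPR/TNR use the whole-grid
convention: the prediction is the box interior, positives are all reference
voxels, negatives all non-reference voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume import BinaryMask, BoundingBox

__all__ = [
    "SegmentationMetrics",
    "FoldSplit",
    "dsc",
    "localization_metrics",
    "make_folds",
]


@dataclass(frozen=True)
class SegmentationMetrics:
    dsc: float
    tpr: float
    tnr: float
    tp: int
    tn: int
    p: int
    n: int


@dataclass(frozen=True)
class FoldSplit:
    """k pairwise-disjoint case-ID subsets covering the whole cohort."""

    folds: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        all_ids = [i for f in self.folds for i in f]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("folds must be pairwise disjoint")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def __len__(self):
        return len(self.folds)

    def split(self, k: int) -> tuple[list[int], list[int]]:
        """(train_ids, test_ids) with fold ``k`` held out."""
        test = list(self.folds[k])
        train = [i for j, f in enumerate(self.folds) if j != k for i in f]
        return train, test


def dsc(x: BinaryMask | np.ndarray, y: BinaryMask | np.ndarray) -> float:
    """Dice–Sørensen coefficient of two binary masks.

    Two empty masks are perfect agreement; the undefined 0/0 is returned as
    1.0 with a warning.
    """
    xv = np.asarray(getattr(x, "voxels", x), dtype=bool)
    yv = np.asarray(getattr(y, "voxels", y), dtype=bool)
    if xv.shape != yv.shape:
        raise ValueError(f"shape mismatch: {xv.shape} vs {yv.shape}")
    size = int(xv.sum()) + int(yv.sum())
    if size == 0:
        warnings.warn("dsc: both masks empty, returning 1.0")
        return 1.0
    return 2.0 * int(np.logical_and(xv, yv).sum()) / size


def localization_metrics(box: BoundingBox, truth: BinaryMask) -> SegmentationMetrics:
    """TPR/TNR/DSC of a bounding box against the reference mask."""
    box.check_within(truth.shape)
    tv = truth.voxels.astype(bool)
    p = int(tv.sum())
    if p == 0:
        raise ValueError("localization_metrics: empty reference mask")
    n = tv.size - p
    box_mask = np.zeros_like(tv)
    box_mask[box.slices()] = True
    tp = int(np.logical_and(tv, box_mask).sum())
    tn = int(np.logical_and(~tv, ~box_mask).sum())
    return SegmentationMetrics(
        dsc=dsc(box_mask, tv),
        tpr=tp / p,
        tnr=tn / n if n else 1.0,
        tp=tp,
        tn=tn,
        p=p,
        n=n,
    )


def make_folds(case_ids, k: int = 4, seed: int = 0) -> FoldSplit:
    """Seeded-shuffle round-robin assignment; fold sizes differ by <= 1."""
    ids = list(case_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} cases, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[int(idx)])
    return FoldSplit(tuple(tuple(f) for f in folds))
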