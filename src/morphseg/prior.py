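"""Stage 3: the morphology prior and its fusion with soft labels.

The prior is a single 3D probability template built from the reference
labels of the *training* images only. Labels are translation-aligned for
maximum overlap, then combined multiplicatively: a voxel covered by k of the
n labels receives baseline^(n-k) (baseline 0.1 by default, so no voxel is
ever exactly 0), and the map is normalized by its maximum. Fusion is the
voxel-wise joint probability of prior and soft label, min–max rescaled to
[0, 1]; the final segmentation threshold is chosen on the training data over
the grid {0.51, 0.52, ..., 0.99}.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import center_of_mass
from scipy.signal import correlate

from .volume import BinaryMask, write_probability_map

__all__ = [
    "MorphologyPrior",
    "FusionResult",
    "align_labels",
    "build_prior",
    "match_prior",
    "fuse",
    "select_threshold",
    "segment",
    "save_prior",
    "load_prior",
]


@dataclass(frozen=True)
class MorphologyPrior:
    """The probability template plus its construction metadata."""

    map: np.ndarray = field(repr=False)
    baseline: float
    n_labels: int
    offsets: tuple[tuple[int, int, int], ...]
    coverage: np.ndarray | None = field(repr=False, default=None)

    @property
    def shape(self):
        return self.map.shape

    def coverage_map(self) -> np.ndarray:
        """Graded coverage-frequency view of the prior: max(k/n, baseline)
        for a voxel covered by k of the n labels.

        This is the log-domain magnitude of the multiplicative map — the
        same template on a linear instead of exponential coverage scale —
        and is the natural probabilistic-atlas reading of "center bright,
        periphery darker". The baseline floor keeps every voxel possible.
        """
        if self.coverage is not None:
            k = self.coverage.astype(np.float64)
        else:
            # map = baseline^(kmax - k); recover coverage below the max
            below = np.rint(np.log(self.map) / np.log(self.baseline))
            k = below.max() - below
        return np.maximum(k / self.n_labels, self.baseline)


@dataclass(frozen=True)
class FusionResult:
    fused: np.ndarray = field(repr=False)
    threshold: float = 0.55
    segmentation: BinaryMask = None

    def __post_init__(self):
        if self.threshold <= 0.5:
            raise ValueError("threshold must exceed 0.5")


def _shift_int(mask: np.ndarray, offset) -> np.ndarray:
    """Translate by an integer offset with zero fill: out[v] = in[v - offset]."""
    out = np.zeros_like(mask)
    src, dst = [], []
    for o, n in zip(offset, mask.shape):
        o = int(o)
        if abs(o) >= n:
            return out
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _best_shift(target: np.ndarray, mv: np.ndarray, base, search_radius: int,
                current=None):
    """Integer shift of ``mv`` maximizing sum(target * shifted(mv)) within
    ``base`` +/- ``search_radius`` per axis; ties go to the first candidate
    in scan order (or to ``current`` when given, so refinement only moves on
    a strict improvement)."""
    scores = correlate(target, mv, mode="full", method="auto")
    center = np.asarray(mv.shape) - 1  # index of zero shift in 'full' output
    best, best_off = -1.0, tuple(int(b) for b in base)
    if current is not None:
        idx = tuple(c + o for c, o in zip(center, current))
        if all(0 <= i < s for i, s in zip(idx, scores.shape)):
            best, best_off = float(scores[idx]), tuple(int(o) for o in current)
    r = search_radius
    for dz in range(base[0] - r, base[0] + r + 1):
        for dy in range(base[1] - r, base[1] + r + 1):
            for dx in range(base[2] - r, base[2] + r + 1):
                idx = (center[0] + dz, center[1] + dy, center[2] + dx)
                if any(i < 0 or i >= s for i, s in zip(idx, scores.shape)):
                    continue
                s = float(scores[idx])
                if s > best + 1e-9:
                    best, best_off = s, (dz, dy, dx)
    return best_off


def align_labels(
    labels: list[BinaryMask], search_radius: int = 5, refine_passes: int = 2
) -> tuple[list[BinaryMask], list[tuple[int, int, int]]]:
    """Translate each label to maximize the cohort's mutual overlap.

    First pass: the first label anchors the frame; each subsequent label is
    moved by the rounded centroid difference to the running average of the
    already-aligned labels, then refined by an exhaustive integer-translation
    search within ``search_radius`` voxels per axis maximizing the
    intersection score. Subsequent ``refine_passes`` re-fit every label
    against the sum of all the others (standard groupwise refinement).
    Offsets are recorded so the construction is reproducible.
    """
    if not labels:
        raise ValueError("need at least one label")
    shape = labels[0].shape
    for m in labels:
        if m.shape != shape:
            raise ValueError("labels must share a common shape")
        if m.count() == 0:
            raise ValueError("empty label in list")
    originals = [m.voxels.astype(np.float64) for m in labels]
    aligned = [originals[0].copy()]
    offsets = [(0, 0, 0)]
    running = originals[0].copy()
    for mv in originals[1:]:
        c_run = np.asarray(center_of_mass(running))
        c_m = np.asarray(center_of_mass(mv))
        base = np.rint(c_run - c_m).astype(int)
        off = _best_shift(running, mv, base, search_radius)
        shifted = _shift_int(mv, off)
        aligned.append(shifted)
        offsets.append(tuple(int(o) for o in off))
        running += shifted
    for _ in range(max(0, refine_passes)):
        for j in range(len(originals)):
            others = running - aligned[j]
            if others.sum() <= 0:
                continue
            off = _best_shift(
                others, originals[j], np.asarray(offsets[j]), search_radius,
                current=offsets[j],
            )
            if off != offsets[j]:
                running -= aligned[j]
                aligned[j] = _shift_int(originals[j], off)
                offsets[j] = tuple(int(o) for o in off)
                running += aligned[j]
    return (
        [BinaryMask(a.astype(np.uint8)) for a in aligned],
        offsets,
    )


def build_prior(
    aligned_labels: list[BinaryMask],
    baseline: float = 0.1,
    offsets: list[tuple[int, int, int]] | None = None,
) -> MorphologyPrior:
    """Multiplicative prior: voxel value baseline^(n-k) for coverage count k,
    computed in the log domain (n can reach 60+, spanning ~60 orders of
    magnitude), then normalized by the maximum so max = 1 and no voxel is 0.
    """
    if not (0.0 < baseline < 1.0):
        raise ValueError(f"baseline must be in (0, 1), got {baseline}")
    if not aligned_labels:
        raise ValueError("need at least one label")
    coverage = np.zeros(aligned_labels[0].shape, dtype=np.int64)
    for m in aligned_labels:
        if m.shape != coverage.shape:
            raise ValueError("labels must share a common shape")
        coverage += m.voxels
    n = len(aligned_labels)
    k_max = int(coverage.max())
    # value = b^(n-k) / b^(n-k_max) = b^(k_max - k); log = (k_max - k) * log(b)
    prior_map = np.exp((k_max - coverage) * np.log(baseline))
    if offsets is None:
        offsets = [(0, 0, 0)] * n
    return MorphologyPrior(
        prior_map,
        float(baseline),
        n,
        tuple(tuple(int(v) for v in o) for o in offsets),
        coverage,
    )


def match_prior(prior: MorphologyPrior, target_shape) -> np.ndarray:
    """Center-pad (or center-crop) the prior map to ``target_shape``.

    Padding fills with the prior's own minimum value — padded zones stay
    "unlikely but possible", never 0.
    """
    arr = prior.map
    fill = float(arr.min())
    out = arr
    # crop axes where the target is smaller
    sl = []
    for cur, tgt in zip(arr.shape, target_shape):
        if tgt < cur:
            start = (cur - tgt) // 2
            sl.append(slice(start, start + tgt))
        else:
            sl.append(slice(None))
    out = out[tuple(sl)]
    widths = []
    for cur, tgt in zip(out.shape, target_shape):
        diff = max(0, tgt - cur)
        b = diff // 2
        widths.append((b, diff - b))
    if any(b or a for b, a in widths):
        out = np.pad(out, widths, constant_values=fill)
    return out.copy()


def _shift_filled(arr: np.ndarray, offset, fill: float) -> np.ndarray:
    out = np.full_like(arr, fill)
    src, dst = [], []
    for o, n in zip(offset, arr.shape):
        o = int(o)
        if abs(o) >= n:
            return out
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def align_prior_to(
    prior_map: np.ndarray, reference: np.ndarray, search_radius: int = 0
) -> np.ndarray:
    """Integer-shift the prior onto a case's predicted region (optional
    per-case pre-alignment).

    The base shift matches the prior's coverage-weighted centroid (weights
    are the log-excess over the floor, i.e. coverage counts — raw
    probabilities would let the single maximal voxel dominate) to the
    reference's centroid. With ``search_radius`` > 0 the shift is refined by
    an exhaustive integer search within that window, maximizing the overlap
    score sum(prior * reference). Shifted-in border voxels take the prior's
    minimum value, never 0.
    """
    ref = np.asarray(reference, dtype=np.float64)
    if ref.sum() == 0:
        return prior_map.copy()
    lo = float(prior_map.min())
    w = np.log(prior_map) - np.log(lo) if lo > 0 else prior_map
    if w.max() <= 0:
        return prior_map.copy()
    c_prior = np.asarray(center_of_mass(w))
    c_ref = np.asarray(center_of_mass(ref))
    base = np.rint(c_ref - c_prior).astype(int)
    offset = tuple(base)
    if search_radius > 0:
        scores = correlate(ref, prior_map, mode="full", method="auto")
        center = np.asarray(prior_map.shape) - 1
        best = -np.inf
        r = search_radius
        for dz in range(base[0] - r, base[0] + r + 1):
            for dy in range(base[1] - r, base[1] + r + 1):
                for dx in range(base[2] - r, base[2] + r + 1):
                    idx = (center[0] + dz, center[1] + dy, center[2] + dx)
                    if any(i < 0 or i >= s for i, s in zip(idx, scores.shape)):
                        continue
                    s = float(scores[idx])
                    if s > best + 1e-9:
                        best, offset = s, (dz, dy, dx)
    if not any(offset):
        return prior_map.copy()
    return _shift_filled(prior_map, offset, lo)


def fuse(soft: np.ndarray, prior_map: np.ndarray) -> np.ndarray:
    """Joint probability of soft labels and prior, min–max rescaled to [0,1]."""
    soft = np.asarray(soft, dtype=np.float64)
    prior_map = np.asarray(prior_map, dtype=np.float64)
    if soft.shape != prior_map.shape:
        raise ValueError(f"shape mismatch: {soft.shape} vs {prior_map.shape}")
    prod = soft * prior_map
    lo, hi = float(prod.min()), float(prod.max())
    if hi == lo:
        warnings.warn("fuse: constant product, returning zeros")
        return np.zeros_like(prod)
    return (prod - lo) / (hi - lo)


def _dsc_arrays(x: np.ndarray, y: np.ndarray) -> float:
    inter = float(np.logical_and(x, y).sum())
    size = float(x.sum()) + float(y.sum())
    if size == 0:
        return 1.0
    return 2.0 * inter / size


def threshold_grid(step: float = 0.01) -> np.ndarray:
    """Candidate thresholds strictly above 0.5 and below 1.0."""
    n = int(round((1.0 - 0.5) / step))
    grid = 0.5 + step * np.arange(1, n)
    return np.round(grid, 10)


def select_threshold(pairs, grid_step: float = 0.01) -> float:
    """Grid value maximizing mean DSC over training (fused map, mask) pairs;
    ties go to the smallest candidate."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty training set")
    grid = threshold_grid(grid_step)
    best_tau, best_score = float(grid[0]), -1.0
    for tau in grid:
        score = float(
            np.mean([_dsc_arrays(f > tau, m.voxels) for f, m in pairs])
        )
        if score > best_score + 1e-12:
            best_score, best_tau = score, float(tau)
    return best_tau


def segment(fused: np.ndarray, threshold: float) -> BinaryMask:
    """Strict thresholding of the fused map; thresholds at or below 0.5 are
    excluded by construction."""
    if threshold <= 0.5:
        raise ValueError(f"threshold must exceed 0.5, got {threshold}")
    return BinaryMask((np.asarray(fused) > threshold).astype(np.uint8))


# ---------------------------------------------------------------------------
# Persistence: float32 NIfTI + JSON sidecar with construction metadata


def save_prior(prior: MorphologyPrior, path: str | Path) -> None:
    path = Path(path)
    write_probability_map(prior.map, path)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
    meta = {
        "baseline": prior.baseline,
        "n_labels": prior.n_labels,
        "offsets": [list(o) for o in prior.offsets],
    }
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=2))


def load_prior(path: str | Path) -> MorphologyPrior:
    from .volume import read_probability_map

    path = Path(path)
    arr = read_probability_map(path)
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    meta = json.loads(sidecar.read_text())
    return MorphologyPrior(
        arr,
        float(meta["baseline"]),
        int(meta["n_labels"]),
        tuple(tuple(o) for o in meta["offsets"]),
    )
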