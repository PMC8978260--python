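"""End-to-end pipeline: fourfold cross-validation and component ablation.

Per fold the harness trains the localizer and U-net on the training split
only, builds the morphology prior from the training split's gold labels
only (no leakage), selects the fusion threshold on the training split, and
evaluates TPR/TNR/DSC on the held-out split. The ablation runs the six
factor combinations (localization x prior x U-net) through the same folds,
reusing the trained components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter, generate_binary_structure

_STRUCT6 = generate_binary_structure(3, 1)

from .evaluation import FoldSplit, dsc, localization_metrics, make_folds
from .localizer import (
    LocalizationError,
    LocalizerSpec,
    build_localizer,
    localize,
)
from .nn import TrainConfig, fit
from .prior import (
    MorphologyPrior,
    align_labels,
    align_prior_to,
    build_prior,
    fuse,
    match_prior,
    segment,
    select_threshold,
)
from .soft_labeler import UNetSpec, build_unet
from .volume import (
    BinaryMask,
    BoundingBox,
    Volume,
    crop,
    normalize_unity,
    pad_to,
    resample,
    resample_mask,
    unpad,
)

__all__ = ["PipelineConfig", "CVResult", "cross_validate", "ablation", "ABLATION_COMBOS"]

# Table-3-style factor combinations: (localization, prior, unet)
ABLATION_COMBOS = (
    (True, False, False),
    (True, True, False),
    (False, False, True),
    (True, False, True),
    (False, True, True),
    (True, True, True),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Desk-scale pipeline preset (32^3 phantoms, tiny channel widths).

    The architecture and procedure match the full-scale contracts; only the
    grid sizes, channel widths, epochs and learning rates are scaled so the
    whole fourfold harness runs on one CPU in minutes.
    """

    loc_input_shape: tuple[int, int, int] = (32, 32, 32)
    seg_input_shape: tuple[int, int, int] = (32, 32, 32)
    loc_channels: tuple[int, int, int, int] = (8, 16, 32, 64)
    unet_channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    loc_learning_rate: float = 1e-3
    unet_learning_rate: float = 1e-3
    loc_epochs: int = 120
    unet_epochs: int = 60
    loc_target_dilation: int = 4
    unet_crop_jitter: int = 2
    val_fraction: float = 0.25
    prior_baseline: float = 0.1
    prior_fusion: str = "coverage"  # "coverage" (graded atlas) or "product"
    prior_smooth_sigma: float = 2.5  # voxels; ~the cohort's positional variability scale
    prior_align: bool = True
    box_margin: int = 2
    mask_outside: bool = False
    threshold_grid_step: float = 0.01
    align_search_radius: int = 5
    n_folds: int = 4
    seed: int = 0
    # reinitialize and retrain when optimization stalls on a bad init
    train_restarts: int = 2
    restart_loss_threshold: float = 0.7


@dataclass
class CVResult:
    fold_table: pd.DataFrame
    cases: pd.DataFrame
    audit: list[dict] = field(default_factory=list)

    @property
    def mean_dsc_with_prior(self) -> float:
        return float(self.cases["dsc_prior"].mean())

    @property
    def mean_dsc_without_prior(self) -> float:
        return float(self.cases["dsc_no_prior"].mean())


def _train_val_split(ids: list[int], val_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_val = max(1, int(round(val_fraction * len(ids)))) if len(ids) > 1 else 0
    return order[n_val:], order[:n_val]


def _embed(seg_frame_mask: BinaryMask, record, box, grid_shape) -> BinaryMask:
    """Map a segmentation from the padded crop frame back to the full grid."""
    inner = unpad(seg_frame_mask, record)
    full = np.zeros(grid_shape, dtype=np.uint8)
    full[box.slices()] = inner.voxels
    return BinaryMask(full)


class _Fold:
    """All artifacts of one fold, trained on its training split only."""

    def __init__(self, fold_idx, train_ids, test_ids, norm_vols, masks, cfg: PipelineConfig):
        self.idx = fold_idx
        self.train_ids, self.test_ids = train_ids, test_ids
        self.norm_vols, self.masks, self.cfg = norm_vols, masks, cfg
        self.grid_shape = norm_vols[train_ids[0]].shape
        self.tr_ids, self.val_ids = _train_val_split(
            train_ids, cfg.val_fraction, cfg.seed * 1000 + 17 + fold_idx
        )
        self.audit = {
            "fold": fold_idx,
            "train_ids": list(train_ids),
            "test_ids": list(test_ids),
        }
        self._cache = {}

    # -- stage 1 -----------------------------------------------------------
    def _loc_pairs(self, ids):
        """Localizer training pairs; the target is the reference mask dilated
        by ``loc_target_dilation`` voxels — the localizer learns a loose
        boundary around the organ, not its outline."""
        cfg = self.cfg
        pairs = []
        for i in ids:
            v = self.norm_vols[i]
            m = self.masks[i]
            if v.shape != cfg.loc_input_shape:
                v = resample(v, cfg.loc_input_shape)
                m = resample_mask(m, cfg.loc_input_shape)
            target = m.voxels
            if cfg.loc_target_dilation > 0:
                target = binary_dilation(
                    target, _STRUCT6, iterations=cfg.loc_target_dilation
                ).astype(np.float32)
            pairs.append((v.voxels, target))
        return pairs

    def _fit_with_restarts(self, build, train_pairs, val_pairs, lr, epochs, name):
        """Train, reinitializing on a stalled optimization (plateau init trap
        at batch size 1 is an occasional failure mode of the Dice loss)."""
        cfg = self.cfg
        model = history = None
        for attempt in range(cfg.train_restarts + 1):
            model = build(attempt)
            history = fit(
                model,
                train_pairs,
                val_pairs,
                TrainConfig(lr, 1, epochs, cfg.seed + self.idx + 7919 * attempt),
            )
            if min(history["train_loss"]) <= cfg.restart_loss_threshold:
                break
            self.audit[f"{name}_restarts"] = attempt + 1
        self.audit[f"{name}_best_epoch"] = history["best_epoch"]
        self.audit[f"{name}_min_val_loss"] = min(history["val_loss"])
        return model, history

    @property
    def localizer(self):
        if "localizer" not in self._cache:
            cfg = self.cfg
            self._cache["localizer"] = self._fit_with_restarts(
                lambda attempt: build_localizer(
                    LocalizerSpec(cfg.loc_input_shape, cfg.loc_channels),
                    seed=cfg.seed * 1000 + self.idx + 104729 * attempt,
                ),
                self._loc_pairs(self.tr_ids),
                self._loc_pairs(self.val_ids),
                cfg.loc_learning_rate,
                cfg.loc_epochs,
                "localizer",
            )
        return self._cache["localizer"][0]

    def localization(self, i):
        key = ("loc", i)
        if key not in self._cache:
            cfg = self.cfg
            try:
                res = localize(
                    self.localizer,
                    self.norm_vols[i],
                    cfg.seg_input_shape,
                    margin_voxels=cfg.box_margin,
                    mask_outside=cfg.mask_outside,
                )
            except LocalizationError as err:
                raise LocalizationError(f"fold {self.idx}, case {i}: {err}") from err
            self._cache[key] = res
        return self._cache[key]

    def seg_frame_mask(self, i) -> tuple[BinaryMask, object]:
        """Gold mask cropped and padded identically to the localized volume."""
        res = self.localization(i)
        cropped = crop(self.masks[i], res.box)
        padded, record = pad_to(cropped, self.cfg.seg_input_shape, 0)
        return padded, record

    def train_seg_pair(self, i):
        """(localized volume, seg-frame gold mask) for a *training* case.

        If the predicted box missed the target entirely (possible early in
        desk-scale training), fall back to the reference-label bounding box —
        training labels are available at training time, and an empty
        reference would make the Dice loss undefined. Test cases never use
        this path.
        """
        mask_frame, _ = self.seg_frame_mask(i)
        if mask_frame.count() > 0:
            return self.localization(i).localized.voxels, mask_frame.voxels
        cfg = self.cfg
        from .localizer import bounding_box_of, _shrink_box_to

        box = bounding_box_of(self.masks[i], cfg.box_margin)
        box = _shrink_box_to(box, cfg.seg_input_shape, self.grid_shape)
        vol_c = crop(self.norm_vols[i], box)
        msk_c = crop(self.masks[i], box)
        vol_p, _ = pad_to(vol_c, cfg.seg_input_shape, 0.0)
        msk_p, _ = pad_to(msk_c, cfg.seg_input_shape, 0)
        self.audit.setdefault("oracle_box_fallback_train_cases", []).append(i)
        return vol_p.voxels, msk_p.voxels

    def _jittered_pairs(self, i, n, rng):
        """Extra training crops with randomized margins around the reference
        box — teaches the U-net robustness to the localizer's box variability."""
        from .localizer import bounding_box_of, _shrink_box_to

        cfg = self.cfg
        gb = bounding_box_of(self.masks[i], 0)
        out = []
        for _ in range(n):
            lo = tuple(max(0, l - int(rng.integers(1, 8))) for l in gb.lo)
            hi = tuple(
                min(s - 1, h + int(rng.integers(1, 8)))
                for h, s in zip(gb.hi, self.grid_shape)
            )
            box = _shrink_box_to(
                BoundingBox(lo, hi), cfg.seg_input_shape, self.grid_shape
            )
            vol_p, _ = pad_to(crop(self.norm_vols[i], box), cfg.seg_input_shape, 0.0)
            msk_p, _ = pad_to(crop(self.masks[i], box), cfg.seg_input_shape, 0)
            out.append((vol_p.voxels, msk_p.voxels))
        return out

    # -- stage 2 -----------------------------------------------------------
    def _unet(self, whole: bool):
        key = "unet_whole" if whole else "unet_loc"
        if key not in self._cache:
            cfg = self.cfg

            def pair(i):
                if whole:
                    v = self.norm_vols[i]
                    m = self.masks[i]
                    if v.shape != cfg.seg_input_shape:
                        v = resample(v, cfg.seg_input_shape)
                        m = resample_mask(m, cfg.seg_input_shape)
                    return (v.voxels, m.voxels)
                return self.train_seg_pair(i)

            train_pairs = [pair(i) for i in self.tr_ids]
            if not whole and cfg.unet_crop_jitter > 0:
                jrng = np.random.default_rng(cfg.seed * 1000 + 31 + self.idx)
                for i in self.tr_ids:
                    train_pairs.extend(
                        self._jittered_pairs(i, cfg.unet_crop_jitter, jrng)
                    )
            model, _ = self._fit_with_restarts(
                lambda attempt: build_unet(
                    UNetSpec(cfg.seg_input_shape, cfg.unet_channels),
                    seed=cfg.seed * 1000 + 500 + self.idx
                    + (7000 if whole else 0) + 104729 * attempt,
                ),
                train_pairs,
                [pair(i) for i in self.val_ids],
                cfg.unet_learning_rate,
                cfg.unet_epochs,
                key,
            )
            self._cache[key] = model
        return self._cache[key]

    def soft_loc(self, i):
        key = ("soft_loc", i)
        if key not in self._cache:
            self._cache[key] = self._unet(False).predict(self.localization(i).localized.voxels)
        return self._cache[key]

    def soft_whole(self, i):
        key = ("soft_whole", i)
        if key not in self._cache:
            v = self.norm_vols[i]
            if v.shape != self.cfg.seg_input_shape:
                v = resample(v, self.cfg.seg_input_shape)
            self._cache[key] = self._unet(True).predict(v.voxels)
        return self._cache[key]

    # -- stage 3 -----------------------------------------------------------
    def cand_seg(self, i) -> np.ndarray:
        """Predicted candidate mask carried into the segmentation-crop frame."""
        res = self.localization(i)
        cand_c = crop(res.candidates, res.box)
        padded, _ = pad_to(cand_c, self.cfg.seg_input_shape, 0)
        return padded.voxels

    def case_prior(self, frame: str, i, soft: np.ndarray | None = None) -> np.ndarray:
        """The fold prior, optionally translation-aligned to case ``i``'s
        predicted region (soft map when available, else candidate mask)."""
        prior = self.prior_map(frame)
        if not self.cfg.prior_align:
            return prior
        if soft is not None:
            ref = np.where(soft > 0.3, soft, 0.0)
            if ref.sum() == 0:
                ref = None
        else:
            ref = None
        if ref is None:
            ref = (
                self.cand_seg(i)
                if frame == "seg"
                else self.localization(i).candidates.voxels
            )
        return align_prior_to(prior, ref, self.cfg.align_search_radius)

    def prior_map(self, frame: str) -> np.ndarray:
        """Morphology prior built from the training split's gold labels only,
        in the segmentation-crop frame or the whole-volume frame."""
        key = f"prior_{frame}"
        if key not in self._cache:
            cfg = self.cfg
            if frame == "seg":
                labels = [
                    BinaryMask(self.train_seg_pair(i)[1]) for i in self.train_ids
                ]
                target = cfg.seg_input_shape
            else:
                labels = [self.masks[i] for i in self.train_ids]
                target = self.grid_shape
            aligned, offsets = align_labels(labels, cfg.align_search_radius)
            prior = build_prior(aligned, cfg.prior_baseline, offsets)
            if cfg.prior_fusion == "coverage":
                cov = prior.coverage_map()
                if cfg.prior_smooth_sigma > 0:
                    # diffuse the atlas by ~the organ's cross-section radius:
                    # across-subject border uncertainty at finite n
                    cov = np.maximum(
                        gaussian_filter(cov, cfg.prior_smooth_sigma), cov.min()
                    )
                view = MorphologyPrior(
                    cov, prior.baseline, prior.n_labels, prior.offsets,
                )
            elif cfg.prior_fusion == "product":
                view = prior
            else:
                raise ValueError(f"unknown prior_fusion {cfg.prior_fusion!r}")
            self._cache[key] = match_prior(view, target)
            self.audit[f"{key}_n_labels"] = prior.n_labels
            self.audit[f"{key}_label_ids"] = list(self.train_ids)
        return self._cache[key]


def _combo_segmentation(fold: _Fold, i: int, combo, tau: float | None) -> BinaryMask:
    """Full-grid segmentation of case ``i`` under one factor combination."""
    use_loc, use_prior, use_unet = combo
    cfg = fold.cfg
    if use_loc and not use_unet and not use_prior:
        return fold.localization(i).candidates
    if use_loc and use_prior and not use_unet:
        prob = fold.localization(i).probability
        if prob.shape != fold.grid_shape:
            prob = resample(Volume(prob.astype(np.float32)), fold.grid_shape).voxels
        fused = fuse(prob, fold.case_prior("whole", i, prob))
        return segment(fused, tau)
    if use_unet and not use_loc:
        soft = fold.soft_whole(i)
        if use_prior:
            soft = fuse(soft, fold.prior_map("whole"))
        seg = segment(soft, tau)
        if seg.shape != fold.grid_shape:
            seg = resample_mask(seg, fold.grid_shape)
        return seg
    # localized U-net variants
    res = fold.localization(i)
    soft = fold.soft_loc(i)
    if use_prior:
        soft = fuse(soft, fold.case_prior("seg", i, soft))
    seg = segment(soft, tau)
    _, record = fold.seg_frame_mask(i)
    return _embed(seg, record, res.box, fold.grid_shape)


def _combo_score_map(fold: _Fold, i: int, combo, train: bool = False) -> np.ndarray | None:
    """The probability map thresholding operates on (None for box-only)."""
    use_loc, use_prior, use_unet = combo
    if use_loc and not use_unet and not use_prior:
        return None
    if use_loc and use_prior and not use_unet:
        prob = fold.localization(i).probability
        if prob.shape != fold.grid_shape:
            prob = resample(Volume(prob.astype(np.float32)), fold.grid_shape).voxels
        return fuse(prob, fold.case_prior("whole", i, prob))
    if use_unet and not use_loc:
        soft = fold.soft_whole(i)
        # no candidate region exists without the localizer; the prior is
        # applied at its population position
        return fuse(soft, fold.prior_map("whole")) if use_prior else soft
    if train:
        x, _ = fold.train_seg_pair(i)
        soft = fold._unet(False).predict(x)
    else:
        soft = fold.soft_loc(i)
    return fuse(soft, fold.case_prior("seg", i, soft)) if use_prior else soft


def _combo_reference(fold: _Fold, i: int, combo, train: bool = False) -> BinaryMask:
    """Reference mask in the frame the score map lives in."""
    use_loc, use_prior, use_unet = combo
    if use_unet and use_loc:
        if train:
            return BinaryMask(fold.train_seg_pair(i)[1])
        return fold.seg_frame_mask(i)[0]
    if (use_unet or use_prior) and not use_loc:
        m = fold.masks[i]
        if m.shape != fold.cfg.seg_input_shape and use_unet:
            m = resample_mask(m, fold.cfg.seg_input_shape)
        return m
    return fold.masks[i]


def _combo_threshold(fold: _Fold, combo) -> float | None:
    use_loc, use_prior, use_unet = combo
    if use_loc and not use_unet and not use_prior:
        return None
    key = ("tau", combo)
    if key not in fold._cache:
        pairs = [
            (
                _combo_score_map(fold, i, combo, train=True),
                _combo_reference(fold, i, combo, train=True),
            )
            for i in fold.train_ids
        ]
        fold._cache[key] = select_threshold(pairs, fold.cfg.threshold_grid_step)
        fold.audit[f"threshold_{''.join('YN'[not f] for f in combo)}"] = fold._cache[key]
    return fold._cache[key]


def _prepare(cohort):
    norm_vols, masks = [], []
    for vol, mask in cohort:
        norm_vols.append(normalize_unity(vol))
        masks.append(mask)
    return norm_vols, masks


def _make_folds(n_cases, cfg) -> FoldSplit:
    return make_folds(range(n_cases), k=cfg.n_folds, seed=cfg.seed)


def cross_validate(cohort, config: PipelineConfig | None = None) -> CVResult:
    """Fourfold cross-validation of the full three-stage pipeline.

    Reports, per fold and overall: localization TPR/TNR (box vs gold label,
    whole-grid convention), test DSC with the morphology prior (full
    pipeline) and without it (same pipeline, threshold selected on raw soft
    labels), and the selected thresholds.
    """
    cfg = config or PipelineConfig()
    norm_vols, masks = _prepare(cohort)
    splits = _make_folds(len(cohort), cfg)
    with_prior = (True, True, True)
    no_prior = (True, False, True)

    rows, audits = [], []
    for k in range(len(splits)):
        train_ids, test_ids = splits.split(k)
        fold = _Fold(k, train_ids, test_ids, norm_vols, masks, cfg)
        tau_p = _combo_threshold(fold, with_prior)
        tau_np = _combo_threshold(fold, no_prior)
        for i in test_ids:
            res = fold.localization(i)
            loc_m = localization_metrics(res.box, masks[i])
            seg_p = _combo_segmentation(fold, i, with_prior, tau_p)
            seg_np = _combo_segmentation(fold, i, no_prior, tau_np)
            rows.append(
                {
                    "fold": k,
                    "case": i,
                    "tpr": loc_m.tpr,
                    "tnr": loc_m.tnr,
                    "dsc_prior": dsc(seg_p, masks[i]),
                    "dsc_no_prior": dsc(seg_np, masks[i]),
                    "threshold": tau_p,
                    "threshold_no_prior": tau_np,
                }
            )
        audits.append(fold.audit)

    cases = pd.DataFrame(rows)
    fold_rows = []
    for k, grp in cases.groupby("fold"):
        fold_rows.append(
            {
                "fold": k,
                "n_test": len(grp),
                "tpr_mean": grp["tpr"].mean(),
                "tpr_min": grp["tpr"].min(),
                "tpr_max": grp["tpr"].max(),
                "tnr_mean": grp["tnr"].mean(),
                "tnr_min": grp["tnr"].min(),
                "tnr_max": grp["tnr"].max(),
                "dsc_mean": grp["dsc_prior"].mean(),
                "dsc_min": grp["dsc_prior"].min(),
                "dsc_max": grp["dsc_prior"].max(),
                "dsc_no_prior_mean": grp["dsc_no_prior"].mean(),
                "threshold": grp["threshold"].iloc[0],
            }
        )
    table = pd.DataFrame(fold_rows)
    mean_row = table.drop(columns=["fold"]).mean().to_dict()
    mean_row["fold"] = "mean"
    table = pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
    return CVResult(table, cases, audits)


def ablation(cohort, config: PipelineConfig | None = None, combos=ABLATION_COMBOS) -> pd.DataFrame:
    """DSC (min/max/mean over all held-out cases of all folds) for each
    factor combination (localization, prior, unet).

    Localizer-only uses the satellite-filtered candidate mask as the
    segmentation; combinations without localization run the U-net (and
    prior) on the whole volume.
    """
    combos = [tuple(c) for c in combos]
    for c in combos:
        if not (c[0] or c[2]):
            raise ValueError(f"combination {c} yields no segmentation")
    cfg = config or PipelineConfig()
    norm_vols, masks = _prepare(cohort)
    splits = _make_folds(len(cohort), cfg)
    scores = {c: [] for c in combos}
    for k in range(len(splits)):
        train_ids, test_ids = splits.split(k)
        fold = _Fold(k, train_ids, test_ids, norm_vols, masks, cfg)
        for combo in combos:
            tau = _combo_threshold(fold, combo)
            for i in test_ids:
                seg = _combo_segmentation(fold, i, combo, tau)
                scores[combo].append(dsc(seg, masks[i]))
    rows = []
    for combo in combos:
        s = np.asarray(scores[combo])
        rows.append(
            {
                "localization": "Yes" if combo[0] else "No",
                "prior": "Yes" if combo[1] else "No",
                "unet": "Yes" if combo[2] else "No",
                "dsc_min": float(s.min()),
                "dsc_max": float(s.max()),
                "dsc_mean": float(s.mean()),
            }
        )
    return pd.DataFrame(rows)
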