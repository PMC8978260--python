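import numpy as np
import pytest

from morphseg.localizer import (
    LocalizationError,
    LocalizerNet,
    LocalizerSpec,
    TrainConfig,
    binarize_candidates,
    bounding_box_of,
    build_localizer,
    localize,
    remove_satellites,
    train_localizer,
)
from morphseg.nn import fit
from morphseg.volume import BinaryMask, BoundingBox, Volume, normalize_unity


class TestArchitecture:
    def test_forward_preserves_shape_and_range(self, rng):
        spec = LocalizerSpec((32, 32, 32), (4, 8, 8, 8))
        model = build_localizer(spec, seed=0)
        out = model.predict(rng.random((32, 32, 32)).astype(np.float32))
        assert out.shape == (32, 32, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            LocalizerSpec((97, 96, 128))

    def test_upsample_factors_must_restore_shape(self):
        with pytest.raises(ValueError, match="multiply"):
            LocalizerSpec((96, 96, 128), upsample_factors=(2, 2, 2))

    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_localizer(LocalizerSpec((16, 16, 16), (2, 4, 4, 4)), seed=1)
        x = rng.random((16, 16, 16)).astype(np.float32)
        before = model.predict(x)
        model.save(tmp_path / "loc.npz")
        again = LocalizerNet.load(tmp_path / "loc.npz")
        np.testing.assert_array_equal(again.predict(x), before)


class TestTraining:
    def _pairs(self, rng, n=2, shape=(16, 16, 16)):
        pairs = []
        for _ in range(n):
            y = np.zeros(shape, dtype=np.float32)
            c = rng.integers(5, 11, size=3)
            y[c[0] - 2 : c[0] + 2, c[1] - 2 : c[1] + 2, c[2] - 2 : c[2] + 2] = 1
            x = y * 0.5 + rng.normal(0, 0.05, shape).astype(np.float32)
            pairs.append((x, y))
        return pairs

    def test_history_reproducible_under_fixed_seed(self, rng):
        pairs = self._pairs(rng)
        histories = []
        for _ in range(2):
            model = build_localizer(LocalizerSpec((16, 16, 16), (2, 4, 4, 4)), seed=3)
            _, h = train_localizer(model, pairs, [], TrainConfig(1e-3, 1, 5, seed=3))
            histories.append(h)
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        assert histories[0]["val_loss"] == histories[1]["val_loss"]

    def test_best_validation_state_kept(self, rng):
        pairs = self._pairs(rng, n=3)
        model = build_localizer(LocalizerSpec((16, 16, 16), (2, 4, 4, 4)), seed=0)
        _, h = train_localizer(model, pairs[:2], pairs[2:], TrainConfig(1e-3, 1, 15, seed=0))
        from morphseg.nn import _mean_loss

        returned_val = _mean_loss(model, pairs[2:])
        assert returned_val == pytest.approx(min(h["val_loss"]), abs=1e-9)
        assert returned_val <= h["val_loss"][-1] + 1e-12

    def test_empty_cohort_rejected(self):
        model = build_localizer(LocalizerSpec((16, 16, 16), (2, 4, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            fit(model, [], [], TrainConfig(1e-3, 1, 1))


class TestBinarize:
    def test_exact_half_is_background(self):
        prob = np.full((4, 4, 4), 0.5)
        assert binarize_candidates(prob).count() == 0

    def test_strict_threshold(self):
        prob = np.array([[[0.4, 0.6]]])
        np.testing.assert_array_equal(binarize_candidates(prob).voxels, [[[0, 1]]])

    def test_tau_zero_keeps_positives(self, rng):
        prob = rng.random((5, 5, 5))
        prob[0, 0, 0] = 0.0
        out = binarize_candidates(prob, tau=0.0)
        np.testing.assert_array_equal(out.voxels, (prob > 0).astype(np.uint8))


def _flood_fill_components(mask, neighbors):
    """Brute-force component labeling oracle (BFS flood fill)."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    coords = np.argwhere(mask)
    coord_set = {tuple(c) for c in coords}
    for start in map(tuple, coords):
        if seen[start]:
            continue
        comp, queue = [], [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.append(v)
            for d in neighbors:
                w = tuple(np.add(v, d))
                if w in coord_set and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(comp)
    return comps


class TestRemoveSatellites:
    NB6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

    def test_single_component_unchanged(self, phantom32):
        _, mask = phantom32
        out = remove_satellites(mask)
        np.testing.assert_array_equal(out.voxels, mask.voxels)

    def test_island_removed_matches_flood_fill_oracle(self, rng):
        m = np.zeros((16, 16, 16), dtype=np.uint8)
        m[2:7, 2:7, 2:6] = 1  # 100-voxel blob
        m[12, 12, 12:15] = 1  # 3-voxel satellite
        out = remove_satellites(BinaryMask(m))
        comps = _flood_fill_components(m, self.NB6)
        largest = max(comps, key=len)
        expected = np.zeros_like(m)
        for v in largest:
            expected[v] = 1
        np.testing.assert_array_equal(out.voxels, expected)
        assert out.count() == 100

    def test_tie_broken_by_scan_order(self):
        m = np.zeros((16, 16, 16), dtype=np.uint8)
        m[1, 1, 1:11] = 1  # first in scan order
        m[10, 10, 1:11] = 1  # same size, later
        out = remove_satellites(BinaryMask(m))
        assert out.voxels[1, 1, 1] == 1 and out.voxels[10, 10, 1] == 0

    def test_empty_stays_empty(self):
        out = remove_satellites(BinaryMask(np.zeros((4, 4, 4), dtype=np.uint8)))
        assert out.count() == 0

    def test_output_subset_single_component(self, rng):
        from scipy.ndimage import generate_binary_structure, label

        for _ in range(5):
            m = (rng.random((12, 12, 12)) < 0.2).astype(np.uint8)
            out = remove_satellites(BinaryMask(m))
            assert np.all(out.voxels <= m)
            if out.count():
                _, n = label(out.voxels, structure=generate_binary_structure(3, 1))
                assert n == 1


class TestBoundingBox:
    def test_single_voxel(self):
        m = np.zeros((8, 8, 8), dtype=np.uint8)
        m[2, 5, 3] = 1
        box = bounding_box_of(BinaryMask(m))
        assert box.lo == (2, 5, 3) and box.hi == (2, 5, 3)

    def test_full_grid(self):
        box = bounding_box_of(BinaryMask(np.ones((4, 5, 6), dtype=np.uint8)))
        assert box.lo == (0, 0, 0) and box.hi == (3, 4, 5)

    def test_margin_clamped_at_edge(self):
        m = np.zeros((10, 10, 10), dtype=np.uint8)
        m[0, 1, 9] = 1
        m[4, 6, 5] = 1
        box = bounding_box_of(BinaryMask(m), margin_voxels=2)
        assert box.lo == (0, 0, 3) and box.hi == (6, 8, 9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bounding_box_of(BinaryMask(np.zeros((4, 4, 4), dtype=np.uint8)))


class _OracleModel:
    """Stand-in localizer emitting the ground-truth mask as probability."""

    def __init__(self, mask, input_shape):
        self.mask = mask
        self.spec = LocalizerSpec(input_shape, (4, 8, 8, 8))

    def predict(self, x):
        return self.mask.voxels.astype(np.float32)


class TestLocalize:
    def test_oracle_model_box_contains_truth(self, phantom32):
        vol, mask = phantom32
        model = _OracleModel(mask, (32, 32, 32))
        res = localize(model, normalize_unity(vol), (32, 32, 32))
        from morphseg.evaluation import localization_metrics

        assert localization_metrics(res.box, mask).tpr == 1.0

    def test_output_shape_is_seg_input_shape(self, phantom32):
        vol, mask = phantom32
        model = _OracleModel(mask, (32, 32, 32))
        res = localize(model, normalize_unity(vol), (32, 32, 32))
        assert res.localized.shape == (32, 32, 32)

    def test_box_contains_candidates(self, phantom32):
        vol, mask = phantom32
        model = _OracleModel(mask, (32, 32, 32))
        res = localize(model, normalize_unity(vol), (32, 32, 32), margin_voxels=1)
        inside = res.candidates.voxels[res.box.slices()]
        assert inside.sum() == res.candidates.count()

    def test_empty_prediction_raises(self, phantom32):
        vol, mask = phantom32
        empty = BinaryMask(np.zeros((32, 32, 32), dtype=np.uint8))
        model = _OracleModel(empty, (32, 32, 32))
        with pytest.raises(LocalizationError, match="localization failed"):
            localize(model, normalize_unity(vol), (32, 32, 32))

    def test_mask_outside_zeroes_nontarget(self, phantom32):
        vol, mask = phantom32
        model = _OracleModel(mask, (32, 32, 32))
        nv = normalize_unity(vol)
        res = localize(model, nv, (32, 32, 32), mask_outside=True)
        from morphseg.volume import crop

        inside = crop(mask, res.box).voxels.astype(bool)
        from morphseg.volume import unpad

        loc = unpad(res.localized, res.pad_record)
        assert not loc.voxels[~inside].any()
        np.testing.assert_array_equal(
            loc.voxels[inside], crop(nv, res.box).voxels[inside]
        )
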