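"""Dataset scanning, filtering, windowing, loading, augmentation, folds."""

from pathlib import Path

import numpy as np
import pytest
from PIL import Image

from polypnextlstm.data import (
    ClipRecord,
    WindowIndex,
    augment_window,
    draw_augment_params,
    first_clip_per_polyp,
    load_window,
    make_folds,
    make_windows,
    scan_dataset,
)


def fake_record(clip_id, case_id, n=10):
    paths = tuple(Path(f"/x/{clip_id}/{i}.png") for i in range(n))
    return ClipRecord(clip_id, case_id, paths, paths)


# ---------------------------------------------------------------------------
# scanning


class TestScan:
    def test_scan_finds_clips_and_attributes(self, dataset_root):
        records = scan_dataset(dataset_root)
        assert [len(r) for r in records] == [8] * 6
        assert all(r.clip_id.startswith("case") for r in records)
        assert any(r.attributes for r in records)

    def test_missing_mask_is_hard_error(self, tmp_path):
        fdir = tmp_path / "caseA_clip1" / "frames"
        fdir.mkdir(parents=True)
        (tmp_path / "caseA_clip1" / "masks").mkdir()
        Image.new("RGB", (8, 8)).save(fdir / "0.png")
        with pytest.raises(FileNotFoundError, match="0.png"):
            scan_dataset(tmp_path)

    def test_empty_clip_skipped_with_warning(self, tmp_path):
        (tmp_path / "caseA_clip1" / "frames").mkdir(parents=True)
        with pytest.warns(UserWarning, match="no frames"):
            assert scan_dataset(tmp_path) == []

    def test_attribute_csv_parsing(self, tmp_path):
        fdir = tmp_path / "clip3" / "frames"
        mdir = tmp_path / "clip3" / "masks"
        fdir.mkdir(parents=True)
        mdir.mkdir()
        Image.new("RGB", (8, 8)).save(fdir / "0.png")
        Image.new("L", (8, 8)).save(mdir / "0.png")
        (tmp_path / "attributes.csv").write_text(
            "clip_id,attributes\nclip3,FM;SO\n"
        )
        (rec,) = scan_dataset(tmp_path)
        assert rec.attributes == {"FM", "SO"}


# ---------------------------------------------------------------------------
# first clip per polyp


class TestFirstClipFilter:
    def test_keeps_first_clip_of_each_case(self):
        recs = [fake_record("a2", "A"), fake_record("a1", "A"),
                fake_record("b1", "B")]
        kept = first_clip_per_polyp(recs)
        assert [r.clip_id for r in kept] == ["a1", "b1"]

    def test_identity_when_all_distinct(self):
        recs = [fake_record(f"c{i}", f"P{i}") for i in range(4)]
        assert first_clip_per_polyp(recs) == sorted(
            recs, key=lambda r: r.clip_id
        )

    def test_51_polyps_with_multiple_clips(self, rng):
        recs = []
        for p in range(51):
            for c in range(int(rng.integers(1, 4))):
                recs.append(fake_record(f"p{p:03d}_clip{c}", f"p{p:03d}"))
        kept = first_clip_per_polyp(recs)
        assert len(kept) == 51
        assert all(r.clip_id.endswith("clip0") for r in kept)


# ---------------------------------------------------------------------------
# windowing


class TestWindows:
    @pytest.mark.parametrize("n,f,expected", [
        (12, 5, [0, 5, 7]),   # end-anchored remainder window
        (10, 5, [0, 5]),
        (5, 5, [0]),
        (7, 3, [0, 3, 4]),
        (6, 1, [0, 1, 2, 3, 4, 5]),
    ])
    def test_start_positions(self, n, f, expected):
        wins = make_windows(fake_record("c", "c", n), f)
        assert [w.start for w in wins] == expected
        assert all(w.length == f for w in wins)

    def test_every_frame_covered(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            f = int(rng.integers(1, 6))
            covered = np.zeros(n, bool)
            for w in make_windows(fake_record("c", "c", n), f):
                assert 0 <= w.start and w.start + f <= n
                covered[w.start:w.start + f] = True
            assert covered.all()

    def test_short_clip_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            assert make_windows(fake_record("c", "c", 3), 5) == []

    def test_overlapping_stride(self):
        wins = make_windows(fake_record("c", "c", 7), 5, stride=1)
        assert [w.start for w in wins] == [0, 1, 2]


# ---------------------------------------------------------------------------
# loading


class TestLoadWindow:
    def test_resize_and_layout(self, dataset_root):
        rec = scan_dataset(dataset_root)[0]
        frames, masks = load_window(rec, WindowIndex(rec.clip_id, 0, 5),
                                    size=(32, 48))
        assert frames.shape == (5, 3, 32, 48)
        assert frames.dtype == np.float32
        assert 0.0 <= frames.min() and frames.max() <= 1.0
        assert masks.shape == (5, 32, 48)
        assert masks.dtype == bool

    def test_mask_fraction_preserved_under_resize(self, dataset_root):
        # smooth ellipse blobs: area fraction within 2 points after resize
        for rec in scan_dataset(dataset_root)[:3]:
            win = WindowIndex(rec.clip_id, 0, 1)
            _, small = load_window(rec, win, size=(32, 32))
            _, native = load_window(rec, win, size=(64, 64))
            assert small.mean() == pytest.approx(native.mean(), abs=0.02)

    def test_imagenet_normalization(self, dataset_root):
        rec = scan_dataset(dataset_root)[0]
        win = WindowIndex(rec.clip_id, 0, 1)
        unit, _ = load_window(rec, win, size=(32, 32), normalize="unit")
        std, _ = load_window(rec, win, size=(32, 32), normalize="imagenet")
        from polypnextlstm.data import IMAGENET_MEAN, IMAGENET_STD

        back = std * IMAGENET_STD[:, None, None] + IMAGENET_MEAN[:, None, None]
        np.testing.assert_allclose(back, unit, atol=1e-5)

    def test_unknown_normalization_rejected(self, dataset_root):
        rec = scan_dataset(dataset_root)[0]
        with pytest.raises(ValueError, match="normalization"):
            load_window(rec, WindowIndex(rec.clip_id, 0, 1), normalize="bad")


# ---------------------------------------------------------------------------
# augmentation


def disc_window(n_frames=5, size=64, radius=10):
    yy, xx = np.mgrid[0:size, 0:size]
    disc = ((yy - size / 2) ** 2 + (xx - size / 2) ** 2) < radius**2
    frame = np.where(disc, 0.9, 0.1).astype(np.float32)
    frames = np.stack([np.stack([frame] * 3)] * n_frames)
    masks = np.stack([disc] * n_frames)
    return frames, masks


class TestAugmentation:
    def test_deterministic_under_seed(self):
        frames, masks = disc_window()
        f1, m1 = augment_window(frames, masks, seed=5)
        f2, m2 = augment_window(frames, masks, seed=5)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(m1, m2)

    def test_single_draw_shared_by_all_frames(self):
        # identical input frames must stay identical after augmentation
        frames, masks = disc_window()
        for seed in range(10):
            af, am = augment_window(frames, masks, seed=seed)
            for t in range(1, frames.shape[0]):
                np.testing.assert_array_equal(af[t], af[0])
                np.testing.assert_array_equal(am[t], am[0])

    def test_parameter_draw_is_deterministic(self):
        p1 = draw_augment_params(np.random.default_rng(3))
        p2 = draw_augment_params(np.random.default_rng(3))
        assert p1 == p2

    def test_mask_stays_aligned_with_frame(self):
        # re-detect the bright disc in the augmented frame; it must overlap
        # the augmented mask almost perfectly
        frames, masks = disc_window(size=96, radius=24)
        for seed in range(8):
            af, am = augment_window(frames, masks, seed=seed)
            detected = af[0, 0] > 0.5
            inter = np.logical_and(detected, am[0]).sum()
            union = np.logical_or(detected, am[0]).sum()
            assert inter / union >= 0.95

    def test_mask_remains_binary(self):
        frames, masks = disc_window()
        _, am = augment_window(frames, masks, seed=1)
        assert am.dtype == bool


# ---------------------------------------------------------------------------
# folds


class TestFolds:
    def test_disjoint_partition_covering_all_clips(self):
        recs = [fake_record(f"c{i}", f"c{i}") for i in range(10)]
        folds = make_folds(recs, k=5, seed=0)
        assert len(folds) == 5
        all_val = []
        for train, val in folds:
            assert len(val) == 2
            assert {r.clip_id for r in train}.isdisjoint(
                {r.clip_id for r in val}
            )
            all_val += [r.clip_id for r in val]
        assert sorted(all_val) == [r.clip_id for r in recs]

    def test_same_seed_same_partition(self):
        recs = [fake_record(f"c{i}", f"c{i}") for i in range(7)]
        f1 = make_folds(recs, k=3, seed=11)
        f2 = make_folds(recs, k=3, seed=11)
        for (_, v1), (_, v2) in zip(f1, f2):
            assert [r.clip_id for r in v1] == [r.clip_id for r in v2]

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            make_folds([fake_record("a", "a")], k=5, seed=0)
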