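"""Manifest parsing, clip assembly, procedure splitting, batch sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image

from metacvs import dataset_io as dio
from metacvs.dataset_io import (FrameRecord, TOY_ONTOLOGY, clip_anchor_indices,
                                largest_remainder_counts, load_manifest,
                                sample_mixed_batch, split_by_procedure)
from metacvs.exceptions import ConfigError, DataError


def _write_frame(root, name, size=8, mask_values=None):
    img = Image.fromarray(np.zeros((size, size, 3), dtype=np.uint8))
    img.save(root / f"{name}.png")
    if mask_values is not None:
        arr = np.zeros((size, size), dtype=np.uint8)
        arr.flat[:len(mask_values)] = mask_values
        Image.fromarray(arr, mode="L").save(root / f"{name}_mask.png")


def _manifest(root, rows):
    df = pd.DataFrame(rows, columns=dio.MANIFEST_COLUMNS)
    path = root / "manifest.csv"
    df.to_csv(path, index=False)
    return path


class TestLoadManifest:
    def test_rows_map_to_records_with_optional_masks(self, tmp_path):
        for i in range(3):
            _write_frame(tmp_path, f"f{i}", mask_values=[1] if i == 0 else None)
        rows = [["p1", i, f"f{i}.png", "f0_mask.png" if i == 0 else "", 1, 0, 1]
                for i in range(3)]
        records = load_manifest(_manifest(tmp_path, rows), TOY_ONTOLOGY)
        assert len(records) == 3
        assert sum(r.mask_path is not None for r in records) == 1
        assert records[0].criteria == (True, False, True)

    def test_empty_manifest_gives_empty_list(self, tmp_path):
        records = load_manifest(_manifest(tmp_path, []), TOY_ONTOLOGY)
        assert records == []

    def test_out_of_ontology_mask_value_is_named(self, tmp_path):
        _write_frame(tmp_path, "f0", mask_values=[9])
        rows = [["p1", 0, "f0.png", "f0_mask.png", 0, 0, 0]]
        with pytest.raises(DataError, match="9"):
            load_manifest(_manifest(tmp_path, rows), TOY_ONTOLOGY)

    def test_missing_image_names_row(self, tmp_path):
        rows = [["p1", 0, "nope.png", "", 0, 0, 0]]
        with pytest.raises(DataError, match="row 0"):
            load_manifest(_manifest(tmp_path, rows), TOY_ONTOLOGY)

    def test_duplicate_timestamp_rejected(self, tmp_path):
        _write_frame(tmp_path, "f0")
        rows = [["p1", 0, "f0.png", "", 0, 0, 0]] * 2
        with pytest.raises(DataError, match="duplicate"):
            load_manifest(_manifest(tmp_path, rows), TOY_ONTOLOGY)


def _records(timestamps, pid="p1"):
    return [FrameRecord(pid, t, f"/x/{pid}_{t}.png", None, (False, False, False))
            for t in timestamps]


def _window_oracle(timestamps, frame_length):
    """Brute-force count of anchors with a full contiguous history."""
    tset = set(timestamps)
    return sum(all(t - d in tset for d in range(frame_length))
               for t in timestamps)


class TestClipAssembly:
    def test_contiguous_run_anchor_count(self):
        idx = clip_anchor_indices(_records(range(8)), 6)
        assert len(idx) == 3           # anchors at t = 5, 6, 7
        assert [i[-1] for i in idx] == [5, 6, 7]

    def test_frame_length_one_gives_one_clip_per_record(self):
        assert len(clip_anchor_indices(_records(range(5)), 1)) == 5

    def test_gap_invalidates_spanning_anchors(self):
        ts = [0, 1, 2, 3, 5, 6, 7, 8]   # missing t=4
        idx = clip_anchor_indices(_records(ts), 6)
        assert len(idx) == _window_oracle(ts, 6) == 0

    @given(st.sets(st.integers(0, 30), min_size=1, max_size=25),
           st.integers(1, 7))
    @settings(max_examples=60, deadline=None)
    def test_anchor_count_matches_sliding_window_oracle(self, tset, L):
        ts = sorted(tset)
        idx = clip_anchor_indices(_records(ts), L)
        assert len(idx) == _window_oracle(ts, L)
        for lst in idx:
            assert len(lst) == L

    def test_invalid_frame_length_rejected(self):
        with pytest.raises(ConfigError):
            clip_anchor_indices(_records([0]), 0)

    def test_repeat_first_pads_early_anchors(self):
        idx = clip_anchor_indices(_records(range(3)), 4, pad_mode="repeat_first")
        assert len(idx) == 3
        assert idx[0] == [0, 0, 0, 0]
        assert idx[2] == [0, 0, 1, 2]

    def test_assembly_is_deterministic(self):
        ts = [0, 1, 2, 3, 7, 8, 9]
        a = clip_anchor_indices(_records(ts), 3)
        b = clip_anchor_indices(_records(ts), 3)
        assert a == b


class TestSplitting:
    def test_ten_procedures_split_7_1_2(self):
        pids = [f"p{i}" for i in range(10)]
        for seed in (0, 1, 99):
            asg = split_by_procedure(pids, seed)
            sizes = [len(asg.procedures(s)) for s in ("train", "val", "test")]
            assert sizes == [7, 1, 2]

    def test_single_procedure_goes_to_train_with_warning(self):
        with pytest.warns(UserWarning):
            asg = split_by_procedure(["only"], 0)
        assert asg.mapping == {"only": "train"}

    def test_106_procedures_largest_remainder(self):
        pids = [f"p{i}" for i in range(106)]
        asg = split_by_procedure(pids, 3)
        sizes = [len(asg.procedures(s)) for s in ("train", "val", "test")]
        assert sizes == [74, 11, 21]

    @given(st.integers(3, 200), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_proportions_match_arithmetic_oracle(self, npids, seed):
        pids = [f"p{i}" for i in range(npids)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            asg = split_by_procedure(pids, seed)
        sizes = [len(asg.procedures(s)) for s in ("train", "val", "test")]
        assert sizes == largest_remainder_counts(npids, [0.7, 0.1, 0.2])
        assert sum(sizes) == npids
        # no procedure in more than one split
        assert set(asg.mapping) == set(pids)

    def test_split_is_pure_function_of_ids_and_seed(self):
        pids = [f"p{i}" for i in range(20)]
        a = split_by_procedure(pids, 7).mapping
        b = split_by_procedure(list(reversed(pids)), 7).mapping
        assert a == b

    def test_split_file_round_trip(self, tmp_path):
        asg = split_by_procedure([f"p{i}" for i in range(12)], 0)
        path = tmp_path / "split.csv"
        asg.save(path)
        first = path.read_bytes()
        loaded = dio.SplitAssignment.load(path)
        assert loaded.mapping == asg.mapping
        loaded.save(path)
        assert path.read_bytes() == first


class TestMixedBatch:
    def test_ratio_5_3_at_batch_16(self, clip_factory):
        clips = [clip_factory(True) for _ in range(12)] + \
                [clip_factory(False) for _ in range(8)]
        rng = np.random.default_rng(0)
        batch = sample_mixed_batch(clips, 10, 6, rng)
        assert batch.m == 10 and batch.n == 6
        assert all(c.is_dual for c in batch.dual_samples)
        assert not any(c.is_dual for c in batch.primary_only_samples)

    def test_all_dual_ratio(self, clip_factory):
        clips = [clip_factory(True) for _ in range(6)]
        batch = sample_mixed_batch(clips, 4, 0, np.random.default_rng(0))
        assert batch.n == 0 and batch.m == 4

    def test_insufficient_dual_clips_suggests_lowering_m(self, clip_factory):
        clips = [clip_factory(True) for _ in range(4)] + \
                [clip_factory(False) for _ in range(10)]
        with pytest.raises(DataError, match="lower m"):
            sample_mixed_batch(clips, 10, 2, np.random.default_rng(0))

    def test_draw_reproducible_from_rng_state(self, clip_factory):
        clips = [clip_factory(True) for _ in range(8)] + \
                [clip_factory(False) for _ in range(8)]
        b1 = sample_mixed_batch(clips, 3, 3, np.random.default_rng(42))
        b2 = sample_mixed_batch(clips, 3, 3, np.random.default_rng(42))
        ids1 = [(c.procedure_id, c.timestamp_s, id(c)) for c in b1.all_samples]
        ids2 = [(c.procedure_id, c.timestamp_s, id(c)) for c in b2.all_samples]
        assert ids1 == ids2

    def test_no_replacement_within_batch(self, clip_factory):
        clips = [clip_factory(True) for _ in range(8)]
        batch = sample_mixed_batch(clips, 8, 0, np.random.default_rng(0))
        assert len({id(c) for c in batch.dual_samples}) == 8
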