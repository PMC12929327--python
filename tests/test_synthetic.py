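"""Generator contracts: label-mask consistency (against an independent
pixel-level oracle), determinism, rate bands, mask partitioning."""

import collections

import numpy as np
import pytest
from PIL import Image

from metacvs.dataset_io import load_mask
from metacvs.exceptions import ConfigError
from metacvs.synthetic import (BG, DUCT_C, ORGAN_A, ORGAN_B, SceneConfig,
                               criteria_from_mask, derive_criteria,
                               generate_dataset, procedure_states, rasterize)


# ---------------------------------------------------------------------------
# independent pixel-level oracle (no scipy): brute-force distances + BFS
# ---------------------------------------------------------------------------

def _pix(mask, value):
    return np.argwhere(mask == value)


def _min_dist(a_pts, b_pts):
    if len(a_pts) == 0 or len(b_pts) == 0:
        return np.inf
    best = np.inf
    for p in a_pts:
        d2 = ((b_pts - p) ** 2).sum(axis=1)
        best = min(best, float(d2.min()))
    return np.sqrt(best)


def _boundary(mask, value):
    h, w = mask.shape
    pts = []
    for r, c in _pix(mask, value):
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w) or mask[rr, cc] != value:
                pts.append((r, c))
                break
    return np.array(pts) if pts else np.zeros((0, 2), dtype=int)


def _components(mask, value):
    """8-connected components by breadth-first flood fill."""
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    comps = []
    for r0, c0 in _pix(mask, value):
        if seen[r0, c0]:
            continue
        comp = []
        queue = collections.deque([(r0, c0)])
        seen[r0, c0] = True
        while queue:
            r, c = queue.popleft()
            comp.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < h and 0 <= cc < w and not seen[rr, cc]
                            and mask[rr, cc] == value):
                        seen[rr, cc] = True
                        queue.append((rr, cc))
        comps.append(np.array(comp))
    return comps


def oracle_criteria(mask, cfg: SceneConfig):
    a, b = _pix(mask, ORGAN_A), _pix(mask, ORGAN_B)
    if len(a) == 0 or len(b) == 0:
        return (False, False, False)
    c1 = _min_dist(b, a) > cfg.c1_clearance_px
    bound = _boundary(mask, ORGAN_B)
    contact = np.mean([_min_dist(np.array([p]), a) <= cfg.c2_contact_tol_px
                       for p in bound])
    c2 = contact < cfg.c2_max_contact_frac
    touching = sum(_min_dist(comp, b) <= cfg.c3_touch_tol_px
                   for comp in _components(mask, DUCT_C))
    return (bool(c1), bool(c2), touching == 2)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestCriteria:
    def test_agrees_with_pixel_oracle_on_seeded_scenes(self):
        cfg = SceneConfig(seed=17, n_procedures=100, frames_per_procedure=1)
        for p in range(40):
            state = procedure_states(cfg, p)[0]
            mask = rasterize(state, cfg.image_size)
            assert criteria_from_mask(mask, cfg) == oracle_criteria(mask, cfg), \
                f"procedure {p} disagrees with the pixel oracle"

    def test_no_ducts_means_c3_false(self):
        cfg = SceneConfig(seed=0)
        state = procedure_states(cfg, 0)[0]
        state.ducts = []
        assert derive_criteria(state, cfg)[2] is False

    def test_criteria_deterministic(self):
        cfg = SceneConfig(seed=3)
        s1 = procedure_states(cfg, 1)
        s2 = procedure_states(cfg, 1)
        assert [st.criteria for st in s1] == [st.criteria for st in s2]


class TestGenerateDataset:
    def test_counts_and_mask_fraction(self, tmp_path):
        cfg = SceneConfig(n_procedures=4, frames_per_procedure=30,
                          dual_label_fraction=0.2, seed=2)
        records = generate_dataset(cfg, tmp_path)
        assert len(records) == 120
        assert sum(r.mask_path is not None for r in records) == 24

    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SceneConfig(n_procedures=2, frames_per_procedure=4, seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(cfg, d1)
        generate_dataset(cfg, d2)
        for rel in sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file()):
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_full_dual_fraction_masks_everything(self, tmp_path):
        cfg = SceneConfig(n_procedures=2, frames_per_procedure=3,
                          dual_label_fraction=1.0, seed=1)
        records = generate_dataset(cfg, tmp_path)
        assert all(r.mask_path is not None for r in records)

    def test_label_mask_consistency_on_every_masked_frame(self, small_dataset):
        cfg, _, records = small_dataset
        for r in records:
            if r.mask_path is None:
                continue
            mask = load_mask(r.mask_path)
            assert criteria_from_mask(mask, cfg) == r.criteria

    def test_masks_partition_the_image(self, small_dataset):
        cfg, _, records = small_dataset
        h, w = cfg.image_size
        for r in records:
            if r.mask_path is None:
                continue
            mask = load_mask(r.mask_path)
            vals, counts = np.unique(mask, return_counts=True)
            assert set(vals) <= {BG, ORGAN_A, ORGAN_B, DUCT_C}
            assert counts.sum() == h * w

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError):
            SceneConfig(dual_label_fraction=1.5)


class TestRateBands:
    def test_positive_rates_within_bands(self):
        """1000 frames: each criterion's base rate in its design band."""
        crits = []
        cfg = SceneConfig(seed=123, n_procedures=100, frames_per_procedure=10)
        for p in range(100):
            crits += [st.criteria for st in procedure_states(cfg, p)]
        rates = np.mean(np.array(crits), axis=0)
        assert 0.25 <= rates[0] <= 0.55      # separation predicate
        assert 0.50 <= rates[1] <= 0.90      # exposure predicate
        assert 0.20 <= rates[2] <= 0.60      # counting predicate

    def test_criteria_invariant_under_dihedral_transforms(self):
        """Flips and right-angle rotations preserve the distance/count
        predicates, the property that makes training-time augmentation exact."""
        cfg = SceneConfig(seed=31, n_procedures=10, frames_per_procedure=1)
        for p in range(10):
            state = procedure_states(cfg, p)[0]
            mask = rasterize(state, cfg.image_size)
            ref = criteria_from_mask(mask, cfg)
            for k in range(4):
                assert criteria_from_mask(np.rot90(mask, k).copy(), cfg) == ref
            assert criteria_from_mask(mask[:, ::-1].copy(), cfg) == ref

    def test_shapes_stay_inside_the_image(self):
        cfg = SceneConfig(seed=7, n_procedures=10, frames_per_procedure=10)
        border = np.zeros(cfg.image_size, dtype=bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        for p in range(10):
            for st in procedure_states(cfg, p):
                mask = rasterize(st, cfg.image_size)
                assert not (mask[border] != BG).any()
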