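import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hippomvpa import (
    RoiMask,
    SearchlightSpec,
    SelectionRule,
    cross_decode,
    loo_decode,
    make_blob_mask,
    searchlight_neighborhood,
    searchlight_scores,
    select_features,
    sphere_offsets,
)
from hippomvpa.glm import BetaSeries


def _brute_force_offsets(radius):
    out = set()
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dz in range(-radius, radius + 1):
                if dx * dx + dy * dy + dz * dz <= radius * radius:
                    out.add((dx, dy, dz))
    return out


class TestSphereGeometry:
    @pytest.mark.parametrize("radius,size", [(0, 1), (1, 7), (2, 33), (3, 123)])
    def test_offset_counts_match_enumeration(self, radius, size):
        offs = sphere_offsets(radius)
        assert offs == _brute_force_offsets(radius)
        assert len(offs) == size
        assert (0, 0, 0) in offs

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            sphere_offsets(-1)

    def test_single_voxel_mask_neighborhood(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        nb = searchlight_neighborhood((2, 2, 2), SearchlightSpec(RoiMask(data), 3))
        assert nb == {(2, 2, 2)}

    def test_deep_interior_full_sphere(self):
        data = np.ones((9, 9, 9), dtype=bool)
        nb = searchlight_neighborhood((4, 4, 4), SearchlightSpec(RoiMask(data), 3))
        assert len(nb) == 123

    def test_flat_face_strictly_clipped(self):
        data = np.ones((9, 9, 9), dtype=bool)
        data[:, :, 5:] = False  # face at z = 4
        nb = searchlight_neighborhood((4, 4, 4), SearchlightSpec(RoiMask(data), 3))
        assert len(nb) < 123

    def test_center_outside_mask_rejected(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[0, 0, 0] = True
        with pytest.raises(ValueError, match="outside"):
            searchlight_neighborhood((2, 2, 2), SearchlightSpec(RoiMask(data), 3))

    @given(st.integers(0, 10_000))
    def test_neighborhood_contained_in_mask(self, seed):
        mask = make_blob_mask((8, 8, 6), 14, seed=seed)
        spec = SearchlightSpec(mask, 3)
        inside = set(map(tuple, mask.coords()))
        for center in list(inside)[:5]:
            assert searchlight_neighborhood(center, spec) <= inside


class TestSearchlightScores:
    def test_two_trial_one_voxel_toy_scores_one(self):
        # both leave-one-out folds train on a single opposite-class trial
        # at x = ∓2 and must place the held-out trial on the other side
        data = np.zeros((3, 3, 3), dtype=bool)
        data[1, 1, 1] = True
        mask = RoiMask(data)
        betas = BetaSeries(np.array([[2.0], [-2.0]]), np.arange(2), np.array([[1, 1, 1]]))
        scores = searchlight_scores(
            betas, np.array(["A", "B"]), SearchlightSpec(mask, 3),
            standardize=False,
        )
        assert scores == {(1, 1, 1): 1.0}

    def test_pure_noise_scores_near_chance(self, toy_betas):
        # single-dataset scores are highly variable (folds and centres are
        # correlated), so average over replicate null datasets; a small
        # leave-one-out pessimism relative to exactly 0.5 is expected
        mask = make_blob_mask((10, 10, 8), 10, seed=1)
        spec = SearchlightSpec(mask, 3)
        means = []
        for rep in range(15):
            betas, labels = toy_betas(mask, 20, 0.0, 1.0, seed=200 + rep)
            scores = searchlight_scores(betas, labels, spec)
            means.append(np.mean(list(scores.values())))
        assert abs(np.mean(means) - 0.5) < 0.12

    def test_duplicating_trials_does_not_degrade_scores(self, toy_betas):
        mask = make_blob_mask((8, 8, 6), 6, seed=3)
        betas, labels = toy_betas(mask, 2, 3.0, 0.3, seed=4)
        spec = SearchlightSpec(mask, 3)
        base = searchlight_scores(betas, labels, spec)
        dup = BetaSeries(
            np.repeat(betas.betas, 2, axis=0),
            np.arange(2 * betas.n_trials),
            betas.voxel_coords,
        )
        doubled = searchlight_scores(dup, np.repeat(labels, 2), spec)
        for c in base:
            assert doubled[c] >= 0.5
            assert doubled[c] >= base[c] - 1e-12

    def test_single_class_rejected(self, small_mask, toy_betas):
        betas, _ = toy_betas(small_mask, 3, 1.0, 1.0, seed=5)
        with pytest.raises(ValueError, match="two classes"):
            searchlight_scores(
                betas, np.repeat(["A"], 6), SearchlightSpec(small_mask, 3)
            )


class TestSelectFeatures:
    def _spec(self, n_vox=40, seed=0):
        mask = make_blob_mask((12, 12, 8), n_vox, seed=seed)
        return SearchlightSpec(mask, 3), mask

    def test_tied_scores_pick_lexicographically_first(self):
        spec, mask = self._spec()
        scores = {tuple(c): 0.7 for c in mask.coords()}
        sel = select_features(scores, spec, SelectionRule("single_best"))
        first = min(scores)
        assert sel == searchlight_neighborhood(first, spec)

    def test_single_peak_selects_its_neighborhood(self):
        spec, mask = self._spec()
        coords = [tuple(c) for c in mask.coords()]
        peak = coords[len(coords) // 2]
        scores = {c: (1.0 if c == peak else 0.0) for c in coords}
        sel = select_features(scores, spec, SelectionRule("single_best"))
        assert sel == searchlight_neighborhood(peak, spec)

    def test_default_rule_on_ca1_sized_roi_selects_about_160(self):
        mask = make_blob_mask((20, 20, 14), 267, seed=6)
        spec = SearchlightSpec(mask, 3)
        rng = np.random.default_rng(7)
        scores = {tuple(c): float(rng.random()) for c in mask.coords()}
        sel = select_features(scores, spec)
        assert 140 <= len(sel) <= 190

    def test_union_always_within_mask(self):
        spec, mask = self._spec(seed=8)
        rng = np.random.default_rng(9)
        scores = {tuple(c): float(rng.random()) for c in mask.coords()}
        sel = select_features(scores, spec)
        assert sel <= set(map(tuple, mask.coords()))

    def test_empty_scores_rejected(self):
        spec, _ = self._spec()
        with pytest.raises(ValueError, match="empty"):
            select_features({}, spec)


class TestLooDecode:
    def test_strong_signal_high_accuracy(self, toy_betas):
        mask = make_blob_mask((10, 10, 8), 12, seed=10)
        betas, labels = toy_betas(mask, 10, 3.0, 1.0, seed=11)
        res = loo_decode(betas, labels, SearchlightSpec(mask, 3))
        assert res.accuracy >= 0.9
        assert res.n_test == 20
        assert len(res.folds) == 20

    def test_selected_voxels_inside_mask_and_counted(self, toy_betas):
        mask = make_blob_mask((10, 10, 8), 12, seed=12)
        betas, labels = toy_betas(mask, 5, 2.0, 1.0, seed=13)
        res = loo_decode(betas, labels, SearchlightSpec(mask, 3))
        inside = set(map(tuple, mask.coords()))
        for fold in res.folds:
            assert set(fold.selected_voxels) <= inside
        assert res.mean_selected_voxels == pytest.approx(
            np.mean([len(f.selected_voxels) for f in res.folds])
        )

    def test_single_trial_class_rejected_with_guidance(self, small_mask, toy_betas):
        betas, _ = toy_betas(small_mask, 2, 1.0, 1.0, seed=14)
        labels = np.array(["A", "A", "A", "B"])
        with pytest.raises(ValueError, match="at least 2 trials"):
            loo_decode(betas, labels, SearchlightSpec(small_mask, 3))

    def test_deterministic(self, toy_betas):
        mask = make_blob_mask((10, 10, 8), 10, seed=15)
        betas, labels = toy_betas(mask, 4, 1.0, 1.0, seed=16)
        a = loo_decode(betas, labels, SearchlightSpec(mask, 3))
        b = loo_decode(betas, labels, SearchlightSpec(mask, 3))
        assert a.accuracy == b.accuracy
        assert all(
            fa.selected_voxels == fb.selected_voxels
            for fa, fb in zip(a.folds, b.folds)
        )

    def test_null_fold_outcomes_binomial(self, toy_betas):
        # under permuted labels the per-fold correctness behaves like fair
        # coin flips: pooled across replicates the total correct count must
        # sit within 3 SD of n/2.  Trial counts are kept near the study's
        # scale: at very small n, leave-one-out class imbalance gives any
        # classifier a genuine below-chance expectation.
        mask = make_blob_mask((8, 8, 6), 8, seed=17)
        total, n_folds = 0, 0
        for rep in range(10):
            betas, labels = toy_betas(mask, 20, 0.0, 1.0, seed=100 + rep)
            res = loo_decode(betas, labels, SearchlightSpec(mask, 3))
            total += sum(f.correct for f in res.folds)
            n_folds += res.n_test
        sd = np.sqrt(n_folds * 0.25)
        assert abs(total - n_folds / 2) < 3 * sd


class TestCrossDecode:
    def test_resubstitution_on_separable_data_is_perfect(self, toy_betas):
        mask = make_blob_mask((10, 10, 8), 10, seed=18)
        betas, labels = toy_betas(mask, 6, 4.0, 0.5, seed=19)
        spec = SearchlightSpec(mask, 3)
        res = cross_decode(betas, labels, betas, labels, spec)
        assert res.accuracy == 1.0
        assert res.n_test == 12

    def test_independent_test_patterns_near_chance(self, toy_betas):
        mask = make_blob_mask((10, 10, 8), 10, seed=20)
        spec = SearchlightSpec(mask, 3)
        accs = []
        for rep in range(10):
            train, lab_tr = toy_betas(mask, 10, 2.0, 1.0, seed=200 + rep)
            test, lab_te = toy_betas(mask, 10, 2.0, 1.0, seed=900 + rep)
            accs.append(cross_decode(train, lab_tr, test, lab_te, spec).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.12

    def test_voxel_mismatch_rejected(self, toy_betas):
        a = make_blob_mask((10, 10, 8), 10, seed=21)
        b = make_blob_mask((10, 10, 8), 9, seed=22)
        betas_a, lab = toy_betas(a, 3, 1.0, 1.0, seed=23)
        betas_b, _ = toy_betas(b, 3, 1.0, 1.0, seed=24)
        with pytest.raises(ValueError, match="different voxels"):
            cross_decode(betas_a, lab, betas_b, lab, SearchlightSpec(a, 3))

    def test_unknown_test_labels_rejected(self, small_mask, toy_betas):
        betas, lab = toy_betas(small_mask, 3, 1.0, 1.0, seed=25)
        bad = np.array(["A", "B", "C", "A", "B", "A"])
        with pytest.raises(ValueError, match="outside training classes"):
            cross_decode(betas, lab, betas, bad, SearchlightSpec(small_mask, 3))
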