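from collections import deque
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from hippomvpa import (
    SimulationConfig,
    dice,
    make_blob_mask,
    make_event_schedule,
    make_ground_truth,
    make_mask_pair,
    make_subfield_masks,
    p_choose_a,
    simulate_behavior,
    simulate_bold,
)
from hippomvpa.events import MORPH_FRACTIONS
from hippomvpa.glm import build_design, fit_beta_series
from hippomvpa.roi import DEFAULT_SUBFIELD_VOXELS


def _is_six_connected(mask):
    coords = set(map(tuple, np.argwhere(mask)))
    if not coords:
        return False
    seen = {next(iter(coords))}
    queue = deque(seen)
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in [(1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)]:
            v = (x + dx, y + dy, z + dz)
            if v in coords and v not in seen:
                seen.add(v)
                queue.append(v)
    return seen == coords


class TestSubfieldMasks:
    def test_default_counts_within_ten_percent(self):
        masks = make_subfield_masks((40, 40, 20), seed=0)
        by_key = {m.key(): m.n_voxels for m in masks}
        for sub, target in DEFAULT_SUBFIELD_VOXELS.items():
            for hemi in "LR":
                n = by_key[f"{sub}_{hemi}"]
                assert 0.9 * target <= n <= 1.1 * target

    def test_disjoint_and_connected(self):
        masks = make_subfield_masks((24, 24, 12), {"CA1": 40, "CA3": 30, "DG": 20, "SUB": 10}, seed=1)
        total = np.zeros((24, 24, 12), dtype=int)
        for m in masks:
            total += m.data
            assert _is_six_connected(m.data)
        assert total.max() == 1

    def test_single_voxel_targets(self):
        masks = make_subfield_masks((8, 8, 4), {s: 1 for s in ("CA1", "CA3", "DG", "SUB")}, seed=2)
        assert len(masks) == 8
        assert all(m.n_voxels == 1 for m in masks)

    def test_deterministic_under_seed(self):
        a = make_subfield_masks((20, 20, 10), {"CA1": 20, "CA3": 15, "DG": 10, "SUB": 5}, seed=7)
        b = make_subfield_masks((20, 20, 10), {"CA1": 20, "CA3": 15, "DG": 10, "SUB": 5}, seed=7)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.data, mb.data)

    def test_too_small_grid_fails_with_placement_error(self):
        with pytest.raises(ValueError, match="too small"):
            make_subfield_masks((6, 6, 4), seed=0)


class TestEventSchedule:
    def test_category_balance_and_count(self):
        cfg = SimulationConfig(n_repeats_per_stimulus=5, seed=1)
        ev = make_event_schedule(cfg)
        assert len(ev) == 45
        counts = ev["morph_fraction"].value_counts()
        assert set(counts.index) == set(MORPH_FRACTIONS)
        assert (counts == 5).all()

    def test_trial_block_is_seven_point_five_seconds(self):
        ev = make_event_schedule(SimulationConfig(n_repeats_per_stimulus=2, seed=0))
        assert np.allclose(np.diff(ev["onset_s"]), 7.5)

    def test_minimal_schedule(self):
        ev = make_event_schedule(SimulationConfig(n_repeats_per_stimulus=1, seed=0))
        assert len(ev) == 9
        assert sorted(ev["morph_fraction"]) == sorted(MORPH_FRACTIONS)


class TestBehavior:
    def test_midpoint_probability_exactly_half(self):
        assert p_choose_a(0.5, 10.0) == 0.5

    def test_steep_slope_limit(self):
        assert p_choose_a(1.0, 1000.0) > 0.999999

    def test_empirical_choice_rate_matches_logistic(self):
        # 10,000 trials at fraction 0.7, slope 10: expected expit(2.0)
        n = 10_000
        ev = pd.DataFrame(
            {
                "onset_s": np.arange(n) * 7.5,
                "morph_fraction": 0.7,
                "choice": "none",
                "confidence": pd.array([pd.NA] * n, dtype="Int64"),
                "correct": pd.array([pd.NA] * n, dtype="boolean"),
                "decision_made": False,
            }
        )
        out = simulate_behavior(ev, 10.0, seed=5, no_decision_rate=0.0)
        p_hat = (out["choice"] == "A").mean()
        p_true = expit(2.0)
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_hat - p_true) < 3 * se

    def test_confidence_rises_with_unambiguity(self):
        n = 3000
        means = []
        for frac in (0.5, 0.7, 1.0):
            ev = pd.DataFrame(
                {
                    "onset_s": np.arange(n) * 7.5,
                    "morph_fraction": frac,
                    "choice": "none",
                    "confidence": pd.array([pd.NA] * n, dtype="Int64"),
                    "correct": pd.array([pd.NA] * n, dtype="boolean"),
                    "decision_made": False,
                }
            )
            out = simulate_behavior(ev, 10.0, seed=6, no_decision_rate=0.0)
            means.append(out["confidence"].astype(float).mean())
        assert means[0] < means[1] < means[2]

    def test_no_decision_rate_respected(self):
        n = 4000
        ev = pd.DataFrame(
            {
                "onset_s": np.arange(n) * 7.5,
                "morph_fraction": 0.5,
                "choice": "none",
                "confidence": pd.array([pd.NA] * n, dtype="Int64"),
                "correct": pd.array([pd.NA] * n, dtype="boolean"),
                "decision_made": False,
            }
        )
        out = simulate_behavior(ev, 10.0, seed=7, no_decision_rate=0.1)
        rate = 1 - out["decision_made"].mean()
        assert abs(rate - 0.1) < 0.02
        assert (out.loc[~out["decision_made"], "choice"] == "none").all()

    def test_invalid_fraction_rejected(self):
        ev = pd.DataFrame(
            {
                "onset_s": [0.0],
                "morph_fraction": [1.5],
                "choice": "none",
                "confidence": pd.array([pd.NA], dtype="Int64"),
                "correct": pd.array([pd.NA], dtype="boolean"),
                "decision_made": False,
            }
        )
        with pytest.raises(ValueError):
            simulate_behavior(ev, 10.0, seed=0)


def _tiny_world(seed=0, **kw):
    cfg = SimulationConfig(
        n_subjects=1,
        grid_dims=(10, 10, 8),
        n_repeats_per_stimulus=2,
        pattern_amplitude=kw.pop("pattern_amplitude", 1.0),
        noise_sd=kw.pop("noise_sd", 1.0),
        seed=seed,
        **kw,
    )
    mask = make_blob_mask(cfg.grid_dims, 10, seed=seed)
    ev = make_event_schedule(cfg)
    ev = simulate_behavior(ev, cfg.psychometric_slope, seed=seed, no_decision_rate=0.0)
    truth = make_ground_truth([mask], ev, cfg)
    return cfg, mask, ev, truth


class TestSimulateBold:
    def test_null_amplitude_gives_baseline_noise(self):
        cfg, mask, ev, truth = _tiny_world(pattern_amplitude=0.0, noise_sd=0.5)
        bold = simulate_bold(ev, [mask], truth, cfg)
        assert bold.data.mean() == pytest.approx(cfg.baseline, abs=0.05)

    def test_deterministic(self):
        cfg, mask, ev, truth = _tiny_world(seed=4)
        a = simulate_bold(ev, [mask], truth, cfg)
        b = simulate_bold(ev, [mask], truth, cfg)
        assert np.array_equal(a.data, b.data)

    def test_noiseless_voxel_follows_trial_regressor(self):
        cfg, mask, ev, truth = _tiny_world(noise_sd=1e-12)
        single = ev.iloc[:1].copy()
        truth.latent_state = truth.latent_state[:1]
        bold = simulate_bold(single, [mask], truth, cfg)
        des = build_design(single, bold.n_scans, cfg.tr_s, stim_duration_s=cfg.stim_s)
        reg = des.matrix[:, 0]
        v = mask.coords()[0]
        series = bold.data[v[0], v[1], v[2], :] - cfg.baseline
        assert abs(np.corrcoef(series, reg)[0, 1]) > 0.9999

    def test_full_share_makes_state_patterns_identical(self):
        cfg, mask, ev, _ = _tiny_world(morph_pattern_share=1.0)
        truth = make_ground_truth([mask], ev, cfg)
        pats = truth.patterns[mask.key()]
        np.testing.assert_allclose(pats["state_A"], pats[1.0])
        np.testing.assert_allclose(pats["state_B"], pats[0.0])

    def test_state_pattern_correlation_tracks_share(self):
        cfg, mask, ev, _ = _tiny_world(morph_pattern_share=0.6)
        big = make_blob_mask((20, 20, 12), 500, seed=9)
        truth = make_ground_truth([big], ev, replace(cfg, grid_dims=(20, 20, 12)))
        pats = truth.patterns[big.key()]
        r = np.corrcoef(pats["state_A"], pats[1.0])[0, 1]
        assert abs(r - 0.6) < 0.12

    def test_overlapping_masks_rejected(self):
        cfg, mask, ev, truth = _tiny_world()
        truth.patterns[mask.key()] = truth.patterns[mask.key()]
        with pytest.raises(ValueError, match="overlap"):
            simulate_bold(ev, [mask, mask], truth, cfg)

    def test_events_past_run_rejected(self):
        cfg, mask, ev, truth = _tiny_world()
        with pytest.raises(ValueError, match="beyond"):
            simulate_bold(ev, [mask], truth, cfg, n_scans=5)

    def test_glm_recovers_embedded_patterns(self):
        # forward/inverse consistency: near-noiseless world, unsmoothed GLM
        cfg, mask, ev, truth = _tiny_world(noise_sd=1e-6, pattern_amplitude=1.0)
        bold = simulate_bold(ev, [mask], truth, cfg)
        des = build_design(ev, bold.n_scans, cfg.tr_s, stim_duration_s=cfg.stim_s)
        bs = fit_beta_series(bold, des, mask)
        pats = truth.patterns[mask.key()]
        frac = ev["morph_fraction"].to_numpy()
        for t in range(len(ev)):
            key = f"state_{truth.latent_state[t]}" if frac[t] == 0.5 else frac[t]
            expected = cfg.pattern_amplitude * pats[key]
            cos = np.dot(bs.betas[t], expected) / (
                np.linalg.norm(bs.betas[t]) * np.linalg.norm(expected)
            )
            assert cos > 0.99


class TestMaskPair:
    def test_unit_target_gives_identical_masks(self, small_mask):
        a, b = make_mask_pair(small_mask, 1.0, seed=0)
        assert dice(a, b) == 1.0

    def test_zero_target_gives_disjoint_masks(self, small_mask):
        a, b = make_mask_pair(small_mask, 0.0, seed=0)
        assert dice(a, b) == 0.0

    def test_intermediate_target_achieved_by_direct_count(self):
        base = make_blob_mask((12, 12, 10), 100, seed=1)
        a, b = make_mask_pair(base, 0.8, seed=2)
        inter = np.logical_and(a.data, b.data).sum()
        d = 2 * inter / (a.n_voxels + b.n_voxels)
        assert 0.78 <= d <= 0.82
        assert d == pytest.approx(dice(a, b))

    def test_unattainable_target_for_single_voxel_base(self):
        base = make_blob_mask((6, 6, 6), 1, seed=0)
        with pytest.raises(ValueError, match="unattainable"):
            make_mask_pair(base, 0.5, seed=0)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(noise_sd=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(morph_pattern_share=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_repeats_per_stimulus=0)
    with pytest.raises(ValueError):
        SimulationConfig(grid_dims=(10, 10))
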