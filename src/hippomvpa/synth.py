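"""Synthetic scene-discrimination fMRI cohorts with known ground truth.

Emulates the study conditions of a scene-morph decision experiment: two
original scenes plus seven morphs (nine stimulus categories, given as the
proportion of scene A), 40 presentations each, a 2.5 s stimulus / 3 s
confidence-rating / 2 s rest trial, 1.5 mm isotropic voxels at TR 3.5 s,
and four bilateral hippocampal-subfield masks (CA1, CA3, DG, SUB) with
voxel counts near typical manual-segmentation means.

Every ROI carries a category-specific multivoxel pattern; 50%-morph trials
instead express the pattern of the simulated latent decision state (A or
B), whose overlap with the corresponding 100%-scene pattern is set by
``morph_pattern_share`` — 0 gives fully independent decision-state
patterns (no cross-condition transfer), 1 makes them identical.  Choices
follow a logistic psychometric function of the morph fraction, and
confidence ratings rise with distance from the ambiguous midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .events import EVENT_COLUMNS, MORPH_FRACTIONS, validate_events
from .glm import Bold4D, HrfParams, build_design
from .roi import DEFAULT_SUBFIELD_VOXELS, HEMISPHERES, SUBFIELDS, RoiMask

# fixed stream tags so each simulation stage draws independent randomness
_STREAM_MASKS = 11
_STREAM_SCHEDULE = 12
_STREAM_BEHAVIOR = 13
_STREAM_TRUTH = 14
_STREAM_NOISE = 15


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort generator.

    ``pattern_amplitude`` scales the embedded multivoxel patterns (BOLD
    units per unit HRF response); ``noise_sd`` the i.i.d. Gaussian scanner
    noise.  ``morph_pattern_share`` is the correlation between each
    decision-state pattern and the matching 100%-scene pattern.
    """

    n_subjects: int = 16
    grid_dims: tuple[int, int, int] = (40, 40, 20)
    voxel_size_mm: float = 1.5
    tr_s: float = 3.5
    n_repeats_per_stimulus: int = 40
    pattern_amplitude: float = 1.0
    noise_sd: float = 2.0
    morph_pattern_share: float = 0.0
    psychometric_slope: float = 10.0
    seed: int = 0
    # trial timeline (seconds)
    stim_s: float = 2.5
    confidence_s: float = 3.0
    rest_s: float = 2.0
    # behaviour nuisances
    no_decision_rate: float = 0.03
    confidence_noise_sd: float = 0.18
    # signal layout
    baseline: float = 100.0
    drift_amplitude: float = 0.0
    roi_target_counts: dict | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_repeats_per_stimulus < 1:
            raise ValueError("counts must be >= 1")
        if len(self.grid_dims) != 3 or any(g < 1 for g in self.grid_dims):
            raise ValueError("grid_dims must be 3 positive integers")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.pattern_amplitude < 0:
            raise ValueError("pattern_amplitude must be >= 0")
        if not 0.0 <= self.morph_pattern_share <= 1.0:
            raise ValueError("morph_pattern_share must be in [0, 1]")
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric_slope must be > 0")
        if min(self.voxel_size_mm, self.tr_s, self.stim_s) <= 0:
            raise ValueError("durations and voxel size must be positive")
        if not 0.0 <= self.no_decision_rate < 1.0:
            raise ValueError("no_decision_rate must be in [0, 1)")

    @property
    def trial_block_s(self) -> float:
        return self.stim_s + self.confidence_s + self.rest_s

    def target_counts(self) -> dict:
        return dict(self.roi_target_counts or DEFAULT_SUBFIELD_VOXELS)


@dataclass
class GroundTruth:
    """What the generator embedded, for parameter-recovery checks.

    ``patterns[roi_key]`` maps each stimulus category (its morph fraction)
    and the two decision states (``"state_A"``, ``"state_B"``) to a pattern
    vector with one entry per ROI voxel (lexicographic coordinate order).
    ``latent_state`` holds the per-trial decision state; ``embedded`` flags
    whether a given ROI carries any signal.
    """

    patterns: dict
    latent_state: np.ndarray
    embedded: dict


_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _grow_blob(
    lo: np.ndarray, hi: np.ndarray, n_target: int, rng: np.random.Generator
) -> np.ndarray:
    """Random 6-connected region of exactly ``n_target`` voxels in a box."""
    center = (lo + hi) // 2
    region = {tuple(center)}
    frontier = []
    seen = {tuple(center)}

    def push_neighbors(v):
        for d in _NEIGHBORS:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if w in seen:
                continue
            if all(lo[k] <= w[k] < hi[k] for k in range(3)):
                seen.add(w)
                frontier.append(w)

    push_neighbors(tuple(center))
    while len(region) < n_target:
        if not frontier:
            raise ValueError("region growing exhausted its box")
        idx = int(rng.integers(len(frontier)))
        v = frontier.pop(idx)
        region.add(v)
        push_neighbors(v)
    return np.array(sorted(region))


def make_subfield_masks(
    grid_dims: tuple[int, int, int],
    target_counts: dict | None = None,
    seed: int = 0,
    voxel_size_mm: float = 1.5,
) -> list[RoiMask]:
    """Eight disjoint connected blobs: four subfields × two hemispheres.

    The grid is partitioned into octants (hemisphere by the x midplane,
    subfield by y/z quadrants) and each mask is grown as a random
    6-connected blob of exactly its target voxel count inside its octant,
    which guarantees pairwise disjointness.  Real anatomy is not modelled;
    only counts, connectedness and disjointness matter downstream.
    """
    targets = dict(target_counts or DEFAULT_SUBFIELD_VOXELS)
    missing = [s for s in SUBFIELDS if s not in targets]
    if missing:
        raise ValueError(f"target_counts missing subfields: {missing}")
    if any(v < 1 for v in targets.values()):
        raise ValueError("target counts must be positive")
    nx, ny, nz = grid_dims
    quad = {"CA1": (0, 0), "CA3": (0, 1), "DG": (1, 0), "SUB": (1, 1)}
    rng = np.random.default_rng([_STREAM_MASKS, seed])
    masks: list[RoiMask] = []
    for hemi_i, hemi in enumerate(HEMISPHERES):
        x0, x1 = (0, nx // 2) if hemi_i == 0 else (nx // 2, nx)
        for sub in SUBFIELDS:
            qy, qz = quad[sub]
            y0, y1 = (0, ny // 2) if qy == 0 else (ny // 2, ny)
            z0, z1 = (0, nz // 2) if qz == 0 else (nz // 2, nz)
            lo = np.array([x0, y0, z0])
            hi = np.array([x1, y1, z1])
            capacity = int(np.prod(hi - lo))
            if capacity < targets[sub]:
                raise ValueError(
                    f"grid {grid_dims} too small to place {sub} ({hemi}): "
                    f"octant holds {capacity} voxels, need {targets[sub]}"
                )
            coords = _grow_blob(lo, hi, targets[sub], rng)
            data = np.zeros(grid_dims, dtype=bool)
            data[tuple(coords.T)] = True
            masks.append(RoiMask(data, sub, hemi, voxel_size_mm))
    return masks


def make_blob_mask(
    grid_dims: tuple[int, int, int],
    n_voxels: int,
    seed: int = 0,
    subfield: str = "CA1",
    hemisphere: str = "L",
    voxel_size_mm: float = 1.5,
) -> RoiMask:
    """A single random connected blob of exactly ``n_voxels`` voxels."""
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if n_voxels > int(np.prod(grid_dims)):
        raise ValueError(f"grid {grid_dims} too small for {n_voxels} voxels")
    rng = np.random.default_rng([_STREAM_MASKS, 7, seed])
    coords = _grow_blob(
        np.zeros(3, dtype=int), np.asarray(grid_dims, dtype=int), n_voxels, rng
    )
    data = np.zeros(grid_dims, dtype=bool)
    data[tuple(coords.T)] = True
    return RoiMask(data, subfield, hemisphere, voxel_size_mm)


def make_event_schedule(config: SimulationConfig) -> pd.DataFrame:
    """Pseudo-random trial order: each category exactly n_repeats times.

    Onsets advance by the fixed trial block (stimulus + confidence + rest).
    Behavioural columns are placeholders until :func:`simulate_behavior`.
    """
    fractions = np.repeat(MORPH_FRACTIONS, config.n_repeats_per_stimulus)
    rng = np.random.default_rng([_STREAM_SCHEDULE, config.seed])
    rng.shuffle(fractions)
    n = fractions.size
    events = pd.DataFrame(
        {
            "onset_s": np.arange(n) * config.trial_block_s,
            "morph_fraction": fractions,
            "choice": "none",
            "confidence": pd.array([pd.NA] * n, dtype="Int64"),
            "correct": pd.array([pd.NA] * n, dtype="boolean"),
            "decision_made": False,
        }
    )
    return validate_events(events)


def p_choose_a(morph_fraction, slope: float):
    """Logistic psychometric function: P(choose A | stimulus).

    Centred on the ambiguous 50% morph, so ``p_choose_a(0.5, s) = 0.5`` for
    any slope.
    """
    return expit(slope * (np.asarray(morph_fraction, dtype=float) - 0.5))


def simulate_behavior(
    events: pd.DataFrame,
    slope: float,
    seed: int = 0,
    no_decision_rate: float = 0.03,
    confidence_noise_sd: float = 0.18,
) -> pd.DataFrame:
    """Draw choices, confidence ratings and correctness for each trial.

    Choices follow the logistic psychometric function; the 1–3 confidence
    rating comes from thresholding a noisy evidence-strength variable that
    grows with distance from the 50% midpoint (so expected confidence rises
    with stimulus unambiguity, and even ambiguous trials are mostly rated
    "fairly sure").  A small fraction of trials registers no decision.
    Correctness is defined only for the unambiguous stimuli.
    """
    validate_events(events)
    if slope <= 0:
        raise ValueError("slope must be > 0")
    frac = events["morph_fraction"].to_numpy(dtype=float)
    n = frac.size
    rng = np.random.default_rng([_STREAM_BEHAVIOR, seed])
    choose_a = rng.random(n) < p_choose_a(frac, slope)
    no_decision = rng.random(n) < no_decision_rate
    strength = 0.45 + 0.8 * np.abs(frac - 0.5) + rng.normal(
        0.0, confidence_noise_sd, n
    )
    confidence = np.where(strength < 0.30, 1, np.where(strength < 0.60, 2, 3))

    out = events.copy()
    out["choice"] = np.where(no_decision, "none", np.where(choose_a, "A", "B"))
    out["decision_made"] = ~no_decision
    out["confidence"] = pd.array(
        [pd.NA if nd else int(c) for nd, c in zip(no_decision, confidence)],
        dtype="Int64",
    )
    correct = []
    for f, ch in zip(frac, out["choice"]):
        if f == 1.0:
            correct.append(ch == "A")
        elif f == 0.0:
            correct.append(ch == "B")
        else:
            correct.append(pd.NA)
    out["correct"] = pd.array(correct, dtype="boolean")
    return validate_events(out)


def make_ground_truth(
    masks: list[RoiMask],
    events: pd.DataFrame,
    config: SimulationConfig,
    embedded: dict | None = None,
) -> GroundTruth:
    """Draw per-ROI category patterns and assign per-trial latent states.

    Pattern vectors are i.i.d. standard normal across voxels.  Each
    decision-state pattern is ``s·p + sqrt(1−s²)·q`` with ``p`` the matching
    100%-scene pattern, ``q`` an independent draw and ``s`` the configured
    ``morph_pattern_share`` — giving correlation exactly ``s`` by
    construction.  The latent state of each trial is the simulated choice
    when one was made, otherwise a fair coin.
    """
    rng = np.random.default_rng([_STREAM_TRUTH, config.seed])
    s = config.morph_pattern_share
    patterns: dict = {}
    emb: dict = {}
    for mask in masks:
        key = mask.key()
        nv = mask.n_voxels
        cat = {f: rng.standard_normal(nv) for f in MORPH_FRACTIONS}
        mix = math.sqrt(max(0.0, 1.0 - s * s))
        cat["state_A"] = s * cat[1.0] + mix * rng.standard_normal(nv)
        cat["state_B"] = s * cat[0.0] + mix * rng.standard_normal(nv)
        patterns[key] = cat
        emb[key] = True if embedded is None else bool(embedded.get(key, True))
    choices = events["choice"].to_numpy()
    coin = rng.random(len(choices)) < 0.5
    latent = np.where(
        np.isin(choices, ["A", "B"]), choices, np.where(coin, "A", "B")
    ).astype("U1")
    return GroundTruth(patterns=patterns, latent_state=latent, embedded=emb)


def required_scans(events: pd.DataFrame, config: SimulationConfig) -> int:
    """Scans needed to cover all trials plus the HRF tail."""
    last = float(events["onset_s"].iloc[-1]) if len(events) else 0.0
    total_s = last + config.trial_block_s + HrfParams().length_s
    return int(math.ceil(total_s / config.tr_s))


def simulate_bold(
    events: pd.DataFrame,
    masks: list[RoiMask],
    truth: GroundTruth,
    config: SimulationConfig,
    n_scans: int | None = None,
) -> Bold4D:
    """Forward model: patterns × HRF-convolved trial regressors + noise.

    Each trial adds its category's pattern (its latent decision state's
    pattern for 50% morphs) scaled by ``pattern_amplitude`` to the voxels
    of every signal-carrying ROI, with the trial's HRF-convolved boxcar as
    the time course; i.i.d. Gaussian noise and an optional linear drift are
    superimposed on a constant baseline everywhere.
    """
    validate_events(events)
    occupied = np.zeros(config.grid_dims, dtype=int)
    for m in masks:
        if m.data.shape != tuple(config.grid_dims):
            raise ValueError("mask grid does not match config grid_dims")
        occupied += m.data
        if truth.patterns[m.key()][1.0].size != m.n_voxels:
            raise ValueError(f"ground-truth pattern size mismatch for {m.key()}")
    if occupied.max() > 1:
        raise ValueError("masks overlap")
    if len(truth.latent_state) != len(events):
        raise ValueError("latent_state must cover every trial")
    if n_scans is None:
        n_scans = required_scans(events, config)
    design = build_design(
        events, n_scans, config.tr_s, stim_duration_s=config.stim_s
    )  # raises if events extend past the run
    R = design.task  # (time, trials)
    n_trials = len(events)
    V = int(np.prod(config.grid_dims))
    A = np.zeros((n_trials, V))
    frac = events["morph_fraction"].to_numpy(dtype=float)
    for m in masks:
        key = m.key()
        if not truth.embedded[key]:
            continue
        flat = np.ravel_multi_index(m.coords().T, config.grid_dims)
        pats = truth.patterns[key]
        for t in range(n_trials):
            if frac[t] == 0.5:
                pat = pats[f"state_{truth.latent_state[t]}"]
            else:
                pat = pats[frac[t]]
            A[t, flat] = config.pattern_amplitude * pat
    rng = np.random.default_rng([_STREAM_NOISE, config.seed])
    data = rng.normal(config.baseline, config.noise_sd, (n_scans, V))
    data += R @ A
    if config.drift_amplitude:
        data += config.drift_amplitude * np.linspace(-0.5, 0.5, n_scans)[:, None]
    vol = np.moveaxis(data.reshape(n_scans, *config.grid_dims), 0, -1)
    return Bold4D(np.ascontiguousarray(vol), config.tr_s, config.voxel_size_mm)


def make_mask_pair(
    base: RoiMask, target_dice: float, seed: int = 0
) -> tuple[RoiMask, RoiMask]:
    """A pair of equal-volume masks with Dice within 0.02 of a target.

    The second mask keeps ``k = round(d·n)`` of the base voxels and replaces
    the rest with voxels drawn from outside the base, so the achieved Dice
    is exactly ``k/n``.  Raises when the nearest attainable value is more
    than 0.02 away (e.g. a one-voxel base with 0 < d < 1).
    """
    if not 0.0 <= target_dice <= 1.0:
        raise ValueError("target_dice must be in [0, 1]")
    n = base.n_voxels
    if n == 0:
        raise ValueError("base mask is empty")
    k = int(round(target_dice * n))
    achieved = k / n
    if abs(achieved - target_dice) > 0.02:
        raise ValueError(
            f"target Dice {target_dice} unattainable for a {n}-voxel base "
            f"(nearest achievable {achieved:.3f})"
        )
    rng = np.random.default_rng([17, seed])
    coords = base.coords()
    keep = coords[rng.choice(n, size=k, replace=False)] if k else coords[:0]
    n_new = n - k
    if n_new:
        outside = np.argwhere(~base.data)
        if outside.shape[0] < n_new:
            raise ValueError("grid too full to place non-overlap voxels")
        extra = outside[rng.choice(outside.shape[0], size=n_new, replace=False)]
        new_coords = np.vstack([keep, extra])
    else:
        new_coords = keep
    data_b = np.zeros_like(base.data)
    data_b[tuple(new_coords.T)] = True
    a = RoiMask(base.data.copy(), base.subfield, base.hemisphere, base.voxel_size_mm)
    b = RoiMask(data_b, base.subfield, base.hemisphere, base.voxel_size_mm)
    return a, b
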