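"""End-to-end cohort orchestration: simulate → GLM → decode → group stats.

One configuration object drives the whole synthetic experiment.  Per
subject: masks, event schedule, behaviour, BOLD, 3-mm smoothing, per-trial
GLM, then the three decoding analyses per subfield × hemisphere —

* ``scenes``: leave-one-out decoding of the two unambiguous scenes
  (choice-labelled, exclusion rules for the unambiguous trials);
* ``cross``: the motor-confound control — train on the unambiguous scenes,
  test on the 50%-morph trials labelled by the participants' choices;
* ``morph50``: leave-one-out decoding of the decision state on the
  ambiguous 50%-morph trials.

Group statistics follow: per-region hemisphere check, collapse across
hemispheres, t-tests against 50% chance, one-way repeated-measures ANOVA
across the four subfields, and all pairwise paired t-tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decoding import (
    DecodingResult,
    SearchlightSpec,
    SelectionRule,
    SvmSpec,
    cross_decode,
    loo_decode,
)
from .events import filter_trials, validate_events
from .glm import BetaSeries, build_design, fit_beta_series, smooth_gaussian
from .roi import SUBFIELDS, RoiMask
from .stats import (
    hemisphere_check_and_collapse,
    paired_ttests,
    rm_anova,
    ttest_vs_chance,
)
from .synth import (
    SimulationConfig,
    make_event_schedule,
    make_ground_truth,
    make_subfield_masks,
    required_scans,
    simulate_behavior,
    simulate_bold,
)

logger = logging.getLogger("hippomvpa.pipeline")

ANALYSES = ("scenes", "cross", "morph50")
_SEED_MOD = 2**31


@dataclass(frozen=True)
class AnalysisSettings:
    """Decoding-stage knobs shared by every subject and ROI."""

    fwhm_mm: float = 3.0
    radius_voxels: int = 3
    svm: SvmSpec = field(default_factory=SvmSpec)
    rule: SelectionRule = field(default_factory=SelectionRule)
    analyses: tuple = ANALYSES
    beta_units: str = "t"
    standardize: bool = False
    save_fold_detail: bool = False


@dataclass
class CohortRun:
    """Everything a cohort run produced, traceable to config + seed."""

    config: SimulationConfig
    settings: AnalysisSettings
    results: dict  # analysis -> list[DecodingResult]
    accuracy_tables: dict  # analysis -> long DataFrame
    group: dict  # analysis -> dict of group statistics
    out_dir: Path | None = None


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def subject_seed(seed: int, subject_id: int) -> int:
    return (seed * 1_000_003 + 7919 * (subject_id + 1)) % _SEED_MOD


def simulate_subject(config: SimulationConfig, subject_id: int):
    """Generate one subject: masks, behavioural events, ground truth, BOLD."""
    cfg = replace(config, seed=subject_seed(config.seed, subject_id))
    masks = make_subfield_masks(
        cfg.grid_dims, cfg.target_counts(), seed=cfg.seed,
        voxel_size_mm=cfg.voxel_size_mm,
    )
    events = make_event_schedule(cfg)
    events = simulate_behavior(
        events,
        cfg.psychometric_slope,
        seed=cfg.seed,
        no_decision_rate=cfg.no_decision_rate,
        confidence_noise_sd=cfg.confidence_noise_sd,
    )
    truth = make_ground_truth(masks, events, cfg)
    bold = simulate_bold(events, masks, truth, cfg)
    return masks, events, truth, bold


def _stage(name: str, subject: int):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise PipelineError(
                    f"stage '{name}' failed for subject {subject}: {exc}"
                ) from exc
            logger.info("subject %d: %s done in %.2fs", subject, name, dt)

    return _Ctx()


def run_cohort(
    config: SimulationConfig,
    settings: AnalysisSettings = AnalysisSettings(),
    out_dir: str | Path | None = None,
) -> CohortRun:
    """Run the full synthetic cohort and its group statistics.

    Deterministic: the same ``config`` (including seed) and ``settings``
    give identical results.  With ``out_dir`` set, writes a structured
    results directory (config snapshot, per-analysis accuracy tables and
    group statistics, per-ROI decoding summaries).
    """
    results: dict = {a: [] for a in settings.analyses}
    for s in range(config.n_subjects):
        with _stage("simulate", s):
            masks, events, truth, bold = simulate_subject(config, s)
        with _stage("smooth", s):
            bold = smooth_gaussian(bold, settings.fwhm_mm)
        with _stage("glm", s):
            design = build_design(
                events, bold.n_scans, config.tr_s, stim_duration_s=config.stim_s
            )
            roi_betas = {
                m.key(): fit_beta_series(
                    bold, design, m, units=settings.beta_units
                )
                for m in masks
            }
        with _stage("filter_trials", s):
            scenes = filter_trials(events, "original_scenes")
            morph50 = filter_trials(events, "morph50")
        with _stage("decode", s):
            for m in masks:
                spec = SearchlightSpec(m, settings.radius_voxels)
                betas = roi_betas[m.key()]
                if "scenes" in settings.analyses or "cross" in settings.analyses:
                    b_tr = betas.subset_trials(scenes.index.to_numpy())
                    lab_tr = scenes["choice"].to_numpy()
                if "scenes" in settings.analyses:
                    res = loo_decode(
                        b_tr, lab_tr, spec, settings.svm, settings.rule,
                        standardize=settings.standardize,
                    )
                    res.subject_id = s
                    results["scenes"].append(res)
                if "cross" in settings.analyses:
                    b_te = betas.subset_trials(morph50.index.to_numpy())
                    res = cross_decode(
                        b_tr, lab_tr, b_te, morph50["choice"].to_numpy(),
                        spec, settings.svm, settings.rule,
                        standardize=settings.standardize,
                    )
                    res.subject_id = s
                    results["cross"].append(res)
                if "morph50" in settings.analyses:
                    b_m = betas.subset_trials(morph50.index.to_numpy())
                    res = loo_decode(
                        b_m, morph50["choice"].to_numpy(),
                        spec, settings.svm, settings.rule,
                        standardize=settings.standardize,
                    )
                    res.subject_id = s
                    results["morph50"].append(res)

    accuracy_tables = {
        a: pd.DataFrame(
            [
                {
                    "subject": r.subject_id,
                    "subfield": r.subfield,
                    "hemisphere": r.hemisphere,
                    "accuracy": r.accuracy,
                }
                for r in rs
            ]
        )
        for a, rs in results.items()
    }
    group = {}
    for a, table in accuracy_tables.items():
        if table.empty or table["subject"].nunique() < 2:
            group[a] = {"note": "group statistics need at least 2 subjects"}
            continue
        check, collapsed = hemisphere_check_and_collapse(table)
        ttests = {
            region: dataclasses.asdict(ttest_vs_chance(collapsed[region].to_numpy()))
            for region in collapsed.columns
        }
        anova = dataclasses.asdict(rm_anova(collapsed))
        paired = paired_ttests(collapsed)
        group[a] = {
            "hemisphere_check": check,
            "collapsed": collapsed,
            "ttests_vs_chance": ttests,
            "rm_anova": anova,
            "paired_ttests": paired,
        }

    run = CohortRun(config, settings, results, accuracy_tables, group)
    if out_dir is not None:
        run.out_dir = Path(out_dir)
        _write_results(run)
    return run


def _write_results(run: CohortRun) -> None:
    out = run.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(run.config)
    cfg["grid_dims"] = list(cfg["grid_dims"])
    snap = {
        "config": cfg,
        "settings": {
            "fwhm_mm": run.settings.fwhm_mm,
            "radius_voxels": run.settings.radius_voxels,
            "svm": dataclasses.asdict(run.settings.svm),
            "rule": dataclasses.asdict(run.settings.rule),
            "analyses": list(run.settings.analyses),
            "beta_units": run.settings.beta_units,
            "standardize": run.settings.standardize,
        },
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(snap, fh, sort_keys=False)
    for a, table in run.accuracy_tables.items():
        adir = out / a
        adir.mkdir(exist_ok=True)
        table.to_csv(adir / "accuracies.csv", index=False)
        g = run.group[a]
        payload: dict = {}
        for k, v in g.items():
            payload[k] = v.to_dict(orient="records") if isinstance(v, pd.DataFrame) else v
        with open(adir / "group.json", "w") as fh:
            json.dump(payload, fh, indent=1, default=float)
        with open(adir / "decoding.json", "w") as fh:
            json.dump(
                [
                    r.to_dict() if run.settings.save_fold_detail else {
                        k: v for k, v in r.to_dict().items() if k != "folds"
                    }
                    for r in run.results[a]
                ],
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# chance calibration at scale


def null_chance_experiment(
    n_runs: int = 100,
    seed: int = 0,
    grid_dims: tuple = (14, 14, 10),
    roi_voxels: int = 16,
    trials_per_class: int = 40,
    fwhm_mm: float = 3.0,
    radius_voxels: int = 3,
    noise_sd: float = 1.0,
) -> dict:
    """Mean decoding accuracy of the full pipeline under the null.

    Each run simulates one subject-ROI with zero embedded pattern
    amplitude, runs smoothing, the per-trial GLM and the nested
    searchlight + SVM leave-one-out decoder, and labels the trials with a
    randomly permuted balanced class vector.  Returns per-run accuracies
    and their mean; under the null the expected accuracy is the 50%
    chance level.
    """
    from .synth import make_blob_mask  # local import to avoid cycle noise

    accs = np.empty(n_runs)
    for r in range(n_runs):
        run_seed = subject_seed(seed, r)
        cfg = SimulationConfig(
            n_subjects=1,
            grid_dims=grid_dims,
            n_repeats_per_stimulus=trials_per_class,
            pattern_amplitude=0.0,
            noise_sd=noise_sd,
            seed=run_seed,
        )
        mask = make_blob_mask(grid_dims, roi_voxels, seed=run_seed)
        rng = np.random.default_rng([23, run_seed])
        n = 2 * trials_per_class
        events = pd.DataFrame(
            {
                "onset_s": np.arange(n) * cfg.trial_block_s,
                "morph_fraction": rng.permutation(
                    np.repeat([1.0, 0.0], trials_per_class)
                ),
                "choice": "none",
                "confidence": pd.array([2] * n, dtype="Int64"),
                "correct": pd.array([pd.NA] * n, dtype="boolean"),
                "decision_made": True,
            }
        )
        events["correct"] = pd.array(
            [True if f in (0.0, 1.0) else pd.NA for f in events["morph_fraction"]],
            dtype="boolean",
        )
        validate_events(events)
        truth = make_ground_truth([mask], events, cfg)
        bold = simulate_bold(events, [mask], truth, cfg)
        bold = smooth_gaussian(bold, fwhm_mm)
        design = build_design(events, bold.n_scans, cfg.tr_s, stim_duration_s=cfg.stim_s)
        betas = fit_beta_series(bold, design, mask, units="t")
        labels = rng.permutation(np.repeat(["A", "B"], trials_per_class))
        res = loo_decode(
            betas, labels, SearchlightSpec(mask, radius_voxels)
        )
        accs[r] = res.accuracy
    return {
        "accuracies": accs,
        "mean": float(accs.mean()),
        "sem": float(accs.std(ddof=1) / np.sqrt(n_runs)),
        "n": int(n_runs),
    }
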