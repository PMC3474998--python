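"""The motor-confound control: train on scenes, test on ambiguous morphs.

If scene decoding were driven by response-related signals (the two scenes
map to two button presses), a classifier trained on the unambiguous
scenes should also decode the choices made on 50%-morph trials.  The
generator's ``morph_pattern_share`` dials exactly this: 0 gives the
ambiguous trials their own decision-state patterns (no transfer expected),
1 reuses the scene patterns (full transfer).
"""

from hippomvpa import SimulationConfig, run_cohort
from hippomvpa.pipeline import AnalysisSettings

targets = {"CA1": 20, "CA3": 18, "DG": 14, "SUB": 10}
for share in (0.0, 1.0):
    cfg = SimulationConfig(
        n_subjects=2, grid_dims=(14, 14, 8), n_repeats_per_stimulus=8,
        pattern_amplitude=1.0, noise_sd=1.0, morph_pattern_share=share,
        seed=11, roi_target_counts=targets,
    )
    run = run_cohort(cfg, AnalysisSettings(analyses=("scenes", "cross")))
    within = run.accuracy_tables["scenes"]["accuracy"].mean()
    transfer = run.accuracy_tables["cross"]["accuracy"].mean()
    print(f"pattern share {share:.0%}: within-condition {within:.3f}, "
          f"cross-condition {transfer:.3f}")

print("\nwith share 0 the transfer sits at chance (~0.5) while the within-"
      "condition accuracy stays high: scene decoding is not explained by a "
      "condition-general confound")
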