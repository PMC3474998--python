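"""Simulate one synthetic subject and look at what the generator made.

Builds the eight bilateral subfield masks, the 9 × 40 trial schedule with
behaviour, and the 4D BOLD run with embedded category patterns.
"""

from hippomvpa import SimulationConfig, filter_trials
from hippomvpa.pipeline import simulate_subject

config = SimulationConfig(seed=7)
masks, events, truth, bold = simulate_subject(config, subject_id=0)

print("ROI voxel counts (target: CA1 267, CA3 248, DG 183, SUB 111):")
for m in masks:
    print(f"  {m.key():7s} {m.n_voxels}")

print(f"\ntrials: {len(events)} (9 categories x 40 presentations)")
print(f"BOLD grid {bold.data.shape[:3]}, {bold.n_scans} scans at TR {bold.tr_s}s")

scenes = filter_trials(events, "original_scenes")
morph50 = filter_trials(events, "morph50")
print(f"\nafter exclusions: {len(scenes)}/80 unambiguous scene trials kept,")
print(f"                  {len(morph50)}/40 50%-morph trials kept")
print("(excluded: no decision, incorrect [scenes only], or rated 'not sure')")
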