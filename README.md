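# hippomvpa

Multi-voxel pattern analysis (MVPA) of hippocampal subfields, as a tested,
reusable Python pipeline. The package implements the analysis chain used to
ask whether the human hippocampal subfields — CA1, CA3, dentate gyrus (DG)
and subiculum (SUB) — carry decodable information about which of two highly
similar scenes a person is seeing or deciding about:

1. **Synthetic cohort generator** — a forward model of the scene-morph
   decision experiment (two original scenes plus seven morphs, 40
   presentations each; 2.5 s stimulus / 3 s confidence / 2 s rest trials;
   1.5 mm voxels at TR 3.5 s; eight bilateral subfield ROIs with realistic
   voxel counts; logistic psychometric choices with confidence ratings) with
   known ground-truth multivoxel patterns, so every downstream stage can be
   validated against what was embedded.
2. **Beta-series GLM** — 3-mm FWHM smoothing, one HRF-convolved regressor
   per trial, per-voxel ordinary least squares: a trials × voxels
   coefficient matrix per ROI.
3. **Two-step decoding** — for each voxel of an ROI, a searchlight sphere of
   radius 3 voxels (clipped to the ROI) is scored by the leave-one-out
   accuracy of a linear SVM (C = 1) on its local pattern; the best-scoring
   neighbourhoods are selected *within the training data of each outer
   fold only*, and an SVM on the selected voxels predicts the held-out
   trial. Cross-condition decoding (train on unambiguous scenes, test on
   ambiguous 50% morphs) checks whether representations transfer.
4. **Segmentation reliability** — the Dice overlap
   `2|A∩B| / (|A| + |B|)`, full-volume or restricted to five consecutive
   slices, as used to validate manual subfield delineation.
5. **Group statistics** — per-region one-sample t-tests against 50% chance,
   a one-way repeated-measures ANOVA across subfields, pairwise paired
   t-tests, and a per-region hemisphere check before collapsing.

Intended users: neuroimaging methods researchers who want a transparent,
fully seeded reference implementation of nested (leakage-free) searchlight
feature selection, and anyone teaching or stress-testing MVPA pipelines
against a generator with known ground truth.

## Worked example

`examples/05_cross_decoding_control.py` reproduces the motor-confound
dissociation on a small synthetic cohort:

```
pattern share 0%: within-condition 1.000, cross-condition 0.458
pattern share 100%: within-condition 1.000, cross-condition 1.000
```

With `morph_pattern_share = 0` the ambiguous 50%-morph trials carry
decision-state patterns unrelated to the scene patterns: a classifier
trained on the scenes decodes them at chance (0.458 ≈ 0.5) even though
within-condition accuracy is at ceiling — so scene decoding cannot be
explained by a condition-general (e.g. motor/response) signal. With full
pattern sharing the same transfer succeeds (1.000).

`examples/06_group_statistics.py` runs a weak-signal four-subject cohort
end to end and prints the group tests:

```
per-region one-sample t-tests vs chance (50%):
  CA1: t(3) = 7.415, p = 0.0051
  CA3: t(3) = 7.635, p = 0.0047
  DG: t(3) = 9.219, p = 0.0027
  SUB: t(3) = 13.422, p = 0.0009

one-way repeated-measures ANOVA across subfields: F(3, 9) = 1.765, p = 0.2236
```

All four subfields decode above chance while no region differs reliably
from the others, and the hemisphere checks stay non-significant (results
are averaged across hemispheres).

The other examples cover the generator (`01`), the beta-series GLM (`02`),
Dice reliability (`03`) and single-ROI decoding (`04`); each runs in
seconds with `python examples/<name>.py`.

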