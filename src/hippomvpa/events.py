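"""Per-trial event tables: schema, validation, trial-exclusion rules, I/O.

An event table has one row per trial with columns

========== =============================================================
onset_s     stimulus onset, seconds from run start (strictly increasing)
morph_fraction  proportion of scene A in the stimulus, in [0, 1]
choice      ``"A"``, ``"B"``, or ``"none"`` (no decision registered)
confidence  1 = not sure, 2 = fairly sure, 3 = very sure (NA if none)
correct     nullable boolean; defined only for the unambiguous stimuli
            (morph_fraction 0 or 1) where a correct answer exists
decision_made  boolean
========== =============================================================
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = [
    "onset_s",
    "morph_fraction",
    "choice",
    "confidence",
    "correct",
    "decision_made",
]

#: Morph continuum: proportion of scene A in each of the 9 stimulus categories.
MORPH_FRACTIONS = (1.0, 0.7, 0.6, 0.55, 0.5, 0.45, 0.4, 0.3, 0.0)

ANALYSES = ("original_scenes", "morph50")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check the event-table schema and invariants; return the table."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    onsets = events["onset_s"].to_numpy(dtype=float)
    if onsets.size and (np.any(onsets < 0) or np.any(np.diff(onsets) <= 0)):
        raise ValueError("onsets must be nonnegative and strictly increasing")
    frac = events["morph_fraction"].to_numpy(dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("morph_fraction outside [0, 1]")
    bad = events["correct"].notna() & ~events["morph_fraction"].isin([0.0, 1.0])
    if bad.any():
        raise ValueError(
            "correctness is defined only for morph_fraction 0 or 1 "
            f"(rows {list(events.index[bad])[:5]} ...)"
        )
    return events


def filter_trials(events: pd.DataFrame, analysis: str) -> pd.DataFrame:
    """Apply the per-analysis trial-exclusion rules.

    ``"original_scenes"`` keeps unambiguous trials (morph_fraction 0 or 1)
    where a decision was made, the decision was correct, and confidence was
    at least "fairly sure".  ``"morph50"`` keeps 50%-morph trials where a
    decision was made with confidence at least "fairly sure"; there is no
    correctness rule because the ambiguous stimulus has no right answer.

    Idempotent: filtering an already-filtered table changes nothing.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}")
    validate_events(events)
    decided = events["decision_made"].astype(bool)
    confident = events["confidence"].fillna(0).astype(int) >= 2
    if analysis == "original_scenes":
        keep = (
            events["morph_fraction"].isin([0.0, 1.0])
            & decided
            & (events["correct"] == True)  # noqa: E712 — nullable boolean
            & confident
        )
    else:
        keep = (events["morph_fraction"] == 0.5) & decided & confident
    out = events.loc[keep].copy()
    if out.empty:
        warnings.warn(
            f"filter_trials({analysis!r}) retained no trials", stacklevel=2
        )
    return out


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write the table as tab-delimited text with header (NA for missing)."""
    validate_events(events)
    out = events.copy()
    out["correct"] = out["correct"].map(
        lambda v: "NA" if pd.isna(v) else ("true" if v else "false")
    )
    out["confidence"] = out["confidence"].map(
        lambda v: "NA" if pd.isna(v) else str(int(v))
    )
    out["decision_made"] = out["decision_made"].map(lambda v: "true" if v else "false")
    out.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["correct"] = df["correct"].map(
        lambda v: pd.NA if pd.isna(v) else str(v).lower() == "true"
    ).astype("boolean")
    df["confidence"] = df["confidence"].astype("Int64")
    df["decision_made"] = df["decision_made"].map(
        lambda v: str(v).lower() == "true"
    )
    return validate_events(df)
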