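"""Group-level inference on classifier accuracies.

Per-region accuracies are compared to the 50% chance level with one-sample
t-tests, regions are compared with a one-way repeated-measures ANOVA
(followed by paired t-tests), and a per-region two-level repeated-measures
test checks for hemispheric differences before results are collapsed
(averaged) across hemispheres.  The decision threshold throughout is
p < 0.05, uncorrected, mirroring common reporting practice; no sphericity
or multiple-comparison correction is applied by default.

Zero-variance inputs are reported as flagged degenerate cases rather than
errors: identical values at the reference give t = 0, p = 1; a constant
nonzero offset gives t = ±inf, p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi import SUBFIELDS

ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class RmAnovaResult:
    F: float
    df_between: int
    df_error: int
    p: float
    degenerate: bool = False


def ttest_vs_chance(accuracies, chance: float = 0.5) -> TTestResult:
    """Two-sided one-sample t-test of accuracies against a chance level."""
    x = np.asarray(accuracies, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1D vector of at least two accuracies")
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0.0:
        mean_off = x.mean() - chance
        if mean_off == 0.0:
            return TTestResult(0.0, n - 1, 1.0, degenerate=True)
        return TTestResult(
            math_inf_sign(mean_off), n - 1, 0.0, degenerate=True
        )
    res = sps.ttest_1samp(x, chance)
    return TTestResult(float(res.statistic), n - 1, float(res.pvalue))


def math_inf_sign(v: float) -> float:
    return float(np.inf) if v > 0 else float(-np.inf)


def _to_wide(table: pd.DataFrame, value: str = "accuracy") -> pd.DataFrame:
    """Accept subjects × regions wide input, or long with subject/subfield."""
    if {"subject", "subfield", value} <= set(table.columns):
        wide = table.pivot_table(
            index="subject", columns="subfield", values=value, aggfunc="mean"
        )
        ordered = [s for s in SUBFIELDS if s in wide.columns]
        other = [c for c in wide.columns if c not in ordered]
        return wide[ordered + other]
    return table.astype(float)


def rm_anova(table: pd.DataFrame) -> RmAnovaResult:
    """One-way repeated-measures ANOVA across regions.

    ``F = MS_regions / MS_(subject × region)`` with degrees of freedom
    ``(r − 1, (r − 1)(n − 1))`` from the classical sums-of-squares
    decomposition; subject main effects are removed, so adding a constant
    per subject leaves F unchanged.  The table must be complete.
    """
    wide = _to_wide(table)
    if wide.isna().any().any():
        raise ValueError("repeated-measures ANOVA requires a complete table")
    X = wide.to_numpy(dtype=float)
    n, r = X.shape
    if n < 2 or r < 2:
        raise ValueError("need at least 2 subjects and 2 regions")
    gm = X.mean()
    ss_cond = n * np.sum((X.mean(axis=0) - gm) ** 2)
    ss_subj = r * np.sum((X.mean(axis=1) - gm) ** 2)
    ss_tot = np.sum((X - gm) ** 2)
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df_b = r - 1
    df_e = (r - 1) * (n - 1)
    # relative tolerance guards the degenerate branches against float noise
    tol = 1e-12 * max(ss_tot, np.finfo(float).tiny)
    if ss_err <= tol:
        if ss_cond <= tol:
            return RmAnovaResult(0.0, df_b, df_e, 1.0, degenerate=True)
        return RmAnovaResult(float(np.inf), df_b, df_e, 0.0, degenerate=True)
    F = (ss_cond / df_b) / (ss_err / df_e)
    p = float(sps.f.sf(F, df_b, df_e))
    return RmAnovaResult(float(F), df_b, df_e, p)


def paired_ttests(
    table: pd.DataFrame, pairs: list | None = None
) -> pd.DataFrame:
    """Paired two-sided t-tests between region columns.

    Defaults to all six pairs of the four subfields.  Each test reduces to
    a one-sample t-test of the paired differences against zero, df = n − 1.
    """
    wide = _to_wide(table)
    if pairs is None:
        pairs = list(combinations([s for s in SUBFIELDS if s in wide.columns], 2))
    rows = []
    for a, b in pairs:
        if a not in wide.columns or b not in wide.columns:
            raise ValueError(f"unknown region pair ({a}, {b})")
        diff = wide[a].to_numpy(dtype=float) - wide[b].to_numpy(dtype=float)
        res = ttest_vs_chance(diff, chance=0.0)
        rows.append(
            {
                "region_a": a,
                "region_b": b,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)


def hemisphere_check_and_collapse(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Left-vs-right check per region, then collapse across hemispheres.

    ``table`` is long format with columns subject, subfield, hemisphere,
    accuracy (both hemispheres required for every subject × region).  The
    per-region check is a two-level repeated-measures ANOVA, numerically
    identical to the square of the paired t-test.  The collapsed table is
    the per-subject mean of the two hemispheres regardless of the test
    outcome; the test results are returned alongside.
    """
    need = {"subject", "subfield", "hemisphere", "accuracy"}
    if not need <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(need)}")
    rows = []
    for sub in sorted(table["subfield"].unique(), key=_subfield_order):
        piv = table[table["subfield"] == sub].pivot_table(
            index="subject", columns="hemisphere", values="accuracy"
        )
        if not {"L", "R"} <= set(piv.columns) or piv[["L", "R"]].isna().any().any():
            raise ValueError(f"missing hemisphere data for {sub}")
        res = rm_anova(piv[["L", "R"]])
        rows.append(
            {
                "subfield": sub,
                "F": res.F,
                "df_between": res.df_between,
                "df_error": res.df_error,
                "p": res.p,
                "degenerate": res.degenerate,
            }
        )
    check = pd.DataFrame(rows)
    collapsed = (
        table.groupby(["subject", "subfield"], as_index=False)["accuracy"]
        .mean()
        .pivot(index="subject", columns="subfield", values="accuracy")
    )
    ordered = [s for s in SUBFIELDS if s in collapsed.columns]
    other = [c for c in collapsed.columns if c not in ordered]
    return check, collapsed[ordered + other]


def _subfield_order(s: str) -> tuple:
    try:
        return (0, SUBFIELDS.index(s))
    except ValueError:
        return (1, 0)
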