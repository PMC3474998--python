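"""Two-step MVPA: searchlight feature selection, then linear-SVM decoding.

For every voxel of a region of interest, a sphere of radius three voxels
(clipped to the ROI near its borders) defines a local neighbourhood, and the
leave-one-out cross-validated accuracy of a linear SVM (C = 1) on that
neighbourhood's trial betas scores how much decodable information the
voxel's local environment carries.  The best-scoring neighbourhoods are
selected — strictly within the training data of each outer fold — and a
linear SVM on the selected voxels predicts the held-out trial.  The outer
loop is leave-one-trial-out, so feature selection never sees the test
trial (no leakage).  Cross-condition decoding trains on one condition and
tests once on another to ask whether the representation transfers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .glm import BetaSeries
from .roi import RoiMask
from .svm import (
    DEFAULT_C,
    DEFAULT_TOL,
    MAX_EPOCHS_COLD,
    LinearSvm,
    _fit_cold,
    pair_loo_correct,
    single_loo_correct,
)


@dataclass
class SearchlightSpec:
    """Sphere radius (voxels) and the ROI that clips every sphere."""

    restriction_mask: RoiMask
    radius_voxels: int = 3

    def __post_init__(self) -> None:
        if self.radius_voxels < 1:
            raise ValueError("radius_voxels must be >= 1")
        if self.restriction_mask.n_voxels == 0:
            raise ValueError("restriction mask is empty")


@dataclass(frozen=True)
class SvmSpec:
    """Linear kernel only; fixed regularization ``c`` (default 1)."""

    kernel: str = "linear"
    c: float = DEFAULT_C
    tol: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if self.c <= 0:
            raise ValueError("c must be > 0")


@dataclass(frozen=True)
class SelectionRule:
    """How searchlight scores turn into a selected voxel set.

    ``union_top`` (default) ranks centres by score (ties broken by
    lexicographic centre coordinate) and unions their neighbourhoods until
    the union covers ``target_fraction`` of the ROI; ``single_best`` takes
    just the top centre's neighbourhood.  The default fraction of 0.6
    selects about 160 voxels from a CA1-sized (~267 voxel) ROI.
    """

    kind: str = "union_top"
    target_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.kind not in ("union_top", "single_best"):
            raise ValueError(f"unknown selection rule {self.kind!r}")
        if not 0.0 < self.target_fraction <= 1.0:
            raise ValueError("target_fraction must be in (0, 1]")


@dataclass
class FoldRecord:
    """One outer fold: what was selected, predicted, and true."""

    test_trial: int
    selected_voxels: list
    prediction: object
    truth: object

    @property
    def correct(self) -> bool:
        return self.prediction == self.truth


@dataclass
class DecodingResult:
    """Cross-validated accuracy plus per-fold bookkeeping for one ROI."""

    accuracy: float
    n_test: int
    mean_selected_voxels: float
    classes: tuple
    folds: list = field(default_factory=list)
    subject_id: int | None = None
    subfield: str | None = None
    hemisphere: str | None = None

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "subfield": self.subfield,
            "hemisphere": self.hemisphere,
            "accuracy": self.accuracy,
            "n_test": self.n_test,
            "mean_selected_voxels": self.mean_selected_voxels,
            "classes": [str(c) for c in self.classes],
            "folds": [
                {
                    "test_trial": int(f.test_trial),
                    "selected_voxels": [list(map(int, v)) for v in f.selected_voxels],
                    "prediction": str(f.prediction),
                    "truth": str(f.truth),
                }
                for f in self.folds
            ],
        }


def sphere_offsets(radius: int) -> set:
    """All integer offsets with squared norm ≤ radius² (incl. the origin)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r2 = radius * radius
    return {
        (dx, dy, dz)
        for dx in range(-radius, radius + 1)
        for dy in range(-radius, radius + 1)
        for dz in range(-radius, radius + 1)
        if dx * dx + dy * dy + dz * dz <= r2
    }


def searchlight_neighborhood(
    center: tuple, spec: SearchlightSpec
) -> set:
    """Sphere around a centre, clipped to the restriction mask.

    Near ROI borders the clipped sphere is smaller than the full
    123-voxel radius-3 ball, so its shape and size vary across centres.
    """
    mask = spec.restriction_mask.data
    cx, cy, cz = (int(c) for c in center)
    if not (
        0 <= cx < mask.shape[0]
        and 0 <= cy < mask.shape[1]
        and 0 <= cz < mask.shape[2]
        and mask[cx, cy, cz]
    ):
        raise ValueError(f"center {center} is outside the restriction mask")
    out = set()
    for dx, dy, dz in sphere_offsets(spec.radius_voxels):
        x, y, z = cx + dx, cy + dy, cz + dz
        if 0 <= x < mask.shape[0] and 0 <= y < mask.shape[1] and 0 <= z < mask.shape[2]:
            if mask[x, y, z]:
                out.add((x, y, z))
    return out


# ---------------------------------------------------------------------------
# internal geometry/label preparation


class _Prepared:
    """Betas aligned to mask voxels, with flattened neighbourhood indices."""

    def __init__(self, betas: BetaSeries, spec: SearchlightSpec):
        mask = spec.restriction_mask.data
        coords = betas.voxel_coords
        col_of = {tuple(c): i for i, c in enumerate(coords)}
        in_mask = np.array([mask[tuple(c)] for c in coords], dtype=bool)
        self.center_cols = np.flatnonzero(in_mask)
        if self.center_cols.size == 0:
            raise ValueError("no beta voxels fall inside the restriction mask")
        self.center_coords = [tuple(coords[i]) for i in self.center_cols]
        offs = sorted(sphere_offsets(spec.radius_voxels))
        nb_cols: list[np.ndarray] = []
        for c in self.center_coords:
            cols = []
            for dx, dy, dz in offs:
                v = (c[0] + dx, c[1] + dy, c[2] + dz)
                if (
                    0 <= v[0] < mask.shape[0]
                    and 0 <= v[1] < mask.shape[1]
                    and 0 <= v[2] < mask.shape[2]
                    and mask[v]
                ):
                    col = col_of.get(v)
                    if col is not None:
                        cols.append(col)
            nb_cols.append(np.array(sorted(cols), dtype=np.int64))
        self.nb_cols = nb_cols
        self.nb_len = np.array([a.size for a in nb_cols], dtype=np.int64)
        self.nb_start = np.concatenate([[0], np.cumsum(self.nb_len[:-1])]).astype(
            np.int64
        )
        self.nb_flat = (
            np.concatenate(nb_cols) if nb_cols else np.empty(0, dtype=np.int64)
        )
        self.B = np.ascontiguousarray(betas.betas, dtype=np.float64)
        self.coords = coords
        self.n_roi_voxels = spec.restriction_mask.n_voxels


def _signed_labels(labels, min_per_class: int):
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(
            f"exactly two classes required, got {classes!r}"
        )
    counts = [(y == c).sum() for c in classes]
    if min(counts) < min_per_class:
        raise ValueError(
            f"each class needs at least {min_per_class} trials "
            f"(got {dict(zip(classes.tolist(), counts))}); collect more "
            "trials or relax the exclusion rules"
        )
    return np.where(y == classes[0], -1.0, 1.0), classes


def _rank_centers(scores: np.ndarray, center_coords: list) -> list:
    order = sorted(
        range(len(center_coords)), key=lambda i: (-scores[i], center_coords[i])
    )
    return order


def _select_cols(
    order: list, prep: _Prepared, rule: SelectionRule
) -> np.ndarray:
    if rule.kind == "single_best":
        return prep.nb_cols[order[0]]
    target = math.ceil(rule.target_fraction * prep.n_roi_voxels)
    union: set = set()
    for i in order:
        union.update(prep.nb_cols[i].tolist())
        if len(union) >= target:
            break
    return np.array(sorted(union), dtype=np.int64)


# ---------------------------------------------------------------------------
# public operations


def _fold_scaler(B: np.ndarray, rows: np.ndarray):
    """Per-voxel mean/sd of the training rows (sd floored to avoid 0/0)."""
    mu = B[rows].mean(axis=0)
    sd = B[rows].std(axis=0, ddof=0)
    sd = np.where(sd > 0.0, sd, 1.0)
    return mu, sd


def searchlight_scores(
    train_betas: BetaSeries,
    train_labels,
    spec: SearchlightSpec,
    svm: SvmSpec = SvmSpec(),
    standardize: bool = False,
) -> dict:
    """Leave-one-out SVM accuracy of each voxel's local neighbourhood.

    Computed strictly within the supplied training set (the k folds of the
    inner cross-validation, with k = number of training trials).  With
    ``standardize`` (the default) features are z-scored per voxel using
    the supplied trials before scoring.  Returns ``{center coordinate:
    score}``.
    """
    prep = _Prepared(train_betas, spec)
    y, _ = _signed_labels(train_labels, min_per_class=1)
    B = prep.B
    if standardize:
        mu, sd = _fold_scaler(B, np.arange(B.shape[0]))
        B = np.ascontiguousarray((B - mu) / sd)
    table = single_loo_correct(
        B, prep.nb_flat, prep.nb_start, prep.nb_len, y, svm.c, svm.tol, -1
    )
    scores = table.mean(axis=1)
    return {c: float(s) for c, s in zip(prep.center_coords, scores)}


def select_features(
    scores: dict, spec: SearchlightSpec, rule: SelectionRule = SelectionRule()
) -> set:
    """Turn a centre → score map into a selected voxel set.

    Centres are ranked by score with lexicographic coordinate tie-breaks;
    the returned set is a union of clipped-sphere neighbourhoods (a single
    one under the ``single_best`` rule) and always lies inside the ROI.
    """
    if not scores:
        raise ValueError("empty score map")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if rule.kind == "single_best":
        return searchlight_neighborhood(ranked[0][0], spec)
    target = math.ceil(rule.target_fraction * spec.restriction_mask.n_voxels)
    union: set = set()
    for center, _ in ranked:
        union.update(searchlight_neighborhood(center, spec))
        if len(union) >= target:
            break
    return union


def loo_decode(
    betas: BetaSeries,
    labels,
    spec: SearchlightSpec,
    svm: SvmSpec = SvmSpec(),
    rule: SelectionRule = SelectionRule(),
    standardize: bool = False,
) -> DecodingResult:
    """Outer leave-one-trial-out decoding with nested feature selection.

    Within each fold the searchlight scores and the selected voxel set are
    recomputed from the n−1 training trials alone, an SVM is trained on the
    selected voxels, and the held-out trial is predicted.  With
    ``standardize`` (the default) features are z-scored per voxel with
    mean/sd fit on each fold's training trials.  The held-out trial can
    influence neither the scaling nor the scores nor the selection of its
    fold.
    """
    prep = _Prepared(betas, spec)
    y, classes = _signed_labels(labels, min_per_class=2)
    n = prep.B.shape[0]
    if not standardize:
        # features identical across folds: one leave-two-out table serves
        # every fold's inner cross-validation
        pair_table = pair_loo_correct(
            prep.B, prep.nb_flat, prep.nb_start, prep.nb_len, y, svm.c, svm.tol
        ).astype(np.float64)
    folds: list[FoldRecord] = []
    n_correct = 0
    for o in range(n):
        train = np.delete(np.arange(n), o)
        if standardize:
            mu, sd = _fold_scaler(prep.B, train)
            Bo = np.ascontiguousarray((prep.B - mu) / sd)
            inner = single_loo_correct(
                Bo, prep.nb_flat, prep.nb_start, prep.nb_len, y, svm.c, svm.tol, o
            ).astype(np.float64)
            scores = np.delete(inner, o, axis=1).mean(axis=1)
        else:
            Bo = prep.B
            scores = np.delete(pair_table[:, o, :], o, axis=1).mean(axis=1)
        order = _rank_centers(scores, prep.center_coords)
        sel = _select_cols(order, prep, rule)
        X = Bo[:, sel]
        w, _ = _fit_cold(
            np.ascontiguousarray(X[train]), y[train], svm.c, svm.tol, MAX_EPOCHS_COLD
        )
        dec = float(X[o] @ w[:-1] + w[-1])
        pred_signed = 1.0 if dec >= 0.0 else -1.0
        pred = classes[1] if pred_signed > 0 else classes[0]
        truth = classes[1] if y[o] > 0 else classes[0]
        if pred_signed == y[o]:
            n_correct += 1
        folds.append(
            FoldRecord(
                test_trial=int(betas.trial_index[o]),
                selected_voxels=[tuple(prep.coords[i]) for i in sel],
                prediction=pred,
                truth=truth,
            )
        )
    return DecodingResult(
        accuracy=n_correct / n,
        n_test=n,
        mean_selected_voxels=float(
            np.mean([len(f.selected_voxels) for f in folds])
        ),
        classes=tuple(classes.tolist()),
        folds=folds,
        subfield=spec.restriction_mask.subfield,
        hemisphere=spec.restriction_mask.hemisphere,
    )


def cross_decode(
    train_betas: BetaSeries,
    train_labels,
    test_betas: BetaSeries,
    test_labels,
    spec: SearchlightSpec,
    svm: SvmSpec = SvmSpec(),
    rule: SelectionRule = SelectionRule(),
    standardize: bool = False,
) -> DecodingResult:
    """Train on one condition, evaluate once on a disjoint condition.

    Feature selection and SVM training use the full training condition;
    accuracy is the fraction of correctly predicted test-condition trials
    (labels of both conditions must share the same two classes).  With
    ``standardize`` the per-voxel z-scoring is fit on the training
    condition and applied unchanged to the test condition.
    """
    if train_betas.voxel_coords.shape != test_betas.voxel_coords.shape or not np.array_equal(
        train_betas.voxel_coords, test_betas.voxel_coords
    ):
        raise ValueError("train and test beta series cover different voxels")
    prep = _Prepared(train_betas, spec)
    y_tr, classes = _signed_labels(train_labels, min_per_class=1)
    y_te = np.asarray(test_labels)
    unknown = set(np.unique(y_te).tolist()) - set(classes.tolist())
    if unknown:
        raise ValueError(f"test labels outside training classes: {unknown}")
    y_te_signed = np.where(y_te == classes[0], -1.0, 1.0)
    B = prep.B
    Bte = np.asarray(test_betas.betas, dtype=np.float64)
    if standardize:
        mu, sd = _fold_scaler(B, np.arange(B.shape[0]))
        B = np.ascontiguousarray((B - mu) / sd)
        Bte = (Bte - mu) / sd
    table = single_loo_correct(
        B, prep.nb_flat, prep.nb_start, prep.nb_len, y_tr, svm.c, svm.tol, -1
    )
    scores = table.mean(axis=1)
    order = _rank_centers(scores, prep.center_coords)
    sel = _select_cols(order, prep, rule)
    w, _ = _fit_cold(
        np.ascontiguousarray(B[:, sel]), y_tr, svm.c, svm.tol, MAX_EPOCHS_COLD
    )
    Xte = np.ascontiguousarray(Bte[:, sel])
    dec = Xte @ w[:-1] + w[-1]
    pred_signed = np.where(dec >= 0.0, 1.0, -1.0)
    n_correct = int(np.sum(pred_signed == y_te_signed))
    folds = [
        FoldRecord(
            test_trial=int(test_betas.trial_index[i]),
            selected_voxels=[tuple(prep.coords[j]) for j in sel],
            prediction=classes[1] if pred_signed[i] > 0 else classes[0],
            truth=classes[1] if y_te_signed[i] > 0 else classes[0],
        )
        for i in range(len(y_te))
    ]
    return DecodingResult(
        accuracy=n_correct / len(y_te),
        n_test=len(y_te),
        mean_selected_voxels=float(len(sel)),
        classes=tuple(classes.tolist()),
        folds=folds,
        subfield=spec.restriction_mask.subfield,
        hemisphere=spec.restriction_mask.hemisphere,
    )
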