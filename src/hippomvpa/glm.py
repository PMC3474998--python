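"""Per-trial beta-series estimation: smoothing, design construction, OLS.

The decoding features are "beta series": each trial is modelled as its own
regressor (the stimulus boxcar convolved with the canonical haemodynamic
response function), nuisance regressors and an intercept are appended, and
ordinary least squares per voxel yields one coefficient image per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.linalg import qr
from scipy.stats import gamma

from .events import validate_events
from .roi import RoiMask

#: FWHM → Gaussian sigma conversion factor, 2·sqrt(2·ln 2).
FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

DEFAULT_STIM_DURATION_S = 2.5
OVERSAMPLING = 16


@dataclass
class Bold4D:
    """A 4D BOLD run on a voxel grid.

    ``data`` is (x, y, z, time); ``tr_s`` the repetition time in seconds;
    ``voxel_size_mm`` the isotropic voxel edge length.  Volume ``k`` is
    taken to sample time ``k * tr_s``.
    """

    data: np.ndarray
    tr_s: float = 3.5
    voxel_size_mm: float = 1.5

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {arr.shape}")
        if arr.shape[3] < 1:
            raise ValueError("time dimension must be >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("BOLD data contains non-finite values")
        if self.tr_s <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("tr_s and voxel_size_mm must be positive")
        self.data = arr

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma haemodynamic response parameters (seconds).

    Defaults are the conventional "canonical" shape: response peak around
    6 s, undershoot around 16 s, unit dispersions, undershoot one sixth of
    the peak, 32 s kernel.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        if min(
            self.peak_delay_s,
            self.undershoot_delay_s,
            self.peak_dispersion_s,
            self.undershoot_dispersion_s,
        ) <= 0:
            raise ValueError("HRF delays and dispersions must be positive")
        if self.length_s <= self.peak_delay_s:
            raise ValueError("kernel length must exceed the peak delay")


@dataclass
class BetaSeries:
    """Trial × voxel matrix of GLM coefficients.

    ``betas[t, v]`` is the coefficient of trial ``t``'s regressor at voxel
    ``v``; ``voxel_coords`` holds the 0-based grid index triple of each
    column; ``trial_index`` aligns rows to event-table rows.
    """

    betas: np.ndarray
    trial_index: np.ndarray
    voxel_coords: np.ndarray
    roi_label: str | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=np.float64)
        self.trial_index = np.asarray(self.trial_index)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=np.intp)
        if self.betas.ndim != 2:
            raise ValueError("betas must be 2D (trials × voxels)")
        if self.trial_index.shape[0] != self.betas.shape[0]:
            raise ValueError("trial_index length must match beta rows")
        if self.voxel_coords.shape != (self.betas.shape[1], 3):
            raise ValueError("voxel_coords must be (n_voxels, 3)")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def subset_trials(self, rows: np.ndarray) -> "BetaSeries":
        rows = np.asarray(rows)
        return BetaSeries(
            self.betas[rows], self.trial_index[rows], self.voxel_coords, self.roi_label
        )


@dataclass
class DesignMatrix:
    """GLM design: task columns first, then nuisance, then the intercept."""

    matrix: np.ndarray
    names: list[str]
    n_task: int

    @property
    def task(self) -> np.ndarray:
        return self.matrix[:, : self.n_task]


def smooth_gaussian(bold: Bold4D, fwhm_mm: float) -> Bold4D:
    """Spatially smooth each volume with an isotropic Gaussian kernel.

    ``sigma = fwhm / (2·sqrt(2·ln 2))`` converted to voxel units; boundary
    handling is reflective, which preserves the total image sum.  A FWHM of
    0 returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return replace(bold, data=bold.data.copy())
    sigma_vox = fwhm_mm / FWHM_SIGMA / bold.voxel_size_mm
    out = ndimage.gaussian_filter(
        bold.data, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0), mode="reflect"
    )
    return replace(bold, data=out)


def canonical_hrf(tr_s: float, params: HrfParams = HrfParams()) -> np.ndarray:
    """Difference-of-gammas response kernel sampled every ``tr_s`` seconds.

    Scaled to unit peak.  With the default parameters the mode of the
    continuous kernel sits at ``peak_delay − dispersion`` = 5 s.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    t = np.arange(0.0, params.length_s, tr_s)
    h = gamma.pdf(
        t, a=params.peak_delay_s / params.peak_dispersion_s,
        scale=params.peak_dispersion_s,
    ) - params.undershoot_ratio * gamma.pdf(
        t,
        a=params.undershoot_delay_s / params.undershoot_dispersion_s,
        scale=params.undershoot_dispersion_s,
    )
    peak = np.max(h)
    if peak <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return h / peak


def build_design(
    events: pd.DataFrame,
    n_scans: int,
    tr_s: float,
    nuisance: np.ndarray | None = None,
    stim_duration_s: float = DEFAULT_STIM_DURATION_S,
    hrf: HrfParams = HrfParams(),
) -> DesignMatrix:
    """One HRF-convolved boxcar regressor per trial, plus nuisance + intercept.

    Regressors are built on a 16×-oversampled time grid (onsets need not be
    TR multiples) and decimated at the scan acquisition times ``k · tr_s``.
    Column order: trials in event order, nuisance columns, constant.
    """
    validate_events(events)
    onsets = events["onset_s"].to_numpy(dtype=float)
    if np.unique(onsets).size != onsets.size:
        raise ValueError("duplicate trial onsets")
    total_s = n_scans * tr_s
    if onsets.size and onsets[-1] + stim_duration_s > total_s:
        raise ValueError(
            f"events extend to {onsets[-1] + stim_duration_s:.1f} s, beyond "
            f"the run duration {total_s:.1f} s"
        )
    dt = tr_s / OVERSAMPLING
    n_fine = n_scans * OVERSAMPLING
    kernel = canonical_hrf(dt, hrf)
    n_trials = onsets.size
    task = np.zeros((n_scans, n_trials))
    for j, onset in enumerate(onsets):
        box = np.zeros(n_fine)
        i0 = int(np.round(onset / dt))
        i1 = min(int(np.round((onset + stim_duration_s) / dt)), n_fine)
        box[i0:i1] = 1.0
        conv = np.convolve(box, kernel)[:n_fine]
        task[:, j] = conv[:: OVERSAMPLING]
    names = [f"trial_{j:03d}" for j in range(n_trials)]
    cols = [task]
    if nuisance is not None and np.size(nuisance):
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            raise ValueError(
                f"nuisance rows ({nuisance.shape[0]}) != n_scans ({n_scans})"
            )
        cols.append(nuisance)
        names += [f"nuisance_{j:02d}" for j in range(nuisance.shape[1])]
    cols.append(np.ones((n_scans, 1)))
    names.append("intercept")
    return DesignMatrix(np.hstack(cols), names, n_trials)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # rank-revealing QR: pivots beyond the numerical rank are the culprits
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    return [names[p] for p in piv[rank:]]


def fit_beta_series(
    bold: Bold4D,
    design: DesignMatrix,
    mask: RoiMask | None = None,
    units: str = "beta",
) -> BetaSeries:
    """Per-voxel ordinary least squares; returns the task coefficients only.

    With a mask, columns cover the mask voxels in lexicographic coordinate
    order; without, every voxel of the grid.

    ``units="beta"`` returns the raw parameter estimates; ``units="t"``
    divides each coefficient by its standard error (per-voxel residual sd ×
    the regressor's leverage factor), i.e. per-trial t-statistic maps.
    t units put every voxel and trial on a common noise scale, which
    matters for classifiers with fixed hyperparameters; the scaling uses
    only the design and the residual variance of the whole run, never any
    trial labels or train/test split.
    """
    if units not in ("beta", "t"):
        raise ValueError(f"units must be 'beta' or 't', got {units!r}")
    X = design.matrix
    if X.shape[0] != bold.n_scans:
        raise ValueError(
            f"design rows ({X.shape[0]}) != number of scans ({bold.n_scans})"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, design.names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    if mask is not None:
        if mask.data.shape != bold.data.shape[:3]:
            raise ValueError("mask grid does not match BOLD grid")
        coords = mask.coords()
        Y = bold.data[mask.data].T  # (time, voxels)
        label = mask.key()
    else:
        nx, ny, nz, _ = bold.data.shape
        coords = np.argwhere(np.ones((nx, ny, nz), dtype=bool))
        Y = bold.data.reshape(-1, bold.n_scans).T
        label = None
    pinv = np.linalg.pinv(X)
    beta_all = pinv @ Y
    betas = beta_all[: design.n_task]
    if units == "t":
        dof = X.shape[0] - X.shape[1]
        if dof < 1:
            raise ValueError(
                f"t units need more scans than regressors (dof = {dof})"
            )
        resid = Y - X @ beta_all
        noise_sd = np.sqrt((resid**2).sum(axis=0) / dof)
        noise_sd = np.where(noise_sd > 0.0, noise_sd, 1.0)
        leverage = np.sqrt(np.sum(pinv**2, axis=1))[: design.n_task]
        betas = betas / (leverage[:, None] * noise_sd[None, :])
    return BetaSeries(
        betas=betas,
        trial_index=np.arange(design.n_task),
        voxel_coords=coords,
        roi_label=label,
    )
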