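"""NIfTI-1 and sidecar I/O for masks, BOLD runs and beta series.

Volumes are written with a diagonal affine carrying the isotropic voxel
size; the affine is round-tripped but never used for resampling (all
coordinates in this package are 0-based voxel indices).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import BetaSeries, Bold4D
from .roi import RoiMask


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_mask(mask: RoiMask, path: str | Path) -> None:
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine(mask.voxel_size_mm)
    )
    nib.save(img, str(path))


def load_mask(
    path: str | Path, subfield: str = "CA1", hemisphere: str = "L"
) -> RoiMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    voxel = float(img.header.get_zooms()[0])
    return RoiMask(data > 0, subfield, hemisphere, voxel)


def save_bold(bold: Bold4D, path: str | Path) -> None:
    img = nib.Nifti1Image(bold.data, _affine(bold.voxel_size_mm))
    img.header.set_zooms((bold.voxel_size_mm,) * 3 + (bold.tr_s,))
    nib.save(img, str(path))


def load_bold(path: str | Path) -> Bold4D:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return Bold4D(
        np.asanyarray(img.dataobj, dtype=np.float64),
        tr_s=float(zooms[3]),
        voxel_size_mm=float(zooms[0]),
    )


def save_beta_series(betas: BetaSeries, path: str | Path) -> None:
    """4D NIfTI with the trial axis fourth, plus a tab-delimited sidecar.

    Voxels outside the series' coordinate set are written as zero; the
    sidecar (``<path>.voxels.tsv``) records the coordinate of every column
    and ``<path>.trials.tsv`` the trial alignment, so the exact trial ×
    voxel matrix round-trips.
    """
    path = Path(path)
    coords = betas.voxel_coords
    dims = tuple(coords.max(axis=0) + 1) if coords.size else (1, 1, 1)
    vol = np.zeros(dims + (betas.n_trials,))
    vol[coords[:, 0], coords[:, 1], coords[:, 2], :] = betas.betas.T
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
    pd.DataFrame(coords, columns=["x", "y", "z"]).to_csv(
        f"{path}.voxels.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"trial_index": betas.trial_index, "roi_label": betas.roi_label or ""}
    ).to_csv(f"{path}.trials.tsv", sep="\t", index=False)


def load_beta_series(path: str | Path) -> BetaSeries:
    path = Path(path)
    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
    coords = pd.read_csv(f"{path}.voxels.tsv", sep="\t").to_numpy(dtype=np.intp)
    trials = pd.read_csv(f"{path}.trials.tsv", sep="\t")
    label = trials["roi_label"].iloc[0] if len(trials) else ""
    return BetaSeries(
        betas=vol[coords[:, 0], coords[:, 1], coords[:, 2], :].T,
        trial_index=trials["trial_index"].to_numpy(),
        voxel_coords=coords,
        roi_label=str(label) if isinstance(label, str) and label else None,
    )
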