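"""Binary ROI masks and segmentation-reliability metrics.

Manual subfield delineation is typically validated by comparing two
segmentations of the same structure (two raters, or one rater at two time
points) with the Dice overlap coefficient, often restricted to a handful of
consecutive slices through the body of the structure.  This module provides
the mask container and those overlap metrics; it does not segment anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SUBFIELDS = ("CA1", "CA3", "DG", "SUB")
HEMISPHERES = ("L", "R")

#: Mean subfield sizes (voxels at 1.5 mm isotropic) used as generator targets.
DEFAULT_SUBFIELD_VOXELS = {"CA1": 267, "CA3": 248, "DG": 183, "SUB": 111}

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class RoiMask:
    """A binary 3D region-of-interest mask.

    Parameters
    ----------
    data
        3D array; nonzero entries mark ROI voxels.  Stored as ``bool``.
    subfield
        One of ``CA1, CA3, DG, SUB`` (free-form tags are tolerated for
        synthetic fixtures).
    hemisphere
        ``"L"`` or ``"R"``.
    voxel_size_mm
        Isotropic voxel edge length in millimetres.
    """

    data: np.ndarray
    subfield: str = "CA1"
    hemisphere: str = "L"
    voxel_size_mm: float = 1.5

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask data must be 3D, got shape {arr.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        self.data = arr.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def coords(self) -> np.ndarray:
        """(n, 3) array of 0-based voxel indices, lexicographically ordered."""
        return np.argwhere(self.data)

    def key(self) -> str:
        return f"{self.subfield}_{self.hemisphere}"


def roi_voxel_count(mask: RoiMask) -> int:
    """Number of nonzero voxels in the mask."""
    return mask.n_voxels


def dice(a: RoiMask, b: RoiMask) -> float:
    """Dice overlap between two masks.

    The volume of overlap divided by the mean of the two volumes,
    ``|a ∩ b| / ((|a| + |b|) / 2) = 2|a ∩ b| / (|a| + |b|)``.
    1 means identical masks, 0 means disjoint.
    """
    if a.data.shape != b.data.shape:
        raise ValueError(
            f"mask shapes differ: {a.data.shape} vs {b.data.shape}"
        )
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 or nb == 0:
        raise ValueError(
            f"dice undefined for empty mask (|a|={na}, |b|={nb})"
        )
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def dice_on_slices(
    a: RoiMask, b: RoiMask, axis: str = "y", start: int = 0, n_slices: int = 5
) -> float:
    """Dice computed on a block of consecutive slices only.

    Reliability protocols compare raters on a few consecutive slices through
    the body of the structure rather than on the full extent; ``n_slices``
    defaults to 5.  ``axis`` names the slice-stacking axis (``"y"`` for a
    coronal stack in x/y/z = left-right / anterior-posterior / inferior-
    superior conventions).
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    ax = _AXES[axis]
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    size = a.data.shape[ax]
    if a.data.shape != b.data.shape:
        raise ValueError(
            f"mask shapes differ: {a.data.shape} vs {b.data.shape}"
        )
    if start < 0 or start + n_slices > size:
        raise ValueError(
            f"slice range [{start}, {start + n_slices}) outside axis of length {size}"
        )
    sl: list[slice] = [slice(None)] * 3
    sl[ax] = slice(start, start + n_slices)
    sub_a = RoiMask(a.data[tuple(sl)], a.subfield, a.hemisphere, a.voxel_size_mm)
    sub_b = RoiMask(b.data[tuple(sl)], b.subfield, b.hemisphere, b.voxel_size_mm)
    if sub_a.n_voxels == 0 or sub_b.n_voxels == 0:
        raise ValueError(
            "slice range contains no mask voxels in one of the inputs"
        )
    return dice(sub_a, sub_b)
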