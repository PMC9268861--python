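"""Volume, mask and cohort-table I/O with geometric validation.

Volumes travel as NIfTI-1 with voxel spacing taken from the header (never
assumed), cohort tables as CSV with a fixed, documented column order.  All
readers reject inconsistent geometry instead of coercing it: a mask that does
not match its companion volume, a non-3-D image, or a non-positive voxel
spacing is an error, not a warning.

Conventions
-----------
Voxel indices are 0-based.  Slices are indexed along a declared ``slice_axis``
(default: the last axis).  All areas are computed in mm² from header spacing.
Missing clinical values are empty CSV fields, never sentinel numbers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume3D",
    "MTVolumePair",
    "NerveROI",
    "COHORT_COLUMNS",
    "GROUPS",
    "SEXES",
    "DEFAULT_SLICE_WINDOW",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "default_slice_range",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

#: Number of central slices analyzed by default.
DEFAULT_SLICE_WINDOW = 40

GROUPS = ("control", "CMT1A", "HNPP")
SEXES = ("M", "F")

#: Fixed cohort CSV column order.
COHORT_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "age",
    "bmi",
    "cmtes_l",
    "cmap",
    "mcv",
    "mtr",
    "csa",
    "circularity",
]


@dataclass
class Volume3D:
    """A scalar 3-D image grid with physical voxel spacing.

    Parameters
    ----------
    data
        Intensity array, one scalar per voxel.
    voxel_spacing
        Physical size of a voxel along each axis, in mm.
    slice_axis
        Axis treated as the slice (through-plane) direction.
    """

    data: np.ndarray
    voxel_spacing: tuple[float, float, float]
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3-D volume, got {self.data.ndim}-D data of shape "
                f"{self.data.shape}"
            )
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be positive on all axes, got {self.voxel_spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            # NaN is used internally to mark invalid MTR voxels; reject only at
            # construction from external input when everything should be finite.
            pass
        if not 0 <= self.slice_axis <= 2:
            raise ValueError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    @property
    def in_plane_axes(self) -> tuple[int, int]:
        return tuple(a for a in range(3) if a != self.slice_axis)  # type: ignore[return-value]

    @property
    def in_plane_voxel_area(self) -> float:
        """Area of one voxel face in the slice plane, mm²."""
        a, b = self.in_plane_axes
        return self.voxel_spacing[a] * self.voxel_spacing[b]

    @property
    def slice_spacing(self) -> float:
        return self.voxel_spacing[self.slice_axis]

    def slice(self, index: int) -> np.ndarray:
        """Return the 2-D in-plane array at ``index`` along the slice axis."""
        return np.take(self.data, index, axis=self.slice_axis)


@dataclass
class MTVolumePair:
    """Co-registered MT-weighted (``s_mt``) and reference (``s_ref``) volumes."""

    s_mt: Volume3D
    s_ref: Volume3D

    def __post_init__(self) -> None:
        if self.s_mt.shape != self.s_ref.shape:
            raise ValueError(
                f"MT and reference volumes differ in shape: {self.s_mt.shape} vs {self.s_ref.shape}"
            )
        if self.s_mt.voxel_spacing != self.s_ref.voxel_spacing:
            raise ValueError(
                "MT and reference volumes differ in voxel spacing: "
                f"{self.s_mt.voxel_spacing} vs {self.s_ref.voxel_spacing}"
            )
        if self.s_mt.slice_axis != self.s_ref.slice_axis:
            raise ValueError("MT and reference volumes declare different slice axes")
        if np.nanmin(self.s_mt.data) < 0 or np.nanmin(self.s_ref.data) < 0:
            raise ValueError("signal intensities must be non-negative")


@dataclass
class NerveROI:
    """Per-slice nerve voxel mask aligned to a volume grid.

    ``slice_range`` is the inclusive ``(first, last)`` index window of analyzed
    slices along ``slice_axis``; slices outside it are ignored by every
    downstream metric.
    """

    mask: np.ndarray
    slice_range: tuple[int, int]
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got {self.mask.ndim}-D")
        lo, hi = (int(self.slice_range[0]), int(self.slice_range[1]))
        n = self.mask.shape[self.slice_axis]
        if not (0 <= lo <= hi < n):
            raise ValueError(
                f"slice_range {self.slice_range} outside grid with {n} slices along axis {self.slice_axis}"
            )
        self.slice_range = (lo, hi)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def slice_mask(self, index: int) -> np.ndarray:
        return np.take(self.mask, index, axis=self.slice_axis)

    def slice_indices(self) -> range:
        lo, hi = self.slice_range
        return range(lo, hi + 1)

    def nonempty_slices(self) -> list[int]:
        return [i for i in self.slice_indices() if self.slice_mask(i).any()]

    def with_mask(self, mask: np.ndarray) -> "NerveROI":
        return replace(self, mask=mask)


# ---------------------------------------------------------------------------
# NIfTI volumes and masks
# ---------------------------------------------------------------------------

def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a :class:`Volume3D` as NIfTI-1 with spacing in the header."""
    affine = np.diag(list(vol.voxel_spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), affine)
    img.header.set_zooms(vol.voxel_spacing)
    nib.save(img, os.fspath(path))


def read_volume(path: str | os.PathLike, slice_axis: int = 2) -> Volume3D:
    """Read a 3-D NIfTI-1 volume; spacing comes from the header, never assumed."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D image, got a {data.ndim}-D image at {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing} in header of {path}")
    return Volume3D(np.asarray(data, dtype=np.float64), spacing, slice_axis=slice_axis)


def default_slice_range(n_slices: int, window: int = DEFAULT_SLICE_WINDOW) -> tuple[int, int]:
    """Inclusive index window of the ``window`` centermost slices, clipped to the grid."""
    if n_slices <= window:
        return (0, n_slices - 1)
    lo = (n_slices - window) // 2
    return (lo, lo + window - 1)


def write_mask(roi: NerveROI, path: str | os.PathLike, voxel_spacing: tuple[float, float, float]) -> None:
    vol = Volume3D(roi.mask.astype(np.uint8), voxel_spacing, slice_axis=roi.slice_axis)
    write_volume(vol, path)


def read_mask(
    path: str | os.PathLike,
    companion: Volume3D,
    slice_range: tuple[int, int] | None = None,
) -> NerveROI:
    """Read a nerve ROI mask and validate it against its companion volume.

    Nonzero voxels become True.  ``slice_range`` defaults to the
    :data:`DEFAULT_SLICE_WINDOW` centermost slices along the companion's slice
    axis, clipped to the grid.
    """
    vol = read_volume(path, slice_axis=companion.slice_axis)
    if vol.shape != companion.shape:
        raise ValueError(
            f"mask shape {vol.shape} does not match companion volume shape {companion.shape}"
        )
    mask = vol.data != 0
    if not mask.any():
        raise ValueError(f"empty ROI: mask at {path} has no nonzero voxels")
    if slice_range is None:
        slice_range = default_slice_range(companion.n_slices)
    return NerveROI(mask, slice_range, slice_axis=companion.slice_axis)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table in place and return it.

    Checks: required columns present, unique subject ids, group and sex drawn
    from the fixed vocabularies, CMTES_L within its 0-20 instrument range when
    present.  Missing clinical values (NaN) are legitimate — nerve conduction
    studies are not collected in controls.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    bad_group = set(table["group"].dropna()) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group tokens {sorted(bad_group)}; expected one of {GROUPS}")
    bad_sex = set(table["sex"].dropna()) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex tokens {sorted(bad_sex)}; expected one of {SEXES}")
    cmtes = table["cmtes_l"].dropna()
    if ((cmtes < 0) | (cmtes > 20)).any():
        bad = cmtes[(cmtes < 0) | (cmtes > 20)].tolist()
        raise ValueError(f"cmtes_l outside the 0-20 instrument range: {bad}")
    return table


def read_cohort(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a cohort CSV; empty fields become NaN (missing)."""
    table = pd.read_csv(path, dtype={"subject_id": str, "group": str, "sex": str})
    return validate_cohort(table)


def write_cohort(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a validated cohort table in the fixed column order."""
    validate_cohort(table)
    table.loc[:, COHORT_COLUMNS].to_csv(path, index=False)
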