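"""Image-analysis core: MTR mapping, fuzzy c-means ROI refinement, morphometrics.

Per-slice pipeline for one subject:

1. voxelwise MTR = (1 - S_MT / S_REF) x 100, with voxels whose reference
   signal falls at or below a noise floor marked invalid (NaN);
2. fuzzy c-means on the reference intensities of the ROI voxels (pooled across
   slices) removes background and fat partial-volume voxels so that only
   fascicular tissue remains — classes are ranked by center intensity and the
   brightest class is fascicle, since fat and background are dark under
   water-selective excitation;
3. per slice: 8-connected components, angulation-corrected cross-sectional
   area (voxel count x in-plane voxel area x cos theta), circularity of the
   dilated-and-filled region(s), and the mean MTR over refined voxels;
4. subject summary: mean of slice MTR means, mean of slice CSAs, median of
   slice circularities (the median resists outlier values from small ROIs).

The nerve's angulation theta relative to the slice normal is estimated from
the centroid track of the refined mask (central differences over neighboring
slices); the same per-slice theta is applied to every component of the slice.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours

from .io import MTVolumePair, NerveROI, Volume3D

logger = logging.getLogger(__name__)

__all__ = [
    "FCMParams",
    "SliceMetrics",
    "SubjectBiomarkers",
    "CenterlineGeometry",
    "fuzzy_cmeans_1d",
    "compute_mtr_map",
    "estimate_background_floor",
    "refine_roi",
    "slice_components",
    "estimate_centerline",
    "slice_csa",
    "slice_circularity",
    "traced_perimeter",
    "subject_biomarkers",
]


@dataclass
class FCMParams:
    """Fuzzy c-means settings for the ROI refinement step.

    ``n_classes`` intensity classes (nerve fascicle / intermediate tissue /
    fat+background by default), fuzziness exponent ``m``, and the minimum
    fascicle-class membership ``membership_cutoff`` a voxel needs to survive.
    """

    n_classes: int = 3
    m: float = 2.0
    tolerance: float = 1e-5
    max_iter: int = 300
    membership_cutoff: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzziness exponent m must be > 1")
        if not 0 < self.membership_cutoff <= 1:
            raise ValueError("membership_cutoff must lie in (0, 1]")


@dataclass
class SliceMetrics:
    """Per-slice imaging features."""

    slice_index: int
    n_components: int
    mtr_mean: float
    csa: float
    circularity: float
    theta_deg: float


@dataclass
class SubjectBiomarkers:
    """Subject-level biomarkers: MTR %, CSA mm², circularity (dimensionless)."""

    mtr: float
    csa: float
    circularity: float
    n_slices: int


@dataclass
class CenterlineGeometry:
    """Per-slice nerve centroid (in-plane mm) and tilt from the slice normal."""

    slice_indices: np.ndarray
    centroids_mm: np.ndarray  # (n, 2)
    theta_deg: np.ndarray  # (n,)

    def theta_at(self, slice_index: int) -> float:
        pos = np.flatnonzero(self.slice_indices == slice_index)
        if pos.size == 0:
            raise KeyError(f"slice {slice_index} not in centerline")
        return float(self.theta_deg[pos[0]])


# ---------------------------------------------------------------------------
# Fuzzy c-means (1-D)
# ---------------------------------------------------------------------------

def fuzzy_cmeans_1d(
    values: np.ndarray,
    n_classes: int,
    m: float = 2.0,
    tolerance: float = 1e-5,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means on scalar data.

    Returns ``(centers, memberships)`` with centers sorted ascending and
    memberships of shape ``(len(values), n_classes)`` in matching column
    order.  Initialization is deterministic (class-quantile centers), so the
    result is reproducible without randomness.  If the data hold fewer unique
    values than ``n_classes``, the class count falls back to that number
    (single-class data yield one class with full membership).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot cluster an empty value set")
    uniq = np.unique(x)
    k = int(min(n_classes, uniq.size))
    if k == 1:
        return np.array([uniq[0]]), np.ones((x.size, 1))
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    # Coincident quantile starts collapse classes; nudge them apart.
    for i in range(1, k):
        if centers[i] <= centers[i - 1]:
            centers[i] = centers[i - 1] + 1e-9 * max(1.0, abs(centers[i - 1]))
    expo = 2.0 / (m - 1.0)
    u = np.empty((x.size, k))
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        zero = d < 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-expo)
            u = inv / inv.sum(axis=1, keepdims=True)
        if zero.any():
            rows = zero.any(axis=1)
            u[rows] = 0.0
            u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        um = u**m
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tolerance:
            break
    order = np.argsort(centers)
    return centers[order], u[:, order]


# ---------------------------------------------------------------------------
# MTR map
# ---------------------------------------------------------------------------

def compute_mtr_map(pair: MTVolumePair, floor: float = 0.0) -> Volume3D:
    """Voxelwise MTR in percent: (1 - S_MT / S_REF) x 100.

    Voxels with ``S_REF <= floor`` are marked invalid (NaN) and excluded from
    every downstream ROI statistic.  Output spacing equals input spacing.
    The map is exactly invariant under joint rescaling of both volumes.
    """
    s_mt, s_ref = pair.s_mt.data, pair.s_ref.data
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = (1.0 - s_mt / s_ref) * 100.0
    mtr = np.where(s_ref > floor, mtr, np.nan)
    return Volume3D(mtr, pair.s_ref.voxel_spacing, slice_axis=pair.s_ref.slice_axis)


def estimate_background_floor(ref: Volume3D, factor: float = 5.0) -> float:
    """Noise-floor estimate: ``factor`` x the modal intensity of the image border.

    The outermost in-plane ring of each slice is taken as background (air);
    its histogram mode approximates the Rician background level.
    """
    mv = np.moveaxis(ref.data, ref.slice_axis, -1)
    border = np.concatenate(
        [mv[0, :, :].ravel(), mv[-1, :, :].ravel(), mv[:, 0, :].ravel(), mv[:, -1, :].ravel()]
    )
    counts, edges = np.histogram(border, bins=64)
    mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    return factor * float(mode)


# ---------------------------------------------------------------------------
# ROI refinement
# ---------------------------------------------------------------------------

def refine_roi(ref: Volume3D, roi: NerveROI, params: FCMParams | None = None) -> NerveROI:
    """Remove background / fat partial-volume voxels from a manual nerve ROI.

    Fuzzy c-means runs on the reference intensities of the ROI voxels pooled
    across analyzed slices; classes are ordered by center intensity and the
    brightest is fascicle.  A voxel survives iff its fascicle membership is
    both maximal across classes and at least ``membership_cutoff``.  The
    result is never larger than the input.  Slices that lose every voxel are
    dropped from downstream metrics with a warning; losing all slices is an
    error.
    """
    params = params or FCMParams()
    if ref.shape != roi.shape:
        raise ValueError(f"volume shape {ref.shape} does not match ROI shape {roi.shape}")
    lo, hi = roi.slice_range
    window = np.zeros_like(roi.mask)
    sl = [slice(None)] * 3
    sl[roi.slice_axis] = slice(lo, hi + 1)
    window[tuple(sl)] = True
    select = roi.mask & window
    if not select.any():
        raise ValueError("ROI is empty within its slice range")
    vals = ref.data[select]
    centers, u = fuzzy_cmeans_1d(
        vals, params.n_classes, m=params.m, tolerance=params.tolerance, max_iter=params.max_iter
    )
    fascicle = centers.size - 1  # brightest class
    keep = (np.argmax(u, axis=1) == fascicle) & (u[:, fascicle] >= params.membership_cutoff)
    refined = np.zeros_like(roi.mask)
    refined[select] = keep

    dropped = [
        i
        for i in roi.slice_indices()
        if roi.slice_mask(i).any() and not np.take(refined, i, axis=roi.slice_axis).any()
    ]
    if dropped:
        warnings.warn(
            f"fuzzy c-means refinement emptied slice(s) {dropped}; they are dropped "
            "from downstream metrics",
            stacklevel=2,
        )
    if not refined.any():
        raise ValueError("refinement removed every ROI voxel in every slice")
    return roi.with_mask(refined)


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

_EIGHT = ndimage.generate_binary_structure(2, 2)


def slice_components(
    roi: NerveROI, slice_index: int, min_voxels: int = 3
) -> list[np.ndarray]:
    """8-connected in-plane components of one slice, smallest specks discarded.

    Components below ``min_voxels`` voxels (default 3) are dropped with a log
    entry.  Returns a (possibly empty) list of 2-D boolean masks.
    """
    lo, hi = roi.slice_range
    if not lo <= slice_index <= hi:
        raise ValueError(f"slice {slice_index} outside analyzed range {roi.slice_range}")
    plane = roi.slice_mask(slice_index)
    labels, n = ndimage.label(plane, structure=_EIGHT)
    out: list[np.ndarray] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        size = int(comp.sum())
        if size < min_voxels:
            logger.info(
                "slice %d: discarding %d-voxel component (< %d voxels)",
                slice_index,
                size,
                min_voxels,
            )
            continue
        out.append(comp)
    return out


def estimate_centerline(roi: NerveROI, voxel_spacing: tuple[float, float, float]) -> CenterlineGeometry:
    """Per-slice centroid track and nerve tilt relative to the slice normal.

    The centroid of the slice mask (union of components) is computed in mm;
    the local tangent is the central difference of the 3-D centroid positions
    over a +-1 nonempty-slice window (one-sided at the ends); theta is the
    angle between that tangent and the slice normal.
    """
    nonempty = roi.nonempty_slices()
    if len(nonempty) < 3:
        raise ValueError(f"centerline needs >= 3 nonempty slices, got {len(nonempty)}")
    a, b = (ax for ax in range(3) if ax != roi.slice_axis)
    sp = voxel_spacing
    pts = []
    for i in nonempty:
        plane = roi.slice_mask(i)
        ia, ib = np.nonzero(plane)
        pts.append(
            [
                (ia.mean() + 0.5) * sp[a],
                (ib.mean() + 0.5) * sp[b],
                (i + 0.5) * sp[roi.slice_axis],
            ]
        )
    pts_arr = np.array(pts)
    n = len(nonempty)
    theta = np.empty(n)
    for j in range(n):
        j0, j1 = max(j - 1, 0), min(j + 1, n - 1)
        tangent = pts_arr[j1] - pts_arr[j0]
        norm = np.linalg.norm(tangent)
        theta[j] = math.degrees(math.acos(min(1.0, abs(tangent[2]) / norm))) if norm > 0 else 0.0
    return CenterlineGeometry(
        slice_indices=np.array(nonempty),
        centroids_mm=pts_arr[:, :2],
        theta_deg=theta,
    )


def slice_csa(
    components: list[np.ndarray],
    voxel_spacing: tuple[float, float, float],
    theta_deg: float = 0.0,
    slice_axis: int = 2,
) -> float:
    """Angulation-corrected cross-sectional area of one slice, mm².

    Total voxel count across components x in-plane voxel area x cos(theta):
    an oblique cut through a tube inflates the in-slice footprint by
    1/cos(theta), so multiplying by cos(theta) recovers the perpendicular
    cross-section.  Branches (multiple components) are summed.
    """
    if not 0 <= theta_deg < 90:
        raise ValueError(f"tilt angle must lie in [0, 90) degrees, got {theta_deg}")
    a, b = (ax for ax in range(3) if ax != slice_axis)
    area = voxel_spacing[a] * voxel_spacing[b]
    count = sum(int(c.sum()) for c in components)
    return count * area * math.cos(math.radians(theta_deg))


def traced_perimeter(mask: np.ndarray, smooth_window: int = 5) -> float:
    """Outer-boundary length of a 2-D mask from its traced sub-pixel contour.

    The 0.5-level marching-squares contour is smoothed with a circular moving
    average (default 5 points) to suppress the staircase overestimate of
    rasterized boundaries, then its polygon length is returned.  Verified
    against analytic circle/square/ellipse perimeters.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return 0.0
    contour = max(contours, key=len)[:-1]  # closed: last point repeats the first
    n = len(contour)
    if n >= smooth_window > 1:
        half = smooth_window // 2
        idx = (np.arange(n)[:, None] + np.arange(-half, half + 1)) % n
        contour = contour[idx].mean(axis=1)
    diffs = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.sqrt((diffs**2).sum(axis=1)).sum())


def slice_circularity(components: list[np.ndarray], dilate: bool = True) -> float:
    """Circularity 4*pi*A/P² of one slice, averaged over its dilated regions.

    The union of the components is dilated by one voxel (3x3 square
    structuring element) to close the gaps between fascicles, interior holes
    are flood-filled (4-connectivity), and each resulting 8-connected region
    contributes 4*pi*A/P² with A its filled pixel area and P its traced outer
    perimeter; the slice value is the unweighted mean over regions.  Fascicle
    fragments separated by sub-voxel gaps therefore merge back into the
    anatomical cross-section before measurement.
    """
    if not components:
        raise ValueError("slice_circularity needs at least one component")
    union = np.logical_or.reduce([c.astype(bool) for c in components])
    if dilate:
        union = ndimage.binary_dilation(union, structure=np.ones((3, 3), bool))
    union = ndimage.binary_fill_holes(union)
    labels, n = ndimage.label(union, structure=_EIGHT)
    values = []
    for lab in range(1, n + 1):
        region = labels == lab
        area = float(region.sum())
        perim = traced_perimeter(region)
        if perim > 0:
            values.append(4.0 * math.pi * area / perim**2)
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Subject-level pipeline
# ---------------------------------------------------------------------------

def subject_biomarkers(
    pair: MTVolumePair,
    roi: NerveROI,
    params: FCMParams | None = None,
    floor: float | None = None,
    min_slices: int = 3,
    min_component_voxels: int = 3,
) -> tuple[SubjectBiomarkers, list[SliceMetrics]]:
    """Run the full per-subject pipeline and aggregate across slices.

    Subject MTR is the unweighted mean of slice MTR means, CSA the unweighted
    mean of slice CSAs, circularity the median of slice circularities.  Slices
    emptied by refinement or containing no component of at least
    ``min_component_voxels`` voxels are excluded from all three aggregates; if
    fewer than ``min_slices`` slices survive, an error is raised.

    ``floor`` defaults to :func:`estimate_background_floor` of the reference
    volume (5x the modal border intensity).
    """
    params = params or FCMParams()
    if floor is None:
        floor = estimate_background_floor(pair.s_ref)
    mtr_vol = compute_mtr_map(pair, floor=floor)
    refined = refine_roi(pair.s_ref, roi, params)
    geom = estimate_centerline(refined, pair.s_ref.voxel_spacing)

    per_slice: list[SliceMetrics] = []
    for i in refined.nonempty_slices():
        comps = slice_components(refined, i, min_voxels=min_component_voxels)
        if not comps:
            logger.info("slice %d: no component survives the size filter; dropped", i)
            continue
        theta = geom.theta_at(i)
        csa = slice_csa(comps, pair.s_ref.voxel_spacing, theta, slice_axis=refined.slice_axis)
        circ = slice_circularity(comps)
        union = np.logical_or.reduce(comps)
        mtr_plane = mtr_vol.slice(i)
        vals = mtr_plane[union]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.info("slice %d: no valid MTR voxel; dropped", i)
            continue
        per_slice.append(
            SliceMetrics(
                slice_index=i,
                n_components=len(comps),
                mtr_mean=float(vals.mean()),
                csa=float(csa),
                circularity=float(circ),
                theta_deg=float(theta),
            )
        )
    if len(per_slice) < min_slices:
        raise ValueError(
            f"only {len(per_slice)} slice(s) survived the pipeline; need >= {min_slices}"
        )
    subject = SubjectBiomarkers(
        mtr=float(np.mean([s.mtr_mean for s in per_slice])),
        csa=float(np.mean([s.csa for s in per_slice])),
        circularity=float(np.median([s.circularity for s in per_slice])),
        n_slices=len(per_slice),
    )
    return subject, per_slice
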