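"""Synthetic inputs: digital thigh phantoms and subject-level cohorts.

Two generators stand in for patient data so every downstream stage is testable
without a download:

* :func:`make_nerve_phantom` renders a paired MT-weighted / reference volume
  containing a straight, tilted, fasciculated nerve tube embedded in a
  muscle / fat / bone background with Rician noise, together with the exact
  ground truth (mask, MTR, perpendicular cross-sectional area, circularity).
* :func:`make_cohort` draws subject-level biomarker + clinical tables with the
  group structure the cohort statistics assume: per-group biomarker normals, a
  linear sex + standardized-MTR model for leg disability (CMTES_L, clamped to
  its 0-20 instrument range), and a monotone noisy link from CSA to
  electrophysiology (CMAP, MCV) in patients.

The signal model inverts the MTR definition: the reference volume is the
tissue intensity map plus Rician noise, and the MT-weighted volume is the
tissue intensity times (1 - MTR/100) plus independent Rician noise, so at
infinite SNR the ratio recovers each tissue's configured MTR exactly.

Rendering is piecewise-constant: each voxel is assigned the tissue occupying
more than half of it (estimated by in-plane supersampling).  There is no
sub-voxel intensity blending — partial-volume contamination, which the fuzzy
c-means refinement must remove, is emulated instead by the perineural fat rim
plus generous or perturbed ROIs (:func:`perturb_roi`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import MTVolumePair, NerveROI, Volume3D, validate_cohort, COHORT_COLUMNS

import pandas as pd

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "make_nerve_phantom",
    "make_cohort",
    "attach_clinical",
    "perturb_roi",
    "dilate_roi",
]

# MTR of tissues the spec does not parameterize, in percent.  Fat and
# background carry almost no magnetization-transfer effect; bone (marrow)
# a modest one.  They only matter for voxels outside the nerve truth mask.
MTR_FAT = 5.0
MTR_BONE = 20.0
MTR_BACKGROUND = 0.0

_TISSUES = ("background", "muscle", "fat", "bone", "nerve", "interstitium")


@dataclass
class PhantomSpec:
    """Geometry, signal and noise parameters of the digital thigh phantom.

    Defaults follow the acquisition geometry the pipeline targets
    (reconstructed 0.75 x 0.75 x 3 mm³ voxels) at a reduced field of view, a
    3 mm nerve of 33% MTR in 25%-MTR muscle, and an SNR of 50 in muscle on the
    reference volume.  Intensities are arbitrary units; only ratios matter.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 20)
    voxel_spacing: tuple[float, float, float] = (0.75, 0.75, 3.0)
    nerve_radius: float = 3.0
    nerve_center: tuple[float, float] | None = None  # in-plane mm; default = FOV center
    tilt_deg: float = 0.0
    n_fascicles: int = 3
    fascicle_gap: float = 0.2  # mm, width of interfascicular septa
    fat_rim_mm: float = 1.0  # perineural fat ring thickness
    mtr_nerve: float = 33.0
    mtr_muscle: float = 25.0
    ref_intensities: dict[str, float] = field(
        default_factory=lambda: {
            "nerve": 1000.0,
            "muscle": 500.0,
            "fat": 40.0,  # near zero: water-selective excitation suppresses fat
            "bone": 150.0,
            "background": 5.0,
        }
    )
    interstitium_fraction: float = 0.6  # interstitial intensity as fraction of nerve
    snr: float = 50.0  # reference-volume SNR in muscle; np.inf = noise-free
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nerve_radius <= 0:
            raise ValueError("nerve_radius must be > 0")
        if not 0 <= self.tilt_deg < 90:
            raise ValueError(f"tilt_deg must be in [0, 90), got {self.tilt_deg}")
        if not (0 <= self.mtr_nerve <= 100 and 0 <= self.mtr_muscle <= 100):
            raise ValueError("tissue MTR values must lie in [0, 100]")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if any(v < 0 for v in self.ref_intensities.values()):
            raise ValueError("reference intensities must be >= 0")
        if self.n_fascicles < 1:
            raise ValueError("n_fascicles must be >= 1")
        if self.fascicle_gap < 0:
            raise ValueError("fascicle_gap must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a rendered phantom."""

    roi: NerveROI
    mtr_true: float
    csa_true: float  # mm², plane perpendicular to the nerve axis
    circularity_true: float
    tilt_deg: float

    def __post_init__(self) -> None:
        if self.csa_true <= 0:
            raise ValueError("csa_true must be > 0")
        if not 0 < self.circularity_true <= 1:
            raise ValueError("circularity_true must lie in (0, 1] for convex cross-sections")


def _rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: |clean + complex Gaussian| with per-channel SD sigma."""
    re = clean + rng.normal(0.0, sigma, clean.shape)
    im = rng.normal(0.0, sigma, clean.shape)
    return np.sqrt(re**2 + im**2)


def make_nerve_phantom(spec: PhantomSpec) -> tuple[MTVolumePair, PhantomTruth]:
    """Render the phantom and its ground truth.

    The nerve is a straight circular tube of radius ``nerve_radius`` whose axis
    is tilted by ``tilt_deg`` from the slice normal (in the x-z plane), passing
    through ``nerve_center`` at the mid-slice.  Inside the tube,
    ``n_fascicles`` sector-shaped fascicles are separated by radial septa of
    interstitial tissue ``fascicle_gap`` mm wide.  A fat rim surrounds the
    tube; a bone (femur) cylinder and a muscle cylinder fill out the thigh.

    Truth: voxels with > 50% nerve occupancy form the ROI mask;
    ``csa_true`` is the analytic perpendicular cross-section (pi r²);
    ``circularity_true`` is 4 pi A / P² of that circular cross-section (1.0).
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_spacing
    fov = (nx * dx, ny * dy, nz * dz)
    center = spec.nerve_center or (fov[0] / 2.0, fov[1] / 2.0)
    theta = math.radians(spec.tilt_deg)
    # Nerve axis: point c at mid-volume depth, direction d in the x-z plane.
    c = np.array([center[0], center[1], fov[2] / 2.0])
    d = np.array([math.sin(theta), 0.0, math.cos(theta)])

    # Field-of-view check per slice: the tilted tube's in-plane footprint is an
    # ellipse with semi-axes (r / cos theta, r) centered at the axis crossing.
    margin_x = spec.nerve_radius / math.cos(theta) + spec.fat_rim_mm
    margin_y = spec.nerve_radius + spec.fat_rim_mm
    z_slices = (np.arange(nz) + 0.5) * dz
    cx_slices = center[0] + math.tan(theta) * (z_slices - c[2])
    if (cx_slices - margin_x).min() < 0 or (cx_slices + margin_x).max() > fov[0]:
        raise ValueError(
            "nerve tube exits the field of view along axis x "
            f"(in-plane extent [{(cx_slices - margin_x).min():.1f}, "
            f"{(cx_slices + margin_x).max():.1f}] mm vs FOV {fov[0]:.1f} mm)"
        )
    if center[1] - margin_y < 0 or center[1] + margin_y > fov[1]:
        raise ValueError("nerve tube exits the field of view along axis y")

    # Voxel-center coordinates (mm).
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    X, Y, Z = np.meshgrid(xs, ys, z_slices, indexing="ij")

    def axial_dist2(px, py, pz):
        vx, vy, vz = px - c[0], py - c[1], pz - c[2]
        t = vx * d[0] + vy * d[1] + vz * d[2]
        return (vx - t * d[0]) ** 2 + (vy - t * d[1]) ** 2 + (vz - t * d[2]) ** 2

    # Nerve occupancy by 3x3 in-plane supersampling (piecewise-constant along z:
    # the tube varies slowly through 3 mm slices relative to in-plane structure).
    sub = np.array([-1.0 / 3.0, 0.0, 1.0 / 3.0])
    occ = np.zeros(spec.grid_shape)
    r2 = spec.nerve_radius**2
    for ox in sub * dx:
        for oy in sub * dy:
            occ += axial_dist2(X + ox, Y + oy, Z) < r2
    occ /= sub.size**2
    nerve_mask = occ > 0.5

    per_slice_counts = nerve_mask.sum(axis=(0, 1))
    if per_slice_counts.min() < 1:
        raise ValueError(
            "grid too coarse: at least one slice contains no nerve voxel "
            f"(minimum per-slice count {int(per_slice_counts.min())})"
        )

    # Fascicle vs interstitium inside the tube, by voxel-center geometry in the
    # plane perpendicular to the axis.
    vx, vy, vz = X - c[0], Y - c[1], Z - c[2]
    t = vx * d[0] + vy * d[1] + vz * d[2]
    wx, wy, wz = vx - t * d[0], vy - t * d[1], vz - t * d[2]
    # Orthonormal in-plane frame (e1 in the x-z plane, e2 = y).
    e1 = np.array([math.cos(theta), 0.0, -math.sin(theta)])
    u = wx * e1[0] + wy * e1[1] + wz * e1[2]
    v = wy  # e2 = (0, 1, 0)
    interstitial = np.zeros(spec.grid_shape, dtype=bool)
    if spec.n_fascicles > 1 and spec.fascicle_gap > 0:
        phi = np.arctan2(v, u)
        septa = 2.0 * np.pi * np.arange(spec.n_fascicles) / spec.n_fascicles - np.pi
        rad = np.sqrt(u**2 + v**2)
        for s_ang in septa:
            dphi = np.angle(np.exp(1j * (phi - s_ang)))
            # distance from the point to the radial septum half-line
            dist = np.where(np.abs(dphi) < np.pi / 2, rad * np.abs(np.sin(dphi)), rad)
            interstitial |= nerve_mask & (dist < spec.fascicle_gap / 2.0)

    # Tissue map.
    tissue = np.zeros(spec.grid_shape, dtype=np.uint8)  # background
    names = {name: i for i, name in enumerate(_TISSUES)}
    thigh_r = 0.46 * min(fov[0], fov[1])
    Rc = np.sqrt((X - fov[0] / 2.0) ** 2 + (Y - fov[1] / 2.0) ** 2)
    tissue[Rc < thigh_r] = names["fat"]  # subcutaneous fat shell
    tissue[Rc < thigh_r - 2.0] = names["muscle"]
    # Femur: parallel-to-z cylinder offset from the FOV center.
    bone_c = (fov[0] / 2.0 - 0.4 * thigh_r, fov[1] / 2.0 - 0.4 * thigh_r)
    bone = (X - bone_c[0]) ** 2 + (Y - bone_c[1]) ** 2 < 6.0**2
    tissue[bone] = names["bone"]
    # Perineural fat rim, then the nerve itself.
    rim = axial_dist2(X, Y, Z) < (spec.nerve_radius + spec.fat_rim_mm) ** 2
    tissue[rim] = names["fat"]
    tissue[nerve_mask] = names["nerve"]
    tissue[interstitial] = names["interstitium"]

    inten = spec.ref_intensities
    intensity_of = {
        names["background"]: inten["background"],
        names["muscle"]: inten["muscle"],
        names["fat"]: inten["fat"],
        names["bone"]: inten["bone"],
        names["nerve"]: inten["nerve"],
        names["interstitium"]: spec.interstitium_fraction * inten["nerve"],
    }
    mtr_of = {
        names["background"]: MTR_BACKGROUND,
        names["muscle"]: spec.mtr_muscle,
        names["fat"]: MTR_FAT,
        names["bone"]: MTR_BONE,
        names["nerve"]: spec.mtr_nerve,
        names["interstitium"]: spec.mtr_muscle,
    }
    lut_i = np.array([intensity_of[k] for k in range(len(_TISSUES))])
    lut_m = np.array([mtr_of[k] for k in range(len(_TISSUES))])
    s_ref_clean = lut_i[tissue]
    s_mt_clean = s_ref_clean * (1.0 - lut_m[tissue] / 100.0)

    if np.isinf(spec.snr):
        s_ref, s_mt = s_ref_clean, s_mt_clean
    else:
        rng = np.random.default_rng(spec.seed)
        sigma = inten["muscle"] / spec.snr
        s_ref = _rician(s_ref_clean, sigma, rng)
        s_mt = _rician(s_mt_clean, sigma, rng)

    pair = MTVolumePair(
        s_mt=Volume3D(s_mt, spec.voxel_spacing),
        s_ref=Volume3D(s_ref, spec.voxel_spacing),
    )
    truth = PhantomTruth(
        roi=NerveROI(nerve_mask | interstitial, (0, nz - 1)),
        mtr_true=spec.mtr_nerve,
        csa_true=math.pi * spec.nerve_radius**2,
        circularity_true=1.0,
        tilt_deg=spec.tilt_deg,
    )
    return pair, truth


# ---------------------------------------------------------------------------
# ROI perturbation (simulated second rater / second scan)
# ---------------------------------------------------------------------------

_CROSS = ndimage.generate_binary_structure(2, 1)


def dilate_roi(roi: NerveROI, n: int = 1) -> NerveROI:
    """In-plane dilation of every slice by ``n`` voxels (3x3 square element).

    Produces the kind of generous outline a human rater draws around the
    nerve, deliberately including perineural fat and muscle for the fuzzy
    c-means refinement to remove.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    m = np.moveaxis(roi.mask.copy(), roi.slice_axis, -1)
    for k in range(m.shape[-1]):
        plane = m[..., k]
        for _ in range(n):
            plane = ndimage.binary_dilation(plane, np.ones((3, 3), bool))
        m[..., k] = plane
    return roi.with_mask(np.moveaxis(m, -1, roi.slice_axis))


def perturb_roi(roi: NerveROI, boundary_noise: int, seed: int) -> NerveROI:
    """Randomly erode/dilate each slice's boundary by up to ``boundary_noise`` voxels.

    Emulates a second rater's (or second scan's) ROI.  Each analyzed slice
    independently draws an integer offset in [-boundary_noise, boundary_noise]
    and is eroded (negative) or dilated (positive) that many times with a
    4-connected structuring element.  A slice that was nonempty never becomes
    empty: erosion steps that would empty it are skipped.
    """
    if boundary_noise < 0:
        raise ValueError("boundary_noise must be >= 0")
    if not roi.mask.any():
        raise ValueError("cannot perturb an empty ROI")
    if boundary_noise == 0:
        return roi.with_mask(roi.mask.copy())
    rng = np.random.default_rng(seed)
    out = roi.mask.copy()
    mv = np.moveaxis(out, roi.slice_axis, -1)
    for k in roi.slice_indices():
        plane = mv[..., k]
        if not plane.any():
            continue
        steps = int(rng.integers(-boundary_noise, boundary_noise + 1))
        for _ in range(abs(steps)):
            if steps > 0:
                plane = ndimage.binary_dilation(plane, structure=_CROSS)
            else:
                eroded = ndimage.binary_erosion(plane, structure=_CROSS)
                if not eroded.any():
                    break
                plane = eroded
        mv[..., k] = plane
    return roi.with_mask(out)


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

_BIOMARKERS = ("mtr", "csa", "circularity")


@dataclass
class CohortSpec:
    """Parameters of the synthetic subject-level cohort.

    Defaults emulate the cohort structure the statistics battery assumes:
    n = (23, 11, 12) for (control, CMT1A, HNPP); CMT1A with lower MTR, roughly
    doubled CSA and lower circularity than controls; HNPP indistinguishable
    from controls; leg disability driven linearly by sex and standardized MTR
    in patients; electrophysiology (CMAP mV, MCV m/s) linked to CSA with a
    negative slope plus noise in patients only.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 23, "CMT1A": 11, "HNPP": 12}
    )
    group_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "control": {"mtr": 33.2, "csa": 30.0, "circularity": 0.88},
            "CMT1A": {"mtr": 29.5, "csa": 60.0, "circularity": 0.65},
            "HNPP": {"mtr": 33.0, "csa": 32.0, "circularity": 0.85},
        }
    )
    group_sds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "control": {"mtr": 3.6, "csa": 8.0, "circularity": 0.10},
            "CMT1A": {"mtr": 3.6, "csa": 17.0, "circularity": 0.15},
            "HNPP": {"mtr": 3.7, "csa": 9.0, "circularity": 0.12},
        }
    )
    #: CMTES_L = intercept + male_coef * [male] + mtr_coef * z(MTR) + N(0, resid_sd),
    #: clamped to the instrument range [0, 20]; zero for controls.
    disability_model: tuple[float, float, float, float] = (5.05, 4.19, -1.69, 2.6)
    #: metric -> (intercept, slope per mm² CSA, residual SD); patients only.
    electrophys_model: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "cmap": (12.0, -0.12, 1.5),  # mV
            "mcv": (60.0, -0.55, 3.0),  # m/s
        }
    )
    #: Count of patients per group whose NCS (cmap/mcv) fields are left missing.
    n_ncs_missing: dict[str, int] = field(default_factory=lambda: {"CMT1A": 1, "HNPP": 2})
    #: Planted-outlier MTR displacement, in units of the subject's group MTR SD.
    outlier_offset_sd: float | None = None
    male_fraction: dict[str, float] = field(
        default_factory=lambda: {"control": 0.391, "CMT1A": 0.455, "HNPP": 0.25}
    )
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "control": (42.6, 13.1),
            "CMT1A": (46.2, 12.7),
            "HNPP": (53.0, 8.7),
        }
    )
    bmi_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "control": (26.8, 5.5),
            "CMT1A": (25.3, 5.7),
            "HNPP": (28.6, 5.2),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 0")
        for g, sds in self.group_sds.items():
            if any(s < 0 for s in sds.values()):
                raise ValueError(f"SDs must be >= 0 (group {g})")
        if self.disability_model[3] < 0:
            raise ValueError("disability residual SD must be >= 0")


def attach_clinical(
    table: pd.DataFrame,
    spec: CohortSpec,
    rng: np.random.Generator,
    recompute_disability: bool = True,
) -> pd.DataFrame:
    """Derive the clinical columns from the biomarker columns, in place.

    CMTES_L is linear in sex and standardized MTR (z-scored over patients)
    plus residual noise, clamped to [0, 20] and zero for controls; CMAP/MCV
    follow the configured monotone noisy link to CSA in patients only, with
    the configured counts left missing (partial NCS availability).
    ``recompute_disability=False`` preserves an existing CMTES_L column (used
    when an outlier plant has already decoupled it from MTR).
    """
    patients = table["group"] != "control"

    icpt, b_male, b_zmtr, resid_sd = spec.disability_model
    if recompute_disability:
        table["cmtes_l"] = 0.0
    if recompute_disability and patients.any():
        mtr_p = table.loc[patients, "mtr"]
        sd = mtr_p.std(ddof=1)
        z = (mtr_p - mtr_p.mean()) / (sd if sd > 0 else 1.0)
        male = (table.loc[patients, "sex"] == "M").astype(float)
        noise = rng.normal(0.0, resid_sd, int(patients.sum())) if resid_sd > 0 else 0.0
        cmtes = icpt + b_male * male + b_zmtr * z + noise
        table.loc[patients, "cmtes_l"] = np.clip(cmtes, 0.0, 20.0)

    # Electrophysiology through the monotone link to CSA, patients only.
    for metric, (b0, b1, sd) in spec.electrophys_model.items():
        table[metric] = np.nan
        if patients.any():
            noise = rng.normal(0.0, sd, int(patients.sum())) if sd > 0 else 0.0
            vals = b0 + b1 * table.loc[patients, "csa"] + noise
            table.loc[patients, metric] = np.maximum(vals, 0.1)

    # Partial NCS availability, as in real cohorts.
    for group, n_missing in spec.n_ncs_missing.items():
        idx = table.index[table["group"] == group]
        if n_missing > 0 and len(idx) > 0:
            drop = rng.choice(idx, size=min(n_missing, len(idx)), replace=False)
            table.loc[drop, ["cmap", "mcv"]] = np.nan
    return table


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one synthetic cohort table (one row per subject).

    Reproducible under a fixed seed.  If ``outlier_offset_sd`` is set, exactly
    one patient's MTR is displaced by that many group-SDs (downward); the
    chosen subject id is recorded in ``table.attrs["outlier_id"]``.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for group in ("control", "CMT1A", "HNPP"):
        n = spec.n_per_group.get(group, 0)
        for i in range(n):
            sid = f"{group}-{i + 1:02d}"
            sex = "M" if rng.random() < spec.male_fraction[group] else "F"
            age = float(np.clip(rng.normal(*spec.age_mean_sd[group]), 18.0, 80.0))
            bmi = float(np.clip(rng.normal(*spec.bmi_mean_sd[group]), 15.0, 45.0))
            row = {"subject_id": sid, "group": group, "sex": sex, "age": age, "bmi": bmi}
            for bm in _BIOMARKERS:
                val = rng.normal(spec.group_means[group][bm], spec.group_sds[group][bm])
                if bm == "circularity":
                    val = float(np.clip(val, 1e-6, 1.0))
                elif bm == "csa":
                    val = max(val, 1.0)
                row[bm] = float(val)
            rows.append(row)
    table = pd.DataFrame(rows)

    patients = table["group"] != "control"
    # Disability first (it depends on undisplaced MTR), electrophysiology and
    # NCS missingness after the outlier plant so draw order stays stable.
    icpt, b_male, b_zmtr, resid_sd = spec.disability_model
    table["cmtes_l"] = 0.0
    if patients.any():
        mtr_p = table.loc[patients, "mtr"]
        sd = mtr_p.std(ddof=1)
        z = (mtr_p - mtr_p.mean()) / (sd if sd > 0 else 1.0)
        male = (table.loc[patients, "sex"] == "M").astype(float)
        noise = rng.normal(0.0, resid_sd, int(patients.sum())) if resid_sd > 0 else 0.0
        cmtes = icpt + b_male * male + b_zmtr * z + noise
        table.loc[patients, "cmtes_l"] = np.clip(cmtes, 0.0, 20.0)

    # Planted outlier: after disability generation, rebuild one patient as a
    # canonical (group-average MTR, noise-free disability) subject and then
    # displace their MTR by the stated offset.  This is a controlled plant —
    # the point sits exactly offset x SD off the MTR-CMTES trendline instead
    # of offset plus the subject's own random deviations, so detection tests
    # measure the rule, not the plant's luck.
    outlier_id = None
    if spec.outlier_offset_sd is not None and patients.any():
        idx = table.index[rng.choice(np.flatnonzero(patients.to_numpy()))]
        g = table.loc[idx, "group"]
        male_i = float(table.loc[idx, "sex"] == "M")
        table.loc[idx, "mtr"] = table.loc[patients, "mtr"].mean()
        table.loc[idx, "cmtes_l"] = float(np.clip(icpt + b_male * male_i, 0.0, 20.0))
        table.loc[idx, "mtr"] -= spec.outlier_offset_sd * spec.group_sds[g]["mtr"]
        outlier_id = table.loc[idx, "subject_id"]

    attach_clinical(table, spec, rng, recompute_disability=False)
    table = table.loc[:, COHORT_COLUMNS]
    table.attrs["outlier_id"] = outlier_id
    return validate_cohort(table)
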