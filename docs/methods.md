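# Methods

## Signal model and MTR mapping

The MT-weighted and reference volumes are assumed co-registered (they are
acquired interleaved in the protocols this pipeline targets; registration is
out of scope). MTR is computed voxelwise as `(1 − S_MT/S_REF) × 100` and is
exactly invariant under joint rescaling of both volumes. Voxels whose
reference signal falls at or below a noise floor are marked invalid (NaN) and
excluded from every ROI statistic; the default floor is 5× the modal
intensity of the image border (taken as air/background), configurable. The
phantom inverts the same model: reference = tissue intensity map + Rician
noise, MT-weighted = intensity × (1 − MTR_tissue/100) + independent Rician
noise, so at infinite SNR the round trip is exact to machine precision.

## ROI refinement by fuzzy c-means

Manual nerve outlines include perineural fat and, at the boundary, partial
volume with fat/muscle. Reference intensities of ROI voxels (pooled across
analyzed slices) are clustered with 1-D fuzzy c-means (default 3 classes,
fuzziness m = 2, tolerance 1e-5); classes are ranked by center intensity and
the brightest is fascicle, because fat and background are dark under
water-selective excitation. A voxel survives iff its fascicle membership is
maximal and ≥ 0.5. Initialization is deterministic (class quantiles), so the
step is reproducible without randomness; if the ROI holds fewer unique
intensities than classes, the class count falls back to that number (a
constant ROI is kept whole). Slices emptied by refinement are dropped with a
warning; losing every slice is an error. The refined mask is never larger
than the input.

## Morphometry

**Angulation.** The oblique-slice correction needs a per-slice tilt θ between
the nerve and the slice normal; how to measure it is an open design point, so
the package estimates it from the centroid track of the refined mask: per
nonempty slice the in-plane centroid (mm) is stacked with the slice position,
and the local tangent is the central difference over the ±1 nonempty-slice
window (one-sided at the ends). A single centerline serves all components of
a slice; per-branch centerlines after the bifurcation are a non-goal.

**CSA** = voxel count × in-plane voxel area × cos θ, summed over the slice's
8-connected components (both branches of a bifurcated nerve count).
Components below 3 voxels (configurable) are discarded with a log entry.

**Circularity.** The slice mask is dilated by one voxel (3×3 square element)
to close inter-fascicle gaps, interior holes are flood-filled
(4-connectivity), and each resulting region contributes `4πA/P²`; the slice
value is the unweighted mean over regions. P is the length of the
marching-squares 0.5-level contour smoothed with a 5-point circular moving
average. The smoothing matters: the raw rasterized contour overestimates
perimeter by ~5% (staircase effect) and weighted pixel-count estimators are
biased the other way; the smoothed-contour estimator was validated against
analytic circle, square and ellipse (elliptic-integral) perimeters before
freezing. Values slightly above 1 are possible for near-circular rasterized
shapes and are reported as computed.

**Aggregation.** Subject MTR = unweighted mean of slice MTR means (weighting
by voxel count is a documented alternative, not used); subject CSA = mean of
slice CSAs; subject circularity = median of slice circularities, which
resists outlier values from small ROIs. At least 3 slices (configurable) must
survive. By default the 40 centermost slices of the grid are analyzed,
clipped to the grid.

## Cohort statistics

All tests are two-sided at α = 0.05 and raw p-values are reported — no
multiple-comparison correction, matching the exploratory design this package
reproduces. Group comparisons: Kruskal–Wallis omnibus followed by pairwise
Wilcoxon rank-sum tests, exact when both groups have ≤ 25 untied
observations, otherwise normal approximation with continuity correction.

**Outlier rule.** Clinical correlations are Spearman. Before correlating, an
OLS trendline of y on x is fit over complete pairs and points lying more than
2.5 standard deviations from it are excluded (both versions are reported).
"Standard deviations from the trendline" is measured by the externally
studentized (deletion) residual: each point is judged against the residual
scale of the fit that excludes it. The naive alternative — residual over the
pooled residual SD — lets a gross outlier inflate its own yardstick (a 4σ
point raises the effective threshold to ≈3.5σ and is then missed a third of
the time), which defeats the rule's purpose. Exclusions propagate to other
correlations by an explicit caller-supplied id list, never by re-derivation.

**Demographic screen** (controls only): rank-based partial correlations of
each biomarker with age (conditioning on BMI and sex) and BMI (conditioning
on age and sex) — the conditioning set is a documented choice, as is the
rank-based flavor — plus rank-sum tests for sex.

**Disability regression.** CMTES_L on standardized continuous predictors and
a 0/1 male indicator (female reference): full fit, type-II ANOVA, terms with
p ≥ 0.05 dropped, refit. A numerically saturated (noise-free) fit makes the
F statistics 0/0 noise, so in that case terms are pruned by their
sum-of-squares contribution instead — this keeps the zero-residual generative
round trip deterministic. Single-sex cohorts drop the sex term with a
warning; an ill-conditioned design raises a condition-number warning.

**Reliability.** ICC is two-way random effects, absolute agreement, single
measurement (computed via pingouin; an independent mean-squares oracle guards
it in the tests), with one-way and consistency variants selectable. CV is the
root-mean-square over subjects of per-subject (SD/mean)×100; a pooled
within-subject-SD variant is available since the field does not standardize
this. Test–retest agreement uses relative differences, (scan2 − scan1)/pair
mean × 100; bias is their mean and the 95% limits of agreement are
bias ± 1.96 SD. Subjects with non-positive means are excluded with a warning;
identical repeats give ICC 1, CV 0 and an undefined (NaN) paired-t p.

## The synthetic world

**Phantom.** A straight circular tube (default radius 3 mm, MTR 33%) tilted
in the x–z plane, passing through a configurable in-plane point, inside a
thigh-like background: muscle cylinder (MTR 25%), subcutaneous fat shell and
perineural fat rim (near-zero intensity, emulating water-selective fat
suppression), femur cylinder. Default grid 64×64×20 at 0.75×0.75×3 mm³ —
the reconstructed resolution of the targeted acquisition. Noise is Rician
(magnitude MRI), parameterized by the reference-volume SNR in muscle
(default 50; the source protocol reports no SNR, so this is a free,
documented parameter), sampled as the magnitude of a complex Gaussian around
the clean signal and verified against the scipy Rice distribution's moments.

Rendering is piecewise-constant: each voxel takes the tissue occupying >50%
of it, estimated by 3×3 in-plane supersampling. There is no sub-voxel
intensity blending — that choice makes the noise-free MTR round trip exact,
while the partial-volume contamination the FCM step must remove is emulated
by the fat rim plus generous/perturbed ROIs. Discretization of the >50% rule
leaves an alignment-dependent area error of up to ~10% at radius 3 mm /
0.75 mm voxels (mean ≈ −2% over random alignments); grid-symmetric center
placements are degenerate alignments whose bias varies systematically with
radius, so cohort-level phantoms jitter the center sub-voxel, as real anatomy
does.

Fascicles are sectors separated by thin radial septa of interstitial tissue
(default 0.2 mm, intensity 0.6× fascicle, MTR of muscle). Septa occasionally
claim voxels, fragmenting the refined mask so the dilation+fill step of
circularity is genuinely exercised, while keeping fascicular area within a
few percent of the tube area. Packed circular sub-tubes were rejected: three
circles cover at most ~65% of a disk, which would make the measured
(fascicular) CSA incommensurable with the analytic tube truth.

Truth values are analytic: mask = >50%-occupancy voxels, CSA = πr² in the
plane perpendicular to the axis, circularity = 1 (circular envelope),
MTR = the configured nerve MTR.

**Cohort.** Defaults state a world shaped like the clinical cohorts this
pipeline serves: n = (23, 11, 12) for control/CMT1A/HNPP; control MTR
33.2 ± 3.6%, CSA 30 ± 8 mm², circularity 0.88 ± 0.10; CMT1A MTR lower
(29.5), CSA doubled (60 ± 17), circularity 0.65 ± 0.15; HNPP ≈ control.
Disability: CMTES_L = 5.05 + 4.19·[male] − 1.69·z(MTR) + N(0, 2.6) for
patients, clamped to the instrument range [0, 20], zero for controls; the
residual SD 2.6 is what an adjusted R² of ~0.68 implies at the observed
CMTES_L spread. Electrophysiology is linear-with-noise in CSA with negative
slope (CMAP ≈ 12 − 0.12·CSA mV, MCV ≈ 60 − 0.55·CSA m/s), patients only,
with a few subjects' nerve-conduction fields left missing as in real tables.
A planted outlier, when requested, rebuilds one random patient as canonical
(group-mean MTR, noise-free disability) and then displaces their MTR by the
stated number of group SDs — a controlled plant that sits exactly that far
off the MTR–disability trendline, so detection tests measure the rule rather
than the plant's luck.

**Rater/scan simulation.** A second rater is the same volume re-read with
each slice boundary randomly eroded or dilated by up to one voxel; a second
scan is the same nerve re-rendered with fresh noise and a fresh ROI
perturbation. What a green reliability test establishes is therefore that
the pipeline is stable under boundary and noise perturbations — not that
human raters would agree: the generator has no inter-rater ambiguity about
where the nerve is, no motion, no repositioning of the imaging volume, and
its ROIs are systematically centered on the true nerve. Real-world CVs and
limits of agreement are wider than the synthetic ones.

## Pipeline

`run_pipeline` executes requested stages into a run directory with per-stage
outputs (NIfTI, CSV, JSON), a JSON-lines event log (dropped slices, flagged
outliers, pruned terms) and the config plus its SHA-256. Every stochastic
stage seeds from CRC32(stage name : global seed), so identical configs
reproduce outputs bit-identically. The image route regenerates the clinical
columns from the *measured* biomarkers after extraction, so the
biomarker–clinical coupling the statistics probe actually holds in the data
they see.

## Known limitations

- No pulse-sequence simulation, B0/B1 inhomogeneity, motion, or
  fat-suppression failure; noise is spatially white.
- The nerve is straight; curvature within the volume (and hence
  slice-varying true angulation) is not modeled, though the estimator
  supports it.
- Circularity of a tilted nerve is measured on the oblique (elliptical)
  cross-section; no de-obliquing is attempted, mirroring the method this
  package reproduces.
- FCM assumes the fascicle class is the brightest; acquisitions where nerve
  is not the brightest ROI tissue would need a different class-assignment
  rule.
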