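"""Extract the three imaging biomarkers from a noisy phantom.

A generous rater-style ROI (ground truth dilated by one voxel, so it includes
perineural fat and muscle) is refined by fuzzy c-means down to fascicular
tissue, then MTR, angulation-corrected CSA and circularity are measured per
slice and aggregated.
"""

from nervemetry import PhantomSpec, make_nerve_phantom, subject_biomarkers
from nervemetry.phantom import dilate_roi

spec = PhantomSpec(nerve_radius=3.0, mtr_nerve=33.0, tilt_deg=20.0, snr=50.0, seed=1)
pair, truth = make_nerve_phantom(spec)
manual_roi = dilate_roi(truth.roi)  # what a human rater would outline

subject, slices = subject_biomarkers(pair, manual_roi)

print(f"{'metric':<14}{'estimate':>10}{'truth':>10}")
print(f"{'MTR [%]':<14}{subject.mtr:>10.2f}{truth.mtr_true:>10.2f}")
print(f"{'CSA [mm^2]':<14}{subject.csa:>10.2f}{truth.csa_true:>10.2f}")
print(f"{'circularity':<14}{subject.circularity:>10.2f}{truth.circularity_true:>10.2f}")
print(f"\naggregated over {subject.n_slices} slices; per-slice tilt estimates "
      f"{min(s.theta_deg for s in slices):.1f}-{max(s.theta_deg for s in slices):.1f} deg "
      f"(true {truth.tilt_deg:.0f} deg)")
print("MTR within a fraction of a percentage point and CSA within a few percent "
      "of truth is typical at SNR 50.")
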