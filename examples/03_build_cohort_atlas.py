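"""Build the four atlas volumes from a small phantom cohort.

Generates an 8-subject cohort (multi-center intensity shifts, partial
coverage, small rigid misalignments), runs the full per-subject pipeline
with the oracle registration backend, accumulates the atlas and prints
the headline values at the left internal carotid landmark: occurrence
probability, mean radius and radius standard deviation — the per-voxel
population statistics a clinician would read off the atlas.
"""

import numpy as np

from vascatlas import PhantomSpec, run_phantom_cohort
from vascatlas.phantom import landmark_roi, landmark_voxel

spec = PhantomSpec(grid_shape=(64, 64, 64), spacing_mm=(0.75, 0.75, 0.75),
                   deformation_amplitude_mm=0.0, seed=3)
bundle, qc, subjects, truth, _ = run_phantom_cohort(spec, 8)
print(qc[["subject", "status"]].to_string(index=False))

lv = landmark_voxel(spec, "ICA_L_sup", 0.0)
roi = landmark_roi(spec, "ICA_L_sup", t=0.0).data
mr = bundle.mean_radius.data[roi]
print(f"\nICA_L landmark (voxel {lv}):")
print(f"  occurrence probability: {bundle.probability.data[lv]:.0f}%")
print(f"  mean radius (core ROI): {mr[mr > 0].mean():.2f} mm "
      f"(population truth {truth.segment_draws['ICA_L_sup'][:, 0].mean():.2f} mm)")
print(f"  radius std  (core ROI): "
      f"{bundle.std_radius.data[roi][mr > 0].mean():.2f} mm "
      f"(population sigma 0.2 mm)")
print(f"  covering subjects: {int(bundle.n_cov.data[lv])}")

out = "scratch_atlas"
paths = bundle.save(out)
print(f"\nwrote canonical atlas files to {out}/: "
      + ", ".join(sorted(p.split('/')[-1] for p in paths.values())))
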