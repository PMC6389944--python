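"""Bundle volume and median microstructure sampling.

Simulates a cingulum-like bundle and an ICVF map whose bundle interior
is lowered in proportion to the subject's developmental-delay penetrance
score, then measures the two tractometry quantities: traversed-voxel
volume and the bundle-median ICVF.
"""

import numpy as np

from cnvtract import (SimulationDesign, build_cohort, bundle_volume,
                      sample_bundle_median, simulate_bundle)
from cnvtract.simulate import bundle_mask, make_grid, simulate_scalar_map

design = SimulationDesign(seed=0, n_streamlines=50)
cohort = build_cohort(design)
subject = cohort[cohort["cnv_label"] == "22q11.2 deletion"].iloc[0]

bundle = simulate_bundle("cingulum_dorsal_L", subject, design,
                         subject_id=str(subject.name))
pts = np.vstack([s.points for s in bundle])
affine, shape = make_grid(pts, design.voxel_size)
mask = bundle_mask(bundle, affine, shape)
icvf = simulate_scalar_map("ICVF", subject, mask, affine, design,
                           subject_id=str(subject.name))

vol = bundle_volume(bundle, affine, shape)
med = sample_bundle_median(bundle, icvf)
expected = design.metric_base["ICVF"] \
    + design.microstructure_effects["ICVF"] * subject["P_DD"]
print(f"subject:             {subject.name} ({subject['cnv_label']}, "
      f"P_DD = {subject['P_DD']:.0f} %)")
print(f"bundle volume:       {vol:.0f} mm^3 "
      f"({int(vol / icvf.voxel_volume)} voxels x {icvf.voxel_volume:.0f} mm^3)")
print(f"bundle-median ICVF:  {med:.3f} (design expectation {expected:.3f})")
print()
print("The median sits at base + slope x penetrance: a 88 % DD-penetrance")
print("carrier loses 0.176 of intracellular volume fraction inside the")
print("bundle relative to a control, the dose effect the GLM later tests.")
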