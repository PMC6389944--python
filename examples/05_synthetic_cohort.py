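"""The synthetic study: cohort structure and dose-response geometry.

Builds the default 36-subject cohort (21 carriers, 15 controls) and
shows the penetrance-linked cingulum curvature: arc amplitude grows by
0.05 mm per percent of developmental-delay penetrance.
"""

import numpy as np

from cnvtract import SimulationDesign, build_cohort, simulate_bundle

design = SimulationDesign(seed=0, amplitude_subject_sd=0.0)
cohort = build_cohort(design)
print(cohort["cnv_label"].value_counts().to_string())
print(f"\ncarriers: {int(cohort.carrier.sum())}, "
      f"controls: {int((1 - cohort.carrier).sum())}")
print(f"age {cohort.age.mean():.1f} +/- {cohort.age.std():.1f} years, "
      f"{(cohort.gender == 'M').sum()} M / {(cohort.gender == 'F').sum()} F")

t = np.linspace(0, 1, design.n_points)
basis = np.sin(np.pi * t)
print("\nfitted cingulum arc amplitude by penetrance:")
picks = [cohort["P_DD"].idxmax(),                       # highest-penetrance carrier
         cohort[cohort.carrier == 1]["P_DD"].idxmin(),  # mildest carrier
         cohort[cohort.carrier == 0].index[0]]          # a control
for sid in picks:
    row = cohort.loc[sid]
    sls = simulate_bundle("cingulum_dorsal_L", row, design, subject_id=sid)
    amps = [(s.points[:, 2] - 25.0) @ basis / (basis @ basis) for s in sls]
    print(f"  {sid} ({row['cnv_label']:20s} P_DD {row['P_DD']:5.1f} %): "
          f"{np.mean(amps):5.2f} mm")
print()
print("Amplitude = 15 mm + 0.05 x P_DD: an 88 %-penetrance carrier bows")
print("4.4 mm higher than a control — the geometric effect the shape")
print("descriptors must detect against jitter and clustering noise.")
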