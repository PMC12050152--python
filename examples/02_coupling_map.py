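"""Regional and global morphology-function coupling for one subject.

Generates a synthetic subject whose functional covariance tracks the
morphological similarity with a planted per-region fidelity gradient,
builds both networks, and prints the coupling map: regions with higher
planted fidelity should show higher estimated coupling.
"""

import numpy as np

import mfcoupling as mfc

cfg = mfc.CohortConfig(
    n_regions=14,
    n_subjects_per_group=1,
    n_voxels_per_region=2000,
    timeseries_length=300,
    group_effect=0.0,
    seed=1,
)
cohort = mfc.generate_cohort(cfg)
subject = cohort.subjects[0]

msn = mfc.build_msn(subject.voxels)
fcn = mfc.build_fcn(subject.timeseries)
cmap = mfc.regional_coupling(msn, fcn)

print("region  network  planted fidelity  estimated coupling")
for i, region in enumerate(cmap.region_labels):
    net = cohort.partition.network_of(region)
    print(
        f"{region:>6}  {net:<7}  {cohort.gamma[i]:>14.2f}  {cmap.values[i]:>17.3f}"
    )

g = mfc.global_coupling(msn, fcn)
print(f"\nglobal coupling (all unique pairs): {g:.3f}")
print(f"mean of regional map:               {np.mean(cmap.values):.3f}")
print("\nnetwork means (mean coupling over member regions):")
for net, val in mfc.network_coupling(cmap, cohort.partition).items():
    print(f"  {net}: {val:+.3f}")
# Estimated coupling rises with the planted fidelity; the global value
# summarises morphology-function correspondence across the whole matrix.
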