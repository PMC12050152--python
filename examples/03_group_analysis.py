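"""Case-control comparison with site harmonization and FDR control.

Simulates a two-site cohort in which the case group's coupling fidelity is
raised inside three designated networks, runs the full inferential battery
(ComBat on regional coupling, covariate residualization, Mann-Whitney tests
per region / network / globally, BH-FDR within each family, symptom partial
correlations for surviving networks), and prints the network table.
"""

import mfcoupling as mfc
from mfcoupling.study import coupling_study

cfg = mfc.CohortConfig(
    n_regions=48,
    n_subjects_per_group=60,
    timeseries_length=100,
    group_effect=0.12,  # planted increase, cases only, in VIS/SMN/DAN
    seed=21,
)
coupling, cohort_df, partition = coupling_study(cfg, seed=21, morphology="planted")
result = mfc.group_pipeline(
    coupling, mfc.CohortTable(cohort_df), partition
)

print("network-level case-control comparison (Mann-Whitney, BH-FDR):")
print(result.network.to_frame().round(4).to_string(index=False))
print(f"\nglobal coupling: z = {result.global_z:.2f}, p = {result.global_p:.4f}")
if len(result.symptom):
    print("\nsymptom partial correlations in significant networks:")
    print(result.symptom.round(4).to_string(index=False))
# The three planted networks should surface with q < 0.05 and positive
# direction (cases > controls); the remaining four should not.
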