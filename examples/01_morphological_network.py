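"""Build a morphological similarity network and check it against theory.

Five regions get Gaussian gray-matter value distributions with known
locations.  The KDE/KLS pipeline estimates each pairwise similarity from
5000 voxel values per region; for Gaussians the true similarity has a
closed form, so we can print estimate vs truth side by side.
"""

import numpy as np

import mfcoupling as mfc

rng = np.random.default_rng(0)
mu = np.array([0.0, 0.5, 1.1, 1.8, 3.0])  # region means (arbitrary GM units)
sigma = np.ones(5)

subject = mfc.VoxelSampleSet(
    subject_id="demo",
    samples=[rng.normal(m, s, 5000) for m, s in zip(mu, sigma)],
)
msn = mfc.build_msn(subject)

print("pair   estimated KLS   closed-form KLS")
for i in range(5):
    for j in range(i + 1, 5):
        oracle = mfc.planted_kls_oracle(mu[i], sigma[i], mu[j], sigma[j])
        print(f"{i + 1}-{j + 1}      {msn.values[i, j]:.4f}          {oracle:.4f}")

# Similar regional distributions give KLS near 1, separated ones near 0;
# the estimate should track the closed form within a few hundredths.
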