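# Methods

## The quantity being computed

`mfcoupling` quantifies **morphology-function coupling (MFC)**: the
region-wise correspondence between a subject's *morphological similarity
network* (MSN), built from the distributions of gray-matter (GM) values
inside each cortical region, and the subject's *functional connectivity
network* (FCN), built from regional BOLD time series.

For region *r* the coupling is

    MFC_r = Spearman( MSN[:, r] \ {r},  FCN[:, r] \ {r} ),

the rank correlation between the two networks' r-th columns with the
self-connection removed. Collecting all regions gives an R-dimensional
coupling map per subject (R = 96 by default); a global scalar pools all
R(R-1)/2 unique off-diagonal pairs into a single Spearman correlation (the
mean of the regional map is also reported as an alternative summary, since
"global" can reasonably mean either).

## Morphological similarity

Each region contributes a sample of voxel-level GM values. Two regions are
compared by:

1. **Density estimation.** Gaussian-kernel KDE per region, evaluated on one
   shared, equally spaced grid of 2^7 = 128 points spanning the pooled
   range of the two samples plus a 10% margin on each side. The shared
   grid is what makes the divergence below well defined; the margin keeps
   kernel tails on-grid.
2. **Bandwidth.** The diffusion / Improved-Sheather-Jones fixed-point
   selector (DCT density representation, fixed point of
   t = xi * gamma^[l](t), l = 7). If the root search fails to bracket —
   which happens for tiny or heavily discretised samples — the selector
   falls back to Silverman's rule with a logged warning. The internal DCT
   grid adapts to sample size (256–1024 points); bandwidths are selected
   once per region, not per pair.
3. **Discretisation.** Density times grid spacing, renormalised to a pmf,
   floored at eps = 1e-12 and renormalised again. The floor guarantees a
   finite divergence even for disjoint-support pairs.
4. **Divergence and similarity.** The symmetric Kullback-Leibler sum
   D(P,Q) = sum_i P_i ln(P_i/Q_i) + Q_i ln(Q_i/P_i), mapped to the
   similarity KLS(P,Q) = exp(-D) in (0, 1]; 1 iff the distributions
   coincide.

For large samples the KDE is evaluated by linear binning onto the pair grid
followed by discrete convolution with the sampled kernel (accuracy
O((spacing/bandwidth)^2), measured < 1e-3 against direct summation); small
samples use the direct sum.

**Accuracy and a known limitation.** For Gaussian regions the true
similarity has the closed form exp(-D) with
D = (s1^2+dmu^2)/(2 s2^2) + (s2^2+dmu^2)/(2 s1^2) - 1. At 5000 voxels per
region and a common scale, the pipeline reproduces this within 0.05
absolutely for every pair (measured max error 0.02-0.03 across seeds).
When region scales differ strongly, mid-similarity pairs acquire a
positive divergence bias of up to ~0.1: the wider distribution has real
tail mass in cells where the narrower region's KDE has no samples at all,
so the floored pmf understates it and the log-ratio overshoots. This is
intrinsic to floored discretized KLD on a finite grid, not a defect of the
bandwidth or binning; rank order of similarities is far more stable than
their absolute values (Spearman agreement with the closed form > 0.95),
which is also why the downstream coupling statistic is rank-based.

## Functional connectivity

Pearson correlation of regional time-series columns; no thresholding,
absolute value, or Fisher transform. Since the coupling statistic is
rank-based, any monotone transform of FCN entries would leave every
coupling value unchanged, so raw r is stored. Zero-variance regions are
reported as errors, not silently dropped.

## Group-level inference

The battery, in order:

1. **ComBat harmonization** of the subjects-by-regions coupling features,
   with site as batch and group membership plus nuisance covariates (age,
   sex, education, mean framewise displacement) protected. Parametric
   empirical-Bayes location/scale model: per-feature standardization
   preserving covariate effects; per-site means/variances shrunk toward
   moment-matched normal / inverse-gamma priors by the iterative
   conditional posterior-mean solver; effects removed; covariate effects
   restored. Per-site variances use the population (ddof = 0) form so a
   single-site round trip is exactly the identity; with one site the EB
   step is skipped (its across-site prior moments are degenerate) and the
   input is returned unchanged to numerical precision.
2. **Covariate adjustment.** Least-squares residualization on
   [intercept | age, sex, education, meanFD], fitted on all subjects
   pooled with group *excluded* from the design — this keeps the group
   effect out of the nuisance projection; groups are then compared on
   residuals.
3. **Mann-Whitney U tests** per region, per network (mean of member
   regions' harmonized coupling; the seven canonical cortical systems VIS,
   SMN, DAN, VAN, LIM, FPN, DMN), and globally (subject mean over
   regions). The U statistic uses midranks; z comes from the
   tie-corrected variance with continuity correction. The p-value uses the
   exact (tie-aware, full enumeration) permutation distribution of U
   whenever both groups have at most 8 subjects — the standard
   small-sample convention, and necessary there because the normal
   approximation deviates from enumeration by up to 0.09 at 2-vs-2 — and
   the asymptotic form otherwise. All tests are two-sided.
4. **BH-FDR** step-up correction, applied within the region family and
   within the network family separately (matching the separate reporting
   of the two levels); threshold q < 0.05.
5. **Symptom association.** For networks passing the FDR threshold,
   partial Pearson correlation (residual method; t-distributed with
   n - k - 2 df) between case-group network coupling and the symptom score,
   adjusting for age, sex and education, BH-corrected over the tested
   networks. The symptom score is a 17-item severity total in [0, 52]
   (nine items scored 0-4, eight scored 0-2).

### Spatial (spin) null

Map-to-map correspondence between two regional maps is tested by rotating
region centroids on the unit sphere: one random rotation per permutation
applied to the left-hemisphere centroids and its mirror image to the
right, followed by an optimal one-to-one assignment of rotated to original
centroids per hemisphere (Hungarian algorithm on the distance matrix).
Using an assignment rather than nearest-neighbour reassignment makes every
null map an exact permutation of the observed map, so the null preserves
the map's value multiset as well as its spatial autocorrelation. The
two-sided p-value is (1 + #{|null| >= |observed|}) / (n_perm + 1) and is
therefore never exactly zero. A plain label-permutation null is available
when centroids are absent.

## Synthetic cohorts

The generator plants every quantity the pipeline estimates:

- **Morphology.** Region r's GM values are Gaussian with location mu_r and
  scale sigma_r (defaults: an irregular golden-ratio sequence spreading
  locations over [0, 3] and scales over [0.8, 1.2], giving pairwise true
  similarities that span (0, 1)). Per-subject locations are jittered
  (SD 0.02) so MSNs vary across subjects. The true similarity matrix
  S_true follows the closed-form Gaussian KLS.
- **Coupling gradient.** Each region carries a fidelity gamma_r in [0, 1]
  (default: linear gradient over [0.15, 0.85]). A subject's functional
  covariance mixes a monotone transform of S_true (scaled to a 0.6 ceiling)
  with an independent symmetric noise matrix (entries N(0, 0.3), clipped),
  weighted per pair by the mean of the two regions' fidelities; the result
  is repaired to the nearest valid correlation matrix by iterated
  eigenvalue clipping and diagonal rescaling (tolerance 1e-8, max 100
  iterations) and the time series are i.i.d. Gaussian rows drawn from it.
  The rank-based coupling estimate is then a monotone function of gamma_r.
- **Group effect.** Cases gain an additive fidelity increment on pairs
  *internal to* the designated networks (default VIS, SMN, DAN). Boosting
  only within-network pairs keeps the contrast concentrated: an
  unaffected region's column profile is untouched. The default increment
  (0.09) was calibrated once on pilot cohorts so that *each* affected
  network's realized case-control shift in mean coupling is roughly half
  a between-subject standard deviation at the default cohort size (96
  regions, 100 subjects per group; measured per-network shifts
  0.46-0.67 SD, minimum ~0.5). Networks containing low-fidelity regions
  respond less to the same increment, which is why the calibration pins
  the weakest network rather than the average.
- **Sites and covariates.** Subjects are assigned round-robin to sites
  within group (so sites are balanced across groups); per-site shifts and
  scales perturb the fidelity parameters, emulating a batch effect on the
  coupling features. Age, sex, education and head motion are drawn from
  ranges matching a typical adult case-control cohort and confound nothing
  unless a config slope says so.
- **Symptoms.** Case severity scores are baseline 22 plus a slope times
  the subject's planted mean fidelity in the first affected network, plus
  noise, clipped to [0, 52].

All randomness flows through a single seeded generator; regeneration with
the same config and seed is bit-identical.

What the generator does **not** emulate: spatial smoothness of GM values
within regions, temporal autocorrelation of BOLD, heavy-tailed motion
artifacts, non-Gaussian GM value distributions, site differences in
anything but the coupling parameters, and any item-level symptom process.
Passing tests therefore demonstrate correctness of the estimators and the
inference chain under a clean generative model, not robustness to real
acquisition artifacts.

## Problem sizes used in validation

Simulation studies are sized to run on a single CPU:

- *Oracle equivalence*: 10 Gaussian regions, 5000 voxels each (45 pairs).
- *Null calibration*: 500 null cohorts of 12 regions and 20 subjects per
  group (80 voxels/region, 60 volumes) through the estimated-MSN pipeline;
  spin-test calibration uses 500 independent map pairs at 96 regions with
  199 rotations each.
- *Gradient recovery*: one full-pipeline cohort at 96 regions, 100
  subjects per group, 5000 voxels per region, 200 volumes.
- *Power*: 100 repetitions at 96 regions and 100 subjects per group with
  the planted similarity standing in for the estimated MSN — at 5000
  voxels the MSN estimation error is negligible relative to functional
  sampling noise (verified by the recovery run), and the group effect
  enters only through the functional side, so this isolates exactly the
  stage under test while keeping 100 repetitions tractable.
- The acceptance script repeats these with somewhat fewer repetitions
  (200 null cohorts, 300 spin replicates, 50 power repetitions).

## Numerical choices

- pmf floor 1e-12 with renormalization before any divergence.
- Matrix TSVs serialized at 6 significant digits; symmetry validated to
  1e-9 on read; voxel and time-series TSVs at full (17-digit) precision
  and re-read with round-trip float parsing, so write-read cycles are
  bit-exact.
- Spearman ties get midranks throughout.
- Region indices are 1-based in every file and 0-based internally; the
  boundary converts exactly once at I/O.
- Degenerate inputs raise typed errors (degenerate region distributions,
  zero-variance time series, constant columns in a correlation,
  rank-deficient designs with the collinear columns named) rather than
  emitting silent sentinel values.

## Known limitations

- Absolute KLS values for strongly scale-heterogeneous region pairs carry
  the tail-floor bias described above; comparisons should lean on ranks.
- ComBat here is the parametric EB variant only; no nonparametric prior or
  reference-batch mode.
- The spin null assumes two hemispheres of centroids on a unit sphere;
  non-spherical coordinates must be projected by the caller.
- Functional time series are i.i.d. in time; serial correlation in real
  BOLD inflates the variance of correlation estimates relative to this
  model.
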