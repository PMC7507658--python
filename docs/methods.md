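# Methods

## The statistic

The analysis substrate is a relative-power tensor P[i, f, s] over grid
nodes i, frequency steps f and subjects s, with an exposure x_s and a
covariate z_s (age). For each cell, the covariate-adjusted Spearman
coefficient is computed on ranks (average ranks for ties): with r_xy,
r_xz, r_yz the Pearson correlations of the standardized rank vectors,

    rho = (r_xy − r_xz r_yz) / sqrt((1 − r_xz²)(1 − r_yz²)),

which is algebraically identical to correlating the least-squares
residuals of the x- and y-ranks on [1, z-ranks]; the identity is what the
vectorized implementation uses (one matrix-vector product per
permutation), while the test suite checks it against the explicit
residual construction. Two-sided p-values use the t approximation with
n − 3 degrees of freedom (n − 2 when no covariate is present). Cells with
zero variance have undefined rho and are never eligible. The per-cell
p-values are never relied on for error control — they only select
candidate cells; family-wise inference comes from the permutation null.

Eligibility requires p < `p_thresh` (default 0.01) inside a same-sign run
of at least `min_consecutive_steps` (default 3) consecutive significant
steps at the node; a significant cell of opposite sign breaks a run. The
run rule is applied per node, not to a cluster's overall frequency
extent; this is one of two readings of the rule and the stricter one (the
other is available by relaxing `min_consecutive_steps` and filtering
clusters afterwards).

Clusters are connected components of equal-sign eligible cells under
spatial adjacency (Euclidean distance ≤ `spatial_neighbor_dist`, default
1.1 × grid spacing, i.e. face adjacency; no diagonal node-and-frequency
joint moves) plus frequency adjacency (same node, step ± 1). Each
cluster's frequency layers with fewer than max(1, ⌊`min_nodes_fraction` ×
n_nodes⌋) nodes (12 at 1% of a 1202-node grid) are trimmed and the run
criterion re-checked on the surviving steps; `under_threshold_policy =
"reject"` discards whole clusters instead of trimming. Trimming was
chosen as default because the extent rule reads most naturally as a
constraint on which layers count, not as a veto on the cluster. The
cluster mass is the sum of member rho values; by construction all members
share one sign, so the mass carries that sign.

The permutation scheme shuffles the exposure values across subjects and
leaves the covariate attached to each subject's power, so the null
hypothesis is "exposure exchangeable given the observed power-covariate
pairs". The entire map → eligibility → clustering pipeline re-runs per
permutation; the largest absolute surrogate mass (0 when no surrogate
cluster forms) is retained. The family-wise p is the plain proportion of
permutations reaching the observed |mass| (p = 0 possible); a smoothed
(k + 1)/(N + 1) estimator and a Freedman–Lane variant (permuting exposure
rank residuals about the covariate fit) are available via `ClusterParams`
but are not defaults, keeping the plain scheme the reference behaviour.

## Follow-up models

The per-subject mean power over a significant cluster's cells is the
marker for all downstream stages. Moderation uses nested OLS (via
statsmodels): marker ~ 1 + exposure + group and the same plus
exposure × group, with the group binary-coded 0/1 (E3/E3 = 0, E3/E4 = 1;
young = 0, old = 1). The interaction coefficient's two-sided t-test
(df = n − 4) gives the moderation p; ΔR² = R²_full − R²_base ≥ 0 is the
effect size. Subgroup correlations default to plain Spearman on complete
cases (n can vary by outcome; fewer than 4 cases flags the estimate
undefined rather than raising); an `adjust_age` flag switches to the
partial coefficient. Region coverage reports, for each labelled region
containing at least one cluster node, 100 × (cluster nodes in region) /
(region nodes), counting nodes once regardless of frequency multiplicity.

## The synthetic generator

The generator emulates the statistical structure of source-space
relative power at rest, not its biophysics (no sensor simulation, head
modelling or beamforming — the tensor enters where beamformer output
would). Components, all per 0.25-Hz bin on 8–14 Hz by default:

- **Mean spectrum**: background `bg_amp · (10/f)^bg_exponent` (0.004 at
  10 Hz, exponent 1) plus an alpha bump `alpha_amp ·
  exp(−(f − 10)²/(2 · 1.2²))` (0.012 at peak). The 25 alpha-window bins
  then carry roughly 20% of broadband power, typical of eyes-closed rest.
- **Subject variability**: log-normal global amplitude (SD 0.2) and bump
  amplitude (SD 0.3), alpha peak-frequency jitter (SD 0.5 Hz), background
  exponent jitter (SD 0.15), and a smooth spatial modulation of the bump
  built from 8 Gaussian kernels (30-mm bandwidth) with per-subject
  coefficients (SD 0.3 after normalization). A small independent
  log-normal residual (SD 0.1) per cell completes the model. These
  latents make power strongly correlated between adjacent cells
  (empirically ≈ 0.93 across subjects for 10-mm neighbours and adjacent
  steps), which is what real source spectra look like and what the
  cluster statistic exploits; with independent cell noise the null
  pipeline would almost never form clusters and permutation p-values
  would be vacuous.
- **Planted effects** use a Gaussian copula on ranks: inside the target
  (nodes × band × strata) cells the subject variation is replaced by a
  monotone transform of `r·z_x + √(1 − r²)·ε`, where z_x are normal
  scores of the exposure ranks and r = 2 sin(π ρ_s/6) converts the target
  Spearman ρ_s to the latent Pearson r. Spearman correlations are
  invariant under the monotone map, so the realized rank correlation
  approaches the target regardless of marginals. A fraction
  `noise_share_subject` (default 0.8) of the residual ε is drawn once per
  subject and shared across the planted cells, the rest per cell; real
  spectra move together within a subject, and a high share keeps the
  cluster-average marker's correlation near the per-cell target instead
  of averaging the noise away.
- **Cohort**: four strata (young/old × E3/E3, E3/E4) of 44/33/20/16
  subjects by default; exposure from a gamma distribution parameterized
  by mean 0.012 and SD 0.012 (nonnegative and right-skewed, as a
  fraction of wear time must be; only mean ± SD are constrained, the
  gamma shape is a stand-in); ages uniform on 48–59 (young) and 60–82
  (old) with the young/old cut at 60 years. Sex, MMSE and BMI columns
  carry realistic marginals and no signal.
- **Outcomes** (memory indices, gray-matter volumes) are planted by the
  same copula construction on the marker's ranks within one designated
  stratum, independent noise elsewhere, with plausible marginal means
  and SDs; a `missing_rate` can blank entries to exercise complete-case
  handling.

What passing tests on this generator do **not** show: robustness to
non-exchangeable confounding (e.g. exposure–age dependence beyond what
partialling removes), to inhomogeneous grids, to the true anatomical
correlation structure of cortex, or to artifacts of real recordings.

## Validation experiments and problem sizes

`alphaclust.validation` measures operating characteristics at a
desk-scale setting chosen to keep a full run in the minutes range on one
CPU: a 150-node grid (8 × 8 × 3 lattice, 78% contiguous mask, 10-mm
spacing), 25 frequency steps.

- **Null calibration**: 100 datasets of 60 subjects with exposure
  independent of power, 200 permutations each; the fraction of datasets
  with any cluster at family-wise p < 0.05 should sit inside the exact
  binomial 95% interval around 0.05. Note the test is self-calibrating by
  exchangeability; the experiment checks the implementation, and is only
  informative because the generator's smooth fields let surrogate
  clusters form at a healthy rate (≈ 10–15% of permutations).
- **Recovery**: ρ = 0.5 planted over 30 nodes × 10 steps, n = 113, 500
  permutations, 20 seeds; the top cluster must be significant at 0.05
  with Jaccard overlap ≥ 0.5 against the planted support in ≥ 80% of
  seeds (observed: 20/20 with overlap ≈ 1).

## Numerical choices and degenerate inputs

- Ranks: average ranks everywhere (scipy `rankdata`); rank vectors are
  standardized to zero mean and unit norm so correlations are dot
  products.
- Eligibility thresholding inside the permutation loop uses the exact
  |rho| threshold equivalent to p < `p_thresh` under the t
  approximation, so observed and surrogate passes run identical code.
- Spectral estimation averages Hann-tapered periodograms over
  non-overlapping 4-s segments (mean, not median); 4-s windows natively
  give 0.25-Hz bins, so no extra smoothing kernel is applied; a coarser
  `df_target` is honoured by averaging adjacent bins. Fewer than
  `min_segments` (default 20, i.e. 80 s) raises an insufficient-data
  error. Band edges are inclusive with a 1e-9 Hz tolerance;
  normalization over 1.5–45 Hz precedes band selection.
- Power tensors are validated on load: finite, inside [0, 1], dimension
  labels present; axis order on disk is free and normalized on read.
- Determinism: every stochastic stage takes a seed; the pipeline expands
  one master seed into per-stage child seeds (SeedSequence), so a
  simulate + analyze run is a pure function of its config. HDF5 datasets
  are written with timestamps disabled.
- Degenerate inputs: constant exposure raises; constant covariate falls
  back to the unadjusted coefficient; constant cells are flagged
  undefined; single-level or collinear moderation designs raise;
  subgroups below n = 4 are flagged undefined rather than raising.

## Known limitations

- The t approximation for per-cell Spearman p-values is inaccurate at
  very small n; only the eligibility threshold depends on it, and the
  permutation null absorbs the miscalibration at the cluster level.
- Layer trimming can in principle leave a cluster whose retained steps
  are spatially disconnected at some layers; the component is kept as
  one cluster (no re-splitting), matching the flood-fill oracle.
- The generator's spatial field is low-dimensional by design; its null
  cluster-mass distribution is heavier-tailed than a high-dimensional
  cortical field would give, which makes the recovery experiment
  conservative with respect to surrogate competition.
- No three-way (exposure × age × genotype) interaction model is
  provided.
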