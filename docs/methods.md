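# Methods

`scpowersim` estimates the power of a planned multi-sample single-cell
study to detect a differentially abundant (DA) cell state, by simulating
the whole analysis — dataset generation in principal-component (PC) space,
re-clustering, and mixed-model association testing — many times under a
user-controlled study design.

## Model

### Stage 1 — parameter estimation

A *prototype* dataset (cells × PCs embedding plus per-cell sample, batch
and cluster labels) is reduced to a parameter set:

**PC-space variation.** For every cluster and every PC we fit, by REML,

    PC ~ 1 + (1 | batch) + (1 | sample)

i.e. a linear mixed model with two crossed random intercepts.  The fitted
intercepts across PCs form the cluster centroid μ; the random-intercept
variances τ²_B and τ²_S across PCs form the diagonals of the batch and
sample covariance matrices Σ_B and Σ_S (enforced diagonal); and the full
empirical covariance of the per-cell residual matrix gives the residual
covariance Σ_C, interpreted as variation intrinsic to the cluster.
Clusters present in fewer than two batches (or samples) drop the
corresponding random effect and record its variance as 0.

The REML solver exploits the structure of the model: with q = n_batches +
n_samples random levels, each likelihood evaluation reduces through the
Woodbury identity to dense q × q linear algebra, independent of cell
count, so k × nPC fits cost seconds even for large prototypes.  Variance
ratios are optimised on the log scale (Nelder-Mead, two starts) and
boundary solutions are snapped to exactly 0 with a `singular` flag.  The
solver agrees with statsmodels' `MixedLM` (variance-components
formulation) to ~1e-6 in log-likelihood on test fixtures.

**Cluster-frequency variation.** Per sample, cluster counts are
incremented by a pseudo-count of 1 (so clusters absent from a sample keep
positive mass) and normalised to proportions by the incremented totals
(so they sum to exactly 1 — the source procedure is ambiguous about the
denominator; this choice keeps the resampling model internally
consistent).  μ_cf is the natural log of the across-sample mean
proportions; Σ_cf is the unbiased covariance of per-sample log
proportions.  Note the deliberate asymmetry (log of mean vs covariance of
logs): it mirrors the estimation procedure the simulation model assumes.

### Stage 2 — dataset generation

For each simulated sample a frequency profile is drawn in log space,

    F ∝ exp( N(μ_cf, Σ_cf · cf_scale) ),   normalised to sum 1,

so frequencies are never negative; `cf_scale = 0` gives every sample the
identical profile.  Case samples then have a fold change induced in a
target cluster: its frequency f becomes min(fc · f, 1) and the remaining
clusters are rescaled proportionally into the leftover mass (exactly 0
each when the cap consumes everything).  With `cf_scale = 0` the realised
case/control frequency ratio equals fc exactly at the profile level.

Cells are allocated to clusters by deterministic largest-remainder
rounding of profile × cells_per_sample (ties by cluster index).  A
multinomial draw would be equally defensible; the deterministic rule makes
the induced fold change exact rather than exact-in-expectation, which is
the property the rest of the pipeline is calibrated against.

Each cluster receives one linear shift per batch, b_m ~ N(0, Σ_B·b_scale),
and one per sample, s_d ~ N(0, Σ_S·s_scale); a cell of that cluster in
batch m and sample d then draws its coordinates from

    L ~ N(μ + b_m + s_d, Σ_C).

Setting a scale factor to 0 removes that variance source exactly (the
shift is the zero vector, not a small draw).

Randomness is organised as one root generator per simulation with
deterministic sub-streams for target choice, profiles, batch shifts,
sample shifts and coordinates, so each stage's draws are stable under
changes to the others.

Batch-layout helpers cover the designs of interest: balanced round-robin
(`distribute_samples`, e.g. 4 samples per batch), one-sample-per-batch
sequential processing (`distribute_sample_per_batch`), and multiplexing
(`distribute_split_sample`: each sample split into equal subsample units,
laid out Latin-square style so a batch mixes units of distinct samples
and a sample's units never share a batch).

### Stage 3 — DA testing and power

Simulated coordinates are re-clustered: a shared-nearest-neighbor graph
(k = 30 neighborhoods including the cell itself; edge weight = Jaccard
similarity of neighborhoods; edges below 1/15 pruned — the convention of
the mainstream single-cell toolkits) followed by Louvain community
detection at a user resolution (defaults 1.2; tissue-style presets use
0.4–2.0).  igraph's Louvain draws shuffles from Python's `random`, which
the wrapper seeds for reproducibility.

Each resulting cluster is tested with MASC: per-cell membership is
modelled by logistic mixed models

    null:  member ~ 1         + (1 | batch) + (1 | sample)
    full:  member ~ condition + (1 | batch) + (1 | sample)

fitted by maximum likelihood under the Laplace approximation, and
compared by a likelihood-ratio test against χ²₁.  Because all covariates
are constant within a (sample, batch) pair, the per-cell Bernoulli data
collapse losslessly to a few binomial rows, making each fit essentially
instant regardless of cell count.  The fitting criterion matches lme4's
`glmer` (nAGQ = 1) — fixed effects are part of the outer optimisation
because the Laplace log-determinant depends on them — and agrees with
glmer to < 1e-3 in deviance on test fixtures.  A per-sample fixed-effects
alternative (OLS of case-control status on cluster frequency) is provided
for comparison.

A simulation *detects* DA when any cluster's p-value beats the Bonferroni
threshold 0.05/k, where k is the number of clusters found in that
simulation.  Power over n simulations is the detection fraction with a
95% Wilson score interval.  An *interpretability* score asks whether the
right cells were detected: the Pearson correlation between the per-cell
indicator of originating from the causal (induced) cluster and the
indicator of membership in any significant cluster; it is 0 when nothing
is significant, and defined as 0 (with a warning) in the degenerate case
of a constant indicator.  Interpretability can be legitimately negative —
a strong expansion of one cluster depletes the others, which may
themselves reach significance.

## Synthetic prototypes

`synthetic_prototype` generates prototype datasets with known ground
truth by running the simulation machinery itself at scale factors 1:
centroids placed at pairwise distance `centroid_separation` along random
orthonormal directions (one scalar controls cluster distinctness),
isotropic residual covariance `residual_sd² I`, diagonal batch/sample
shift covariances, and log-normal frequency variation.  The generating
log-frequency covariance is constructed as P diag(logfreq_sd²) P' with
P = I − 1 w' (w the mean proportions): log proportions of compositional
data always carry this centering, so estimation can recover the matrix it
simulates from (an uncentered covariance would be distorted by the
normalisation with an irreducible ~(1 − 1/k) bias).

Defaults (5 clusters, 20 PCs, 40 samples in 10 batches, 200 cells per
sample, separation 10, batch/sample shift SD 0.5/0.3, residual SD 1,
log-frequency SD 0.5, geometric mean-frequency decay 0.65) describe a
mid-sized tissue study: clusters distinct but with realistic batch
structure and large across-sample frequency variation.  Three presets
encode qualitative contrasts between study types — `ra_like` / `uc_like`
(fewer samples, wide centroid spread, high frequency variation) vs
`tb_like` (many samples, low frequency variation).  Preset numbers are
illustrative and not calibrated to any real dataset.

What the generator does *not* emulate: non-Gaussian within-cluster shape,
continuous differentiation trajectories, doublets/ambient RNA, per-cell
library-size effects, or gene-level counts.  Passing tests therefore
demonstrate correctness of the estimation/simulation/testing machinery
under its own model, and calibration/power behaviour in Gaussian-mixture
regimes — not that any particular real tissue will match a preset.

## Numerical choices

- Variance parameters optimised on log scale with bound log γ ∈ [−14, 10]
  (LMM) and log σ ∈ [−6, 4] (GLMM); boundary fits snapped to 0 and
  flagged.
- Covariance factorisation for simulation: Cholesky with an eigenvalue
  fallback clipping tiny negatives (tolerance 1e-8 relative); a zero
  matrix yields exactly degenerate draws.
- LRT statistics clipped at 0; constant-condition designs return p = 1
  flagged rather than erroring.
- Largest-remainder ties broken by stable cluster-index order.
- PSD validation accepts eigenvalues ≥ −1e-8 (relative).

## Problem sizes

Monte-Carlo tests in the suite run scaled down — null calibration at
10+10 samples × 100 cells × 40 simulations, monotonicity at 25
simulations per level, 10 PCs — sizes chosen so the whole suite completes
in minutes while the binomial confidence intervals remain informative.
The acceptance script (`scripts/acceptance.py`) runs the null-calibration
study at full size: 5 clusters, 20+20 samples × 200 cells, 20 PCs, 100
simulations.

## Known limitations

- Only batch and sample are modelled as variance components; other
  covariates (age, sex, protocol) fold into the residual.
- Σ_B and Σ_S are diagonal in PC space; correlated batch effects across
  PCs are not represented.
- The Laplace approximation can be slightly anti-conservative for very
  small clusters (few cells per sample); the null-calibration test bounds
  the aggregate effect.
- Power estimates are conditional on the prototype: a poorly chosen or
  tiny prototype (fewer than ~6 samples, < 500 cells/sample — the loader
  warns) yields unstable variance estimates and optimistic or pessimistic
  power.
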