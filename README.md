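# scpowersim

Simulation-based power analysis for detecting **differentially abundant
(DA) cell states** in multi-sample, case-control single-cell studies.

Planning a single-cell experiment raises questions a standard power
calculator cannot answer: how many samples and cells are needed to detect
a 50% expansion of a T-cell state, given realistic batch effects and the
large sample-to-sample variation of cell-state frequencies in human
tissue?  `scpowersim` answers them by simulating the entire analysis —
data generation, clustering, and association testing — many times under a
candidate study design, using variance parameters estimated from a
*prototype* dataset (a pilot or public dataset from a similar setting).

## The model in brief

Three stages:

1. **Estimate.**  From a prototype (cells × PCs embedding plus
   sample/batch/cluster labels), fit per cluster and per PC the linear
   mixed model `PC ~ 1 + (1|batch) + (1|sample)` by REML, yielding the
   centroid μ, diagonal batch/sample covariances Σ_B, Σ_S (the τ²'s), and
   the residual covariance Σ_C.  Cluster frequencies per sample are
   pseudo-counted, normalised, and summarised by μ_cf (log mean
   proportions) and Σ_cf (covariance of log proportions).

2. **Simulate.**  Per sample, draw a frequency profile
   `F ∝ exp N(μ_cf, Σ_cf·cf_scale)`; induce a fold change *fc* in a
   target cluster of case samples (capped at 1, others renormalised);
   allocate cells by largest-remainder rounding; draw each cell's
   coordinates from `N(μ + b_m + s_d, Σ_C)` with cluster-specific batch
   and sample shifts `b_m ~ N(0, Σ_B·b_scale)`, `s_d ~ N(0, Σ_S·s_scale)`.

3. **Test.**  Re-cluster the simulated cells (SNN graph, k = 30, Jaccard
   weights + Louvain), test each cluster with MASC — a logistic mixed
   model likelihood-ratio test of `member ~ condition + (1|batch) +
   (1|sample)` — and call the study *detected* if any cluster passes the
   Bonferroni threshold 0.05/k.  Power = detection fraction over
   simulations, with a 95% Wilson interval, plus an interpretability
   score asking whether the detected cells are the induced ones.

See `docs/methods.md` for assumptions, parameter meanings and numerical
details.

## Worked example

No download is needed — the package ships a synthetic-prototype generator
with known ground truth:

```python
import scpowersim as sp

# a synthetic prototype: 5 cell states, 40 samples in 10 batches
spec = sp.PrototypeSpec(k=5, n_pcs=10, n_samples=40, n_batches=10,
                        cells_per_sample=200, seed=1)
data, truth = sp.generate_prototype(spec)

params = sp.estimate_params(data)            # stage 1

design = sp.StudyDesign(n_case=10, n_control=10, cells_per_sample=200,
                        n_batches=5, fold_change=2.0,
                        resolution=1.2, seed=7)
report = sp.run_power_study(params, design, n_sims=20)   # stages 2+3
print(f"power = {report.power:.2f}  "
      f"[{report.ci_low:.2f}, {report.ci_high:.2f}]")
print(f"mean interpretability = "
      f"{sum(r['interpretability'] for r in report.simulations) / 20:.2f}")
```

prints

```
power = 0.80  [0.58, 0.92]
mean interpretability = 0.43
```

i.e. a 20-sample study with 200 cells/sample detects a two-fold expansion
of a (randomly chosen) cell state in 80% of simulated experiments
(the interval is the Wilson 95% CI over the 20 Monte-Carlo runs), and the
clusters flagged as significant overlap substantially — though not
perfectly — with the cells whose state was actually expanded.

The same pipeline is scriptable from the shell:

```bash
scpowersim synth --preset ra_like --seed 1 --out proto/
scpowersim estimate --embeddings proto/embeddings.tsv --meta proto/meta.tsv \
                    --npc 20 --out params.json
scpowersim power --params params.json --design design.yaml \
                 --nsims 500 --test masc --seed 7 --out report.json
```

and `scpowersim pipeline --config grid.yaml --out results/` sweeps a grid
of fold changes × sample sizes (default fold-change grid
1, 1.05, 1.1, 1.25, 1.5, 2, 4) and writes one report per point plus a
summary table.

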