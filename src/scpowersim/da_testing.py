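"""Differential-abundance testing and power aggregation.

The third stage of the pipeline: simulated PC coordinates are re-clustered
(shared-nearest-neighbor graph + Louvain communities), each resulting
cluster is tested for an association between membership and case-control
status with a logistic mixed model controlling batch and sample as random
intercepts (the MASC test), and a study is called detected when any
cluster's likelihood-ratio p-value beats the Bonferroni threshold
``0.05 / k``.  Power over many simulated studies is the detection fraction
with a Wilson binomial confidence interval, and an interpretability score
quantifies whether the detected cells are the ones whose cluster actually
expanded.
"""

from __future__ import annotations

import random as _pyrandom
import warnings

import igraph
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.proportion import proportion_confint

from .data_model import EstimatedParams, PowerReport, SimulatedDataset, StudyDesign
from .glmm import fit_logistic_mixed
from .simulation import simulate_dataset

__all__ = [
    "build_snn_graph",
    "louvain_cluster",
    "cluster_dataset",
    "MASCResult",
    "masc_test",
    "fixed_effects_test",
    "detect",
    "estimate_power",
    "interpretability_score",
    "run_power_study",
]

DEFAULT_SNN_K = 30
DEFAULT_PRUNE = 1.0 / 15.0


def build_snn_graph(embeddings, k: int = DEFAULT_SNN_K,
                    prune: float = DEFAULT_PRUNE) -> igraph.Graph:
    """Shared-nearest-neighbor graph over cells.

    Each cell's neighborhood is its ``k`` nearest cells (Euclidean distance
    in PC space, the cell itself included).  Cells are joined by an edge
    weighted with the Jaccard similarity of their neighborhoods; edges
    below ``prune`` are dropped.
    """
    X = np.asarray(embeddings, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    idx = nn.kneighbors(return_distance=False)  # excludes self
    idx = np.column_stack([np.arange(n), idx[:, : k - 1]])  # self + k-1 others
    rows = np.repeat(np.arange(n), k)
    A = sparse.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    shared = A @ A.T  # |N(i) & N(j)|
    shared = sparse.triu(shared, k=1).tocoo()
    jac = shared.data / (2.0 * k - shared.data)
    keep = jac >= prune
    edges = np.column_stack([shared.row[keep], shared.col[keep]]).astype(np.int64)
    g = igraph.Graph(n=n)
    g.add_edges(edges)
    g.es["weight"] = jac[keep]
    return g


def louvain_cluster(graph: igraph.Graph, resolution: float = 1.2,
                    seed: int = 0) -> np.ndarray:
    """Louvain community detection on a weighted graph; labels as strings.

    igraph draws its shuffles from Python's ``random`` module, so seeding
    makes the partition reproducible.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        part = graph.community_multilevel(weights="weight", resolution=resolution)
    finally:
        _pyrandom.setstate(state)
    return np.asarray([str(c) for c in part.membership], dtype=object)


def cluster_dataset(dataset: SimulatedDataset, resolution: float = 1.2,
                    k: int = DEFAULT_SNN_K, seed: int = 0) -> SimulatedDataset:
    """Attach post-hoc SNN+Louvain cluster labels to a simulated dataset."""
    g = build_snn_graph(dataset.embeddings, k=k)
    dataset.new_clusters = louvain_cluster(g, resolution=resolution, seed=seed)
    return dataset


class MASCResult(dict):
    """Per-cluster MASC output: maps label -> dict with keys
    ``lrt_statistic``, ``p_value``, ``converged``."""

    def p_values(self) -> dict:
        return {c: r["p_value"] for c, r in self.items()}


def _collapse_rows(condition_of, batch_of, sample_of):
    """Group cells by (sample, batch); covariates are constant within groups."""
    df = pd.DataFrame({
        "cond": np.asarray(condition_of),
        "batch": np.asarray(batch_of),
        "sample": np.asarray(sample_of),
    })
    df["row"] = df["sample"].astype(str) + "\x00" + df["batch"].astype(str)
    row_codes, row_ids = pd.factorize(df["row"])
    first = df.groupby(row_codes).first()
    m = np.bincount(row_codes).astype(float)
    bc, n_b = pd.factorize(first["batch"])
    sc, n_s = pd.factorize(first["sample"])
    cond01 = (first["cond"].to_numpy() == "case").astype(float)
    return row_codes, m, bc.astype(np.intp), len(n_b), sc.astype(np.intp), len(n_s), cond01


def masc_test(new_cluster_of, condition_of, batch_of, sample_of) -> MASCResult:
    """MASC: per-cluster logistic mixed-model test of differential abundance.

    For every cluster the per-cell indicator of membership is modelled as

        null:  member ~ 1         + (1 | batch) + (1 | sample)
        full:  member ~ condition + (1 | batch) + (1 | sample)

    both fitted by maximum likelihood (Laplace approximation); the p-value
    is the chi-square(1) upper tail of twice the log-likelihood-ratio.
    """
    clusters = np.asarray(new_cluster_of)
    conds = np.asarray(condition_of)
    labels = sorted(set(clusters))
    row_codes, m, bc, n_b, sc, n_s, cond01 = _collapse_rows(
        condition_of, batch_of, sample_of)
    n_rows = len(m)
    constant_cond = len(set(conds)) < 2
    X_null = np.ones((n_rows, 1))
    X_full = np.column_stack([np.ones(n_rows), cond01])
    out = MASCResult()
    for label in labels:
        member = (clusters == label).astype(float)
        y = np.bincount(row_codes, weights=member, minlength=n_rows)
        if constant_cond:
            out[str(label)] = {"lrt_statistic": 0.0, "p_value": 1.0,
                               "converged": True, "flag": "constant condition"}
            continue
        f_null = fit_logistic_mixed(y, m, X_null, bc, n_b, sc, n_s)
        f_full = fit_logistic_mixed(y, m, X_full, bc, n_b, sc, n_s,
                                    x0=f_null.log_sd_opt)
        lrt = max(0.0, 2.0 * (f_full.loglik - f_null.loglik))
        out[str(label)] = {
            "lrt_statistic": lrt,
            "p_value": float(stats.chi2.sf(lrt, df=1)),
            "converged": bool(f_null.converged and f_full.converged),
        }
    return out


def fixed_effects_test(sample_frequencies: pd.DataFrame,
                       condition_per_sample) -> dict:
    """Per-cluster linear regression of case-control status on frequency.

    ``sample_frequencies`` is samples x clusters; the p-value of the slope
    is reported per cluster.  A cluster with constant frequency across
    samples gets p = 1.
    """
    cond = pd.Series(condition_per_sample).reindex(sample_frequencies.index)
    y = (cond.to_numpy() == "case").astype(float)
    out = {}
    for label in sample_frequencies.columns:
        x = sample_frequencies[label].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            out[str(label)] = 1.0
            continue
        res = stats.linregress(x, y)
        out[str(label)] = float(res.pvalue)
    return out


def detect(p_values, k: int | None = None, alpha: float = 0.05) -> bool:
    """Bonferroni detection rule: any p below ``alpha / k``.

    ``k`` defaults to the number of p-values supplied (the number of
    clusters tested in this simulation).
    """
    p = list(p_values.values()) if isinstance(p_values, dict) else list(p_values)
    if not p:
        return False
    if k is None:
        k = len(p)
    return bool(min(p) < alpha / k)


def significant_clusters(p_values: dict, alpha: float = 0.05) -> list:
    """Cluster labels passing the Bonferroni threshold alpha / k."""
    k = len(p_values)
    return [c for c, p in p_values.items() if p < alpha / k]


def estimate_power(detections) -> tuple:
    """Detection fraction with a 95% Wilson confidence interval."""
    d = np.asarray(list(detections), dtype=bool)
    if d.size == 0:
        raise ValueError("no simulations to aggregate")
    n_hit = int(d.sum())
    power = n_hit / d.size
    lo, hi = proportion_confint(n_hit, d.size, alpha=0.05, method="wilson")
    return float(power), float(lo), float(hi)


def interpretability_score(origin_cluster_of, causal_cluster,
                           new_cluster_of, significant) -> float:
    """Correlation between causal-origin membership and detected membership.

    Per cell, two indicators are formed: originated from the causal
    (induced) cluster, and member of a significantly DA cluster.  The score
    is their Pearson correlation; 0 when nothing was detected, and defined
    as 0 (with a warning) when an indicator is constant despite detections.
    """
    significant = set(str(s) for s in significant)
    if not significant:
        return 0.0
    a = (np.asarray(origin_cluster_of) == str(causal_cluster)).astype(float)
    b = np.isin(np.asarray(new_cluster_of).astype(str), list(significant)).astype(float)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        warnings.warn("constant indicator while DA clusters exist; "
                      "interpretability set to 0", UserWarning, stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def run_power_study(params: EstimatedParams, design: StudyDesign,
                    n_sims: int, seed: int | None = None,
                    test: str = "masc", snn_k: int = DEFAULT_SNN_K,
                    alpha: float = 0.05) -> PowerReport:
    """Monte-Carlo power estimate: simulate, re-cluster, test, aggregate.

    Each simulation derives its own random stream from ``seed`` (falling
    back to ``design.seed``), so results are reproducible and independent
    of execution order.  ``test`` selects the per-cluster DA test:
    ``"masc"`` (mixed model on cells) or ``"fixed"`` (linear regression on
    per-sample frequencies).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if test not in {"masc", "fixed"}:
        raise ValueError(f"unknown test {test!r}")
    if seed is None:
        seed = design.seed
    root = np.random.SeedSequence(seed)
    records = []
    for i, child in enumerate(root.spawn(n_sims)):
        rng = np.random.default_rng(child)
        ds = simulate_dataset(params, design, rng=rng)
        cluster_dataset(ds, resolution=design.resolution, k=snn_k,
                        seed=int(child.generate_state(1)[0] % (2 ** 31)))
        if test == "masc":
            res = masc_test(ds.new_clusters, ds.conditions, ds.batches, ds.samples)
            pvals = res.p_values()
        else:
            freq = pd.crosstab(pd.Series(ds.samples, name="sample"),
                               pd.Series(ds.new_clusters, name="cluster"),
                               normalize="index")
            cond = pd.Series(ds.conditions, index=ds.samples).groupby(level=0).first()
            pvals = fixed_effects_test(freq, cond)
        hit = detect(pvals, alpha=alpha)
        sig = significant_clusters(pvals, alpha=alpha)
        interp = interpretability_score(ds.origin_clusters, ds.target_cluster,
                                        ds.new_clusters, sig)
        records.append({
            "p_values": {c: float(p) for c, p in pvals.items()},
            "n_clusters": len(pvals),
            "detected": bool(hit),
            "significant_clusters": sig,
            "interpretability": interp,
            "target_cluster": ds.target_cluster,
        })
    power, lo, hi = estimate_power([r["detected"] for r in records])
    report = PowerReport(
        simulations=records, power=power, ci_low=lo, ci_high=hi,
        config={"design": design.to_dict(), "n_sims": n_sims, "seed": seed,
                "test": test, "snn_k": snn_k, "alpha": alpha},
    )
    return report.validate()
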