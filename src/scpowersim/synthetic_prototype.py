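"""Synthetic prototype datasets with known ground-truth parameters.

Real prototype datasets (e.g. tissue scRNA-seq studies) supply the PC
embeddings and metadata the estimation stage consumes.  This module builds
structurally similar datasets from scratch — multiple clusters with
distinct PC centroids, cluster-specific batch and sample shifts, and
log-normal cluster-frequency variation across samples — while returning
the exact generating parameters, so parameter recovery and power behaviour
can be tested end to end without any download.

Generation reuses the simulation machinery itself: a ground-truth
parameter set is constructed from the spec, and one multi-sample dataset
is drawn from it with all scale factors at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import EstimatedParams, PrototypeDataset, StudyDesign
from .simulation import simulate_dataset

__all__ = ["PrototypeSpec", "build_truth_params", "generate_prototype",
           "preset_prototypes", "PRESET_NAMES"]

PRESET_NAMES = ("ra_like", "tb_like", "uc_like")


@dataclass
class PrototypeSpec:
    """Ground-truth description of a synthetic prototype.

    ``centroid_separation`` is the pairwise Euclidean distance between
    cluster centroids (placed along random orthogonal directions, so one
    scalar controls cluster distinctness).  ``batch_sd`` / ``sample_sd``
    are per-PC standard deviations of the cluster-specific batch and
    sample shifts; ``residual_sd`` the isotropic within-cluster spread.
    ``logfreq_sd`` sets the across-sample spread of log cluster
    frequencies; ``mean_freqs`` (optional) fixes mean cluster proportions,
    defaulting to a geometric decay over clusters.
    """

    k: int = 5
    n_pcs: int = 20
    n_samples: int = 40
    n_batches: int = 10
    cells_per_sample: int = 200
    centroid_separation: float = 10.0
    batch_sd: float = 0.5
    sample_sd: float = 0.3
    residual_sd: float = 1.0
    logfreq_sd: float = 0.5
    mean_freqs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k, self.n_pcs, self.n_samples, self.n_batches,
               self.cells_per_sample) < 1:
            raise ValueError("all counts must be >= 1")
        if self.k > self.n_pcs:
            raise ValueError("need n_pcs >= k to place orthogonal centroids")
        if self.n_batches > self.n_samples:
            raise ValueError("more batches than samples is infeasible")
        if min(self.batch_sd, self.sample_sd, self.residual_sd,
               self.logfreq_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.mean_freqs is not None:
            f = np.asarray(self.mean_freqs, dtype=float)
            if f.shape != (self.k,) or np.any(f <= 0):
                raise ValueError("mean_freqs must be k positive values")
            self.mean_freqs = f / f.sum()


def _default_mean_freqs(k: int) -> np.ndarray:
    f = 0.65 ** np.arange(k)
    return f / f.sum()


def build_truth_params(spec: PrototypeSpec) -> EstimatedParams:
    """Construct the generating parameter set for a spec.

    Centroids sit at ``separation / sqrt(2)`` along random orthonormal
    directions (pairwise distance = ``centroid_separation``).  The
    log-frequency covariance is ``P diag(logfreq_sd^2) P'`` with
    ``P = I - 1 w'`` (w = mean proportions): log proportions of a
    composition always carry this centering, so the estimation stage can
    recover the matrix it simulates from.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xC3)))
    basis, _ = np.linalg.qr(rng.standard_normal((spec.n_pcs, spec.k)))
    centroids = basis.T * (spec.centroid_separation / np.sqrt(2.0))
    w = (np.asarray(spec.mean_freqs, dtype=float) if spec.mean_freqs is not None
         else _default_mean_freqs(spec.k))
    P = np.eye(spec.k) - np.outer(np.ones(spec.k), w)
    logfreq_cov = P @ np.diag(np.full(spec.k, spec.logfreq_sd ** 2)) @ P.T
    labels = [f"clu{i:02d}" for i in range(spec.k)]
    return EstimatedParams(
        cluster_labels=labels,
        centroids=centroids,
        batch_var=np.full((spec.k, spec.n_pcs), spec.batch_sd ** 2),
        sample_var=np.full((spec.k, spec.n_pcs), spec.sample_sd ** 2),
        residual_cov=np.stack([np.eye(spec.n_pcs) * spec.residual_sd ** 2
                               for _ in range(spec.k)]),
        mean_logfreq=np.log(w),
        logfreq_cov=(logfreq_cov + logfreq_cov.T) / 2.0,
    ).validate()


def generate_prototype(spec: PrototypeSpec):
    """Draw one prototype dataset plus its generating parameters.

    Returns ``(dataset, truth)`` where ``dataset`` is a validated
    :class:`PrototypeDataset` whose ``clusters`` are the true generating
    labels, and ``truth`` the exact :class:`EstimatedParams` it was drawn
    from.  Deterministic under ``spec.seed``.
    """
    truth = build_truth_params(spec)
    n_case = spec.n_samples // 2
    design = StudyDesign(
        n_case=n_case, n_control=spec.n_samples - n_case,
        cells_per_sample=spec.cells_per_sample, n_batches=spec.n_batches,
        b_scale=1.0, s_scale=1.0, cf_scale=1.0, fold_change=1.0,
        target_cluster=truth.cluster_labels[0], seed=spec.seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xDA)))
    sim = simulate_dataset(truth, design, rng=rng)
    ds = PrototypeDataset(
        embeddings=sim.embeddings,
        cell_ids=sim.cell_ids,
        samples=sim.samples,
        batches=sim.batches,
        clusters=sim.origin_clusters,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # small-study advisories
        ds.validate()
    return ds, truth


def preset_prototypes(name: str) -> PrototypeSpec:
    """Named prototype specs mirroring qualitative contrasts between tissue
    settings: ``ra_like`` and ``uc_like`` have fewer samples, wider centroid
    spread and high cluster-frequency variation; ``tb_like`` has many
    samples and low frequency variation.  Numbers are illustrative, not
    calibrated to any real dataset's estimates.
    """
    presets = {
        "ra_like": PrototypeSpec(k=8, n_pcs=20, n_samples=20, n_batches=5,
                                 cells_per_sample=250, centroid_separation=12.0,
                                 batch_sd=0.8, sample_sd=0.5, logfreq_sd=0.8,
                                 seed=101),
        "tb_like": PrototypeSpec(k=12, n_pcs=20, n_samples=48, n_batches=12,
                                 cells_per_sample=400, centroid_separation=8.0,
                                 batch_sd=0.4, sample_sd=0.3, logfreq_sd=0.3,
                                 seed=102),
        "uc_like": PrototypeSpec(k=10, n_pcs=20, n_samples=30, n_batches=10,
                                 cells_per_sample=300, centroid_separation=12.0,
                                 batch_sd=0.6, sample_sd=0.5, logfreq_sd=0.8,
                                 seed=103),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return presets[name]
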