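"""Generation of multi-sample case-control datasets in PC space.

A simulated study is assembled sample by sample: each sample draws a
cluster-frequency profile from a log-normal model, case samples have a fold
change induced in a target cluster, cells are allocated to clusters by
deterministic largest-remainder rounding, and each cell's PC coordinates
are drawn from a multivariate normal around its cluster centroid shifted by
cluster-specific batch and sample effects:

    b_m ~ N(0, Sigma_B * b_scale)     (one per cluster x batch)
    s_d ~ N(0, Sigma_S * s_scale)     (one per cluster x sample)
    L   ~ N(mu + b_m + s_d, Sigma_C)

Setting a scale factor to 0 removes that source of variation exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import EstimatedParams, SimulatedDataset, StudyDesign

__all__ = [
    "distribute_samples",
    "distribute_sample_per_batch",
    "distribute_split_sample",
    "sample_cf_profiles",
    "induce_fold_change",
    "allocate_cells",
    "sample_shift",
    "sample_pc_coords",
    "simulate_dataset",
]

_PSD_TOL = 1e-8


def _batch_name(i: int) -> str:
    return f"batch{i:03d}"


def distribute_samples(case_ids, control_ids, n_batches: int) -> dict:
    """Round-robin samples into batches, balancing cases and controls.

    Cases are dealt round-robin over the batches first; controls continue
    the cycle, so batch sizes (and case/control composition) stay as even
    as the totals allow.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    n = len(case_ids) + len(control_ids)
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if n_batches > n:
        raise ValueError(f"cannot distribute {n} samples into {n_batches} batches")
    mapping = {}
    i = 0
    for s in case_ids:
        mapping[str(s)] = _batch_name(i % n_batches)
        i += 1
    for s in control_ids:
        mapping[str(s)] = _batch_name(i % n_batches)
        i += 1
    return mapping


def distribute_sample_per_batch(sample_ids) -> dict:
    """One batch per sample (sequential, non-multiplexed processing)."""
    return {str(s): _batch_name(i) for i, s in enumerate(sample_ids)}


def distribute_split_sample(sample_ids, n_subsamples: int, n_batches: int):
    """Split each sample into subsample units and spread them over batches.

    Emulates a multiplexed design: each sample is split into
    ``n_subsamples`` equal units, and units are placed so that a batch
    mixes units from distinct samples while no two units of the same
    sample share a batch.

    Returns
    -------
    (batch_map, parent_map) : unit id -> batch, unit id -> original sample.
    Unit ids are ``"<sample>.<j>"``.
    """
    sample_ids = [str(s) for s in sample_ids]
    if n_subsamples < 1:
        raise ValueError("n_subsamples must be >= 1")
    if n_subsamples > n_batches:
        raise ValueError(
            "a sample's units cannot land in distinct batches when "
            f"n_subsamples ({n_subsamples}) exceeds n_batches ({n_batches})")
    batch_map, parent_map = {}, {}
    for i, s in enumerate(sample_ids):
        for j in range(n_subsamples):
            unit = f"{s}.{j}" if n_subsamples > 1 else s
            batch_map[unit] = _batch_name((i + j) % n_batches)
            parent_map[unit] = s
    return batch_map, parent_map


def _check_psd(cov: np.ndarray, what: str) -> None:
    w = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if w.min() < -_PSD_TOL * max(1.0, abs(w.max())):
        raise ValueError(f"{what} is not positive semidefinite")


def sample_cf_profiles(mean_logfreq, logfreq_cov, cf_scale: float,
                       sample_ids, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one cluster-frequency profile per sample.

    Sampling happens in log space (so frequencies stay positive): profiles
    are ``exp(N(mean_logfreq, logfreq_cov * cf_scale))`` normalised to sum
    to 1.  With ``cf_scale = 0`` every sample receives the identical
    profile ``exp(mean_logfreq)`` normalised.

    Returns a DataFrame (samples x clusters, cluster order = vector order).
    """
    mu = np.asarray(mean_logfreq, dtype=float)
    cov = np.asarray(logfreq_cov, dtype=float) * float(cf_scale)
    sample_ids = [str(s) for s in sample_ids]
    if cf_scale < 0:
        raise ValueError("cf_scale must be >= 0")
    if cf_scale == 0:
        f = np.exp(mu)
        profiles = np.tile(f / f.sum(), (len(sample_ids), 1))
    else:
        _check_psd(cov, "scaled logfreq covariance")
        draws = rng.multivariate_normal(mu, cov, size=len(sample_ids),
                                        method="svd")
        f = np.exp(draws)
        profiles = f / f.sum(axis=1, keepdims=True)
    return pd.DataFrame(profiles, index=sample_ids)


def induce_fold_change(profile, target_index: int, fc: float) -> np.ndarray:
    """Scale one cluster's frequency by ``fc`` and renormalise the rest.

    The target frequency becomes ``min(fc * f, 1)``; the remaining clusters
    share the leftover probability mass in proportion to their prior
    frequencies.  When the cap fires with no mass left, the others are
    exactly 0.
    """
    p = np.asarray(profile, dtype=float).copy()
    if not 0 <= target_index < len(p):
        raise ValueError(f"unknown target cluster index {target_index}")
    if fc < 0:
        raise ValueError("fold change must be >= 0")
    new_t = min(fc * p[target_index], 1.0)
    rest_mass = 1.0 - new_t
    others = np.ones(len(p), dtype=bool)
    others[target_index] = False
    rest_sum = p[others].sum()
    if rest_sum > 0:
        p[others] = p[others] / rest_sum * rest_mass
    else:
        p[others] = 0.0
    p[target_index] = new_t
    return p


def allocate_cells(profile, n_cells: int) -> np.ndarray:
    """Deterministic largest-remainder allocation of ``n_cells`` to clusters.

    Counts are ``floor(profile * n_cells)`` with leftover cells given to
    the largest fractional remainders; ties break by cluster index order.
    """
    p = np.asarray(profile, dtype=float)
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    exact = p / p.sum() * n_cells
    base = np.floor(exact).astype(int)
    short = n_cells - base.sum()
    frac = exact - base
    order = np.argsort(-frac, kind="stable")
    base[order[:short]] += 1
    return base


def sample_shift(cov_diag, scale: float, rng: np.random.Generator) -> np.ndarray:
    """One linear shift draw ~ N(0, diag(cov_diag) * scale); exact zero at scale 0."""
    d = np.asarray(cov_diag, dtype=float)
    if np.any(d < 0):
        raise ValueError("covariance diagonal must be >= 0")
    if scale == 0:
        return np.zeros_like(d)
    return rng.normal(0.0, np.sqrt(d * scale))


def sample_pc_coords(mu, shift_batch, shift_sample, residual_cov,
                     n_cells: int, rng: np.random.Generator,
                     chol: np.ndarray | None = None) -> np.ndarray:
    """Draw ``n_cells`` PC coordinate rows ~ N(mu + b_m + s_d, Sigma_C).

    ``chol`` optionally supplies a precomputed factor of ``residual_cov``
    (as returned by :func:`_cov_factor`) to avoid refactorising per call.
    """
    mu = np.asarray(mu, dtype=float)
    centre = mu + np.asarray(shift_batch, dtype=float) + np.asarray(shift_sample, dtype=float)
    if chol is None:
        chol = _cov_factor(np.asarray(residual_cov, dtype=float))
    z = rng.standard_normal((n_cells, len(mu)))
    return centre[None, :] + z @ chol.T


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """A factor A with A A' = cov, tolerant of PSD-singular matrices."""
    cov = (cov + cov.T) / 2.0
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        if w.min() < -_PSD_TOL * max(1.0, abs(w.max())):
            raise ValueError("residual covariance is not positive semidefinite")
        return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_dataset(params: EstimatedParams, design: StudyDesign,
                     rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Generate one study: frequencies, fold change, allocation, coordinates.

    Randomness is split into independent sub-streams (target choice,
    frequency profiles, batch shifts, sample shifts, coordinates) derived
    from ``design.seed`` (or the supplied generator), so each stage's draws
    are stable under changes to the others.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(design.seed)
    streams = rng.spawn(5)
    rng_target, rng_freq, rng_bshift, rng_sshift, rng_coord = streams

    labels = params.cluster_labels
    k = params.k
    case_ids, control_ids = design.case_ids(), design.control_ids()
    sample_ids = case_ids + control_ids
    batch_map = design.batch_map or distribute_samples(
        case_ids, control_ids, design.n_batches)
    missing = set(sample_ids) - set(batch_map)
    if missing:
        raise ValueError(f"batch_map misses samples: {sorted(missing)[:3]}")
    batches = sorted(set(batch_map.values()))

    if design.target_cluster == "random":
        target = labels[int(rng_target.integers(k))]
    else:
        target = str(design.target_cluster)
        if target not in labels:
            raise ValueError(f"unknown target cluster {target!r}")
    t_idx = labels.index(target)

    profiles = sample_cf_profiles(params.mean_logfreq, params.logfreq_cov,
                                  design.cf_scale, sample_ids, rng_freq)
    prof = profiles.to_numpy()
    for i, s in enumerate(sample_ids):
        if s in case_ids:
            prof[i] = induce_fold_change(prof[i], t_idx, design.fold_change)

    # cluster-specific shifts per batch and per sample
    bshift = {(c, b): sample_shift(params.batch_var[ci], design.b_scale, rng_bshift)
              for ci, c in enumerate(labels) for b in batches}
    sshift = {(c, s): sample_shift(params.sample_var[ci], design.s_scale, rng_sshift)
              for ci, c in enumerate(labels) for s in sample_ids}
    chols = [_cov_factor(params.residual_cov[ci]) for ci in range(k)]

    emb_parts, cell_ids, conds, samps, bats, origins = [], [], [], [], [], []
    cell_counter = 0
    for i, s in enumerate(sample_ids):
        cond = "case" if s in set(case_ids) else "control"
        b = batch_map[s]
        counts = allocate_cells(prof[i], design.cells_per_sample)
        for ci, c in enumerate(labels):
            m = int(counts[ci])
            if m == 0:
                continue
            coords = sample_pc_coords(
                params.centroids[ci], bshift[(c, b)], sshift[(c, s)],
                params.residual_cov[ci], m, rng_coord, chol=chols[ci])
            emb_parts.append(coords)
            cell_ids.extend(f"cell{cell_counter + j:06d}" for j in range(m))
            cell_counter += m
            conds.extend([cond] * m)
            samps.extend([s] * m)
            bats.extend([b] * m)
            origins.extend([c] * m)

    ds = SimulatedDataset(
        embeddings=np.vstack(emb_parts),
        cell_ids=np.array(cell_ids, dtype=object),
        conditions=np.array(conds, dtype=object),
        samples=np.array(samps, dtype=object),
        batches=np.array(bats, dtype=object),
        origin_clusters=np.array(origins, dtype=object),
        target_cluster=target,
    )
    return ds.validate()
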