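"""Core containers and tabular/JSON readers and writers.

All stages of the pipeline exchange data through the types defined here:
a prototype dataset (observed PC embeddings plus per-cell metadata), the
parameters estimated from it, a study design, a simulated dataset, and a
power report.  Embeddings travel as dense ``cells x nPC`` arrays; metadata
as parallel per-cell label arrays.  On disk everything is CSV/TSV keyed by
an explicit cell-ID column, so row order never matters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PrototypeDataset",
    "EstimatedParams",
    "LMMFit",
    "StudyDesign",
    "SimulatedDataset",
    "PowerReport",
    "ValidationError",
    "read_prototype",
    "write_simulated",
    "read_simulated",
]

#: recommended minimum study size before estimates become unstable
MIN_SAMPLES_RECOMMENDED = 6
MIN_CELLS_PER_SAMPLE_RECOMMENDED = 500


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


def _as_str_array(values: Sequence) -> np.ndarray:
    return np.asarray([str(v) for v in values], dtype=object)


def _check_sample_batch_consistency(samples: np.ndarray, batches: np.ndarray) -> dict:
    """Every sample must map to exactly one batch; returns the sample->batch map."""
    mapping: dict = {}
    for s, b in zip(samples, batches):
        if s in mapping and mapping[s] != b:
            raise ValidationError(
                f"sample {s!r} is mapped to more than one batch ({mapping[s]!r}, {b!r})"
            )
        mapping[s] = b
    return mapping


@dataclass
class PrototypeDataset:
    """Observed single-cell dataset used for parameter estimation.

    Parameters
    ----------
    embeddings : ndarray of shape (n_cells, n_pcs)
        PC coordinates, one row per cell.
    cell_ids : array of str
        Unique cell identifiers, aligned with ``embeddings`` rows.
    samples, batches, clusters : array of str
        Per-cell sample ID, batch ID and cluster label.
    """

    embeddings: np.ndarray
    cell_ids: np.ndarray
    samples: np.ndarray
    batches: np.ndarray
    clusters: np.ndarray

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.samples = _as_str_array(self.samples)
        self.batches = _as_str_array(self.batches)
        self.clusters = _as_str_array(self.clusters)

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.embeddings.shape[0]

    @property
    def n_pcs(self) -> int:
        return self.embeddings.shape[1]

    @property
    def cluster_labels(self) -> list:
        """Distinct cluster labels in sorted order (defines vector positions)."""
        return sorted(set(self.clusters))

    @property
    def sample_ids(self) -> list:
        return sorted(set(self.samples))

    @property
    def batch_map(self) -> dict:
        return _check_sample_batch_consistency(self.samples, self.batches)

    def validate(self) -> "PrototypeDataset":
        n = self.n_cells
        if self.embeddings.ndim != 2 or self.n_pcs < 2:
            raise ValidationError("embeddings must be 2-D with at least 2 PCs")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValidationError("embeddings contain non-finite values")
        for name, arr in (
            ("cell_ids", self.cell_ids),
            ("samples", self.samples),
            ("batches", self.batches),
            ("clusters", self.clusters),
        ):
            if len(arr) != n:
                raise ValidationError(f"{name} has length {len(arr)}, expected {n}")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell_ids are not unique")
        if len(self.cluster_labels) < 2:
            raise ValidationError("need at least 2 distinct cluster labels")
        _check_sample_batch_consistency(self.samples, self.batches)
        self._warn_small_study()
        return self

    def _warn_small_study(self) -> None:
        counts = pd.Series(self.samples).value_counts()
        if len(counts) < MIN_SAMPLES_RECOMMENDED:
            warnings.warn(
                f"only {len(counts)} samples present; at least "
                f"{MIN_SAMPLES_RECOMMENDED} are recommended for stable estimates",
                UserWarning,
                stacklevel=3,
            )
        small = counts[counts < MIN_CELLS_PER_SAMPLE_RECOMMENDED]
        if len(small):
            warnings.warn(
                f"{len(small)} sample(s) have fewer than "
                f"{MIN_CELLS_PER_SAMPLE_RECOMMENDED} cells "
                f"(smallest: {int(counts.min())})",
                UserWarning,
                stacklevel=3,
            )


@dataclass
class LMMFit:
    """Result of a linear mixed model with batch and sample random intercepts."""

    intercept: float
    tau2_batch: float
    tau2_sample: float
    sigma2: float
    residuals: np.ndarray
    loglik: float
    singular: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if not (np.isfinite(self.tau2_batch) and self.tau2_batch >= 0):
            raise ValidationError("tau2_batch must be finite and >= 0")
        if not (np.isfinite(self.tau2_sample) and self.tau2_sample >= 0):
            raise ValidationError("tau2_sample must be finite and >= 0")


@dataclass
class EstimatedParams:
    """Per-cluster PC-space parameters plus global cluster-frequency parameters.

    ``cluster_labels`` fixes the index order of every array: row ``i`` of
    ``centroids`` / ``batch_var`` / ``sample_var`` / ``residual_cov`` and
    position ``i`` of ``mean_logfreq`` all refer to ``cluster_labels[i]``.

    Attributes
    ----------
    centroids : (k, n_pcs) cluster centroids in PC space.
    batch_var, sample_var : (k, n_pcs) diagonals of the (diagonal) batch and
        sample covariance matrices.
    residual_cov : (k, n_pcs, n_pcs) full residual covariance per cluster.
    mean_logfreq : (k,) natural log of mean cluster proportions.
    logfreq_cov : (k, k) covariance of per-sample log proportions.
    """

    cluster_labels: list
    centroids: np.ndarray
    batch_var: np.ndarray
    sample_var: np.ndarray
    residual_cov: np.ndarray
    mean_logfreq: np.ndarray
    logfreq_cov: np.ndarray

    def __post_init__(self) -> None:
        self.cluster_labels = [str(c) for c in self.cluster_labels]
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.batch_var = np.asarray(self.batch_var, dtype=float)
        self.sample_var = np.asarray(self.sample_var, dtype=float)
        self.residual_cov = np.asarray(self.residual_cov, dtype=float)
        self.mean_logfreq = np.asarray(self.mean_logfreq, dtype=float)
        self.logfreq_cov = np.asarray(self.logfreq_cov, dtype=float)

    @property
    def k(self) -> int:
        return len(self.cluster_labels)

    @property
    def n_pcs(self) -> int:
        return self.centroids.shape[1]

    def cluster_index(self, label) -> int:
        return self.cluster_labels.index(str(label))

    def validate(self, psd_tol: float = 1e-8) -> "EstimatedParams":
        k, d = self.k, self.n_pcs
        if self.centroids.shape != (k, d):
            raise ValidationError("centroids shape mismatch")
        for name, arr in (("batch_var", self.batch_var), ("sample_var", self.sample_var)):
            if arr.shape != (k, d):
                raise ValidationError(f"{name} shape mismatch")
            if np.any(arr < -psd_tol):
                raise ValidationError(f"{name} has negative entries")
        if self.residual_cov.shape != (k, d, d):
            raise ValidationError("residual_cov shape mismatch")
        for i in range(k):
            _check_psd(self.residual_cov[i], f"residual_cov[{self.cluster_labels[i]}]", psd_tol)
        if self.mean_logfreq.shape != (k,):
            raise ValidationError("mean_logfreq shape mismatch")
        if self.logfreq_cov.shape != (k, k):
            raise ValidationError("logfreq_cov shape mismatch")
        _check_psd(self.logfreq_cov, "logfreq_cov", psd_tol)
        return self

    # -- JSON round-trip ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cluster_labels": self.cluster_labels,
            "centroids": self.centroids.tolist(),
            "batch_var": self.batch_var.tolist(),
            "sample_var": self.sample_var.tolist(),
            "residual_cov": self.residual_cov.tolist(),
            "mean_logfreq": self.mean_logfreq.tolist(),
            "logfreq_cov": self.logfreq_cov.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EstimatedParams":
        return cls(**{key: d[key] for key in (
            "cluster_labels", "centroids", "batch_var", "sample_var",
            "residual_cov", "mean_logfreq", "logfreq_cov",
        )})

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "EstimatedParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_psd(mat: np.ndarray, name: str, tol: float) -> None:
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValidationError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh((mat + mat.T) / 2.0)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ValidationError(f"{name} is not positive semidefinite (min eig {w.min():g})")


@dataclass
class StudyDesign:
    """Layout of a simulated case-control study.

    ``b_scale``, ``s_scale`` and ``cf_scale`` multiply the estimated batch,
    sample and cluster-frequency covariances; 0 switches the corresponding
    source of variation off entirely.  ``fold_change`` is the multiplicative
    expansion induced in the target cluster of case samples;
    ``target_cluster`` may be a concrete label or ``"random"``.
    """

    n_case: int
    n_control: int
    cells_per_sample: int = 500
    n_batches: int = 1
    batch_map: dict | None = None
    b_scale: float = 1.0
    s_scale: float = 1.0
    cf_scale: float = 1.0
    fold_change: float = 1.0
    target_cluster: str = "random"
    resolution: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0 or self.n_case + self.n_control < 1:
            raise ValidationError("need at least one sample")
        if self.cells_per_sample < 1:
            raise ValidationError("cells_per_sample must be >= 1")
        for name in ("b_scale", "s_scale", "cf_scale", "fold_change"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control

    def case_ids(self) -> list:
        return [f"case{i:03d}" for i in range(self.n_case)]

    def control_ids(self) -> list:
        return [f"ctrl{i:03d}" for i in range(self.n_control)]

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_case", "n_control", "cells_per_sample", "n_batches",
            "b_scale", "s_scale", "cf_scale", "fold_change",
            "target_cluster", "resolution", "seed")}
        d["batch_map"] = self.batch_map
        return d


@dataclass
class SimulatedDataset:
    """A generated dataset: PC coordinates plus per-cell labels.

    ``origin_clusters`` are the generating cluster identities;
    ``new_clusters`` (optional) are labels obtained by re-clustering the
    simulated coordinates.  ``target_cluster`` records which origin cluster
    had the fold change induced (the causal cluster).
    """

    embeddings: np.ndarray
    cell_ids: np.ndarray
    conditions: np.ndarray
    samples: np.ndarray
    batches: np.ndarray
    origin_clusters: np.ndarray
    new_clusters: np.ndarray | None = None
    target_cluster: str | None = None

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.conditions = _as_str_array(self.conditions)
        self.samples = _as_str_array(self.samples)
        self.batches = _as_str_array(self.batches)
        self.origin_clusters = _as_str_array(self.origin_clusters)
        if self.new_clusters is not None:
            self.new_clusters = _as_str_array(self.new_clusters)

    @property
    def n_cells(self) -> int:
        return self.embeddings.shape[0]

    @property
    def n_pcs(self) -> int:
        return self.embeddings.shape[1]

    def validate(self) -> "SimulatedDataset":
        n = self.n_cells
        if n == 0:
            raise ValidationError("dataset is empty")
        arrays = [self.cell_ids, self.conditions, self.samples, self.batches,
                  self.origin_clusters]
        if self.new_clusters is not None:
            arrays.append(self.new_clusters)
        if any(len(a) != n for a in arrays):
            raise ValidationError("metadata length mismatch")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell_ids are not unique")
        # condition must be constant within sample
        df = pd.DataFrame({"sample": self.samples, "cond": self.conditions})
        if (df.groupby("sample")["cond"].nunique() > 1).any():
            raise ValidationError("condition varies within a sample")
        _check_sample_batch_consistency(self.samples, self.batches)
        return self


@dataclass
class PowerReport:
    """Aggregate of a Monte-Carlo power study.

    ``simulations`` holds one record per simulation with keys
    ``p_values`` (cluster label -> p), ``n_clusters``, ``detected``,
    ``interpretability`` and ``target_cluster``.
    """

    simulations: list = field(default_factory=list)
    power: float = 0.0
    ci_low: float = 0.0
    ci_high: float = 0.0
    config: dict = field(default_factory=dict)

    def validate(self) -> "PowerReport":
        if not (0.0 <= self.power <= 1.0):
            raise ValidationError("power outside [0, 1]")
        if not (self.ci_low <= self.power <= self.ci_high):
            raise ValidationError("power outside its confidence interval")
        return self

    def to_dict(self) -> dict:
        return {
            "power": self.power,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_simulations": len(self.simulations),
            "config": self.config,
            "simulations": self.simulations,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

_META_COLUMNS = ("cell", "sample", "batch", "cluster")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype={"cell": str})


def _write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df.to_csv(path, sep=sep, index=False)


def read_prototype(embeddings_path, metadata_path) -> PrototypeDataset:
    """Load a prototype dataset from an embeddings table and a metadata table.

    The embeddings table needs a ``cell`` column plus one numeric column per
    PC; the metadata table needs ``cell``, ``sample``, ``batch`` and
    ``cluster`` columns.  Rows are joined on ``cell``, so the two files may
    be ordered differently.
    """
    emb = _read_table(embeddings_path)
    meta = _read_table(metadata_path)
    for col in _META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    if "cell" not in emb.columns:
        raise ValueError("embeddings table is missing the 'cell' column")
    emb_cells = set(emb["cell"])
    meta_cells = set(meta["cell"].astype(str))
    if emb_cells != meta_cells:
        missing = (emb_cells ^ meta_cells)
        raise ValueError(
            f"cell sets of embeddings and metadata differ ({len(missing)} "
            f"mismatched ids, e.g. {sorted(missing)[:3]})"
        )
    meta = meta.set_index(meta["cell"].astype(str)).loc[emb["cell"].astype(str)]
    pc_cols = [c for c in emb.columns if c != "cell"]
    ds = PrototypeDataset(
        embeddings=emb[pc_cols].to_numpy(dtype=float),
        cell_ids=emb["cell"].to_numpy(),
        samples=meta["sample"].to_numpy(),
        batches=meta["batch"].to_numpy(),
        clusters=meta["cluster"].to_numpy(),
    )
    return ds.validate()


def write_simulated(dataset: SimulatedDataset, out_dir) -> tuple:
    """Write a simulated dataset as ``embeddings.tsv`` + ``meta.tsv``.

    Returns the two paths written.
    """
    dataset.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    emb_path = out_dir / "embeddings.tsv"
    meta_path = out_dir / "meta.tsv"
    emb = pd.DataFrame(
        dataset.embeddings,
        columns=[f"PC{i + 1}" for i in range(dataset.n_pcs)],
    )
    emb.insert(0, "cell", dataset.cell_ids)
    meta = pd.DataFrame({
        "cell": dataset.cell_ids,
        "sample": dataset.samples,
        "batch": dataset.batches,
        "cluster": (dataset.new_clusters if dataset.new_clusters is not None
                    else dataset.origin_clusters),
        "condition": dataset.conditions,
        "origin_cluster": dataset.origin_clusters,
    })
    _write_table(emb, emb_path)
    _write_table(meta, meta_path)
    return emb_path, meta_path


def read_simulated(out_dir) -> SimulatedDataset:
    """Inverse of :func:`write_simulated` (up to float formatting)."""
    out_dir = Path(out_dir)
    emb = _read_table(out_dir / "embeddings.tsv")
    meta = _read_table(out_dir / "meta.tsv").set_index("cell", drop=False)
    meta = meta.loc[emb["cell"]]
    pc_cols = [c for c in emb.columns if c != "cell"]
    ds = SimulatedDataset(
        embeddings=emb[pc_cols].to_numpy(dtype=float),
        cell_ids=emb["cell"].to_numpy(),
        conditions=meta["condition"].to_numpy(),
        samples=meta["sample"].to_numpy(),
        batches=meta["batch"].to_numpy(),
        origin_clusters=meta["origin_cluster"].to_numpy(),
        new_clusters=meta["cluster"].to_numpy(),
    )
    return ds.validate()
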