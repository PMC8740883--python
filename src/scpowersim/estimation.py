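"""Variance-component estimation from a prototype dataset.

For every cluster and every PC we fit the linear mixed model

    PC ~ 1 + (1 | batch) + (1 | sample)

by REML and read off the intercept (the cluster centroid coordinate), the
two random-intercept variances (batch- and sample-associated variation) and
the per-cell residuals.  Per cluster, the batch and sample variances across
PCs form the diagonals of the batch/sample covariance matrices, and the
empirical covariance of the residual matrix gives the full residual
covariance in PC space.  Cluster-frequency variation across samples is
summarised by the log of the mean pseudo-counted proportions and the
covariance of per-sample log proportions.

The REML solver exploits the crossed-intercepts structure: with q random
levels (batches + samples) every likelihood evaluation reduces to dense
q x q linear algebra via the Woodbury identity, independent of the number
of cells, so fitting k x nPC models is cheap even for large prototypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .data_model import EstimatedParams, LMMFit, PrototypeDataset

__all__ = [
    "fit_two_random_intercepts",
    "estimate_pc_params",
    "estimate_freq_params",
    "estimate_params",
]

_LOG2PI = math.log(2.0 * math.pi)
# log-variance-ratio bounds for the optimiser; exp(-14) is numerically zero
_LOG_G_LO, _LOG_G_HI = -14.0, 10.0
_SNAP = 1e-6  # gamma below this is treated as a boundary (singular) fit


def _codes(labels) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(labels))
    return codes.astype(np.intp), len(uniques)


@dataclass
class _REMLResult:
    beta: float
    gamma_b: float  # tau2_batch / sigma2
    gamma_s: float
    sigma2: float
    neg2_reml: float
    residuals: np.ndarray


class _CrossedREML:
    """REML machinery for y = 1*beta + Zb ub + Zs us + eps with given grouping.

    Either random effect may be disabled (``use_batch`` / ``use_sample``),
    which removes its indicator block entirely.
    """

    def __init__(self, batch_codes, n_batch, sample_codes, n_sample,
                 use_batch=True, use_sample=True):
        self.bc, self.sc = batch_codes, sample_codes
        self.use_batch, self.use_sample = use_batch, use_sample
        self.n = len(batch_codes)
        nb = np.bincount(batch_codes, minlength=n_batch).astype(float)
        ns = np.bincount(sample_codes, minlength=n_sample).astype(float)
        cross = np.zeros((n_batch, n_sample))
        np.add.at(cross, (batch_codes, sample_codes), 1.0)
        blocks = []
        if use_batch:
            blocks.append(("b", nb))
        if use_sample:
            blocks.append(("s", ns))
        self.qb = n_batch if use_batch else 0
        self.qs = n_sample if use_sample else 0
        q = self.qb + self.qs
        self.q = q
        C = np.zeros((q, q))
        if use_batch:
            C[:self.qb, :self.qb] = np.diag(nb)
        if use_sample:
            C[self.qb:, self.qb:] = np.diag(ns)
        if use_batch and use_sample:
            C[:self.qb, self.qb:] = cross
            C[self.qb:, :self.qb] = cross.T
        self.C = C
        self.w = self._zt(np.ones(self.n))  # Z'1

    def _zt(self, v: np.ndarray) -> np.ndarray:
        """Z' v for the active indicator blocks."""
        parts = []
        if self.use_batch:
            parts.append(np.bincount(self.bc, weights=v, minlength=self.qb))
        if self.use_sample:
            parts.append(np.bincount(self.sc, weights=v, minlength=self.qs))
        return np.concatenate(parts) if parts else np.zeros(0)

    def _gvec(self, gamma_b: float, gamma_s: float) -> np.ndarray:
        parts = []
        if self.use_batch:
            parts.append(np.full(self.qb, gamma_b))
        if self.use_sample:
            parts.append(np.full(self.qs, gamma_s))
        return np.concatenate(parts) if parts else np.zeros(0)

    def set_response(self, y: np.ndarray) -> None:
        self.y = np.asarray(y, dtype=float)
        self.u = self._zt(self.y)
        self.yty = float(self.y @ self.y)
        self.s1y = float(self.y.sum())

    def _core(self, gamma_b: float, gamma_s: float):
        g = self._gvec(gamma_b, gamma_s)
        G = np.sqrt(g)
        M = np.eye(self.q) + (G[:, None] * self.C) * G[None, :]
        L = cho_factor(M, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L[0])))
        Gw, Gu = G * self.w, G * self.u
        Mi_Gw = cho_solve(L, Gw)
        Mi_Gu = cho_solve(L, Gu)
        a11 = self.n - Gw @ Mi_Gw          # 1' V0^-1 1
        a1y = self.s1y - Gw @ Mi_Gu        # 1' V0^-1 y
        ayy = self.yty - Gu @ Mi_Gu        # y' V0^-1 y
        return g, G, L, logdet, a11, a1y, ayy

    def neg2_reml(self, gamma_b: float, gamma_s: float) -> float:
        _, _, _, logdet, a11, a1y, ayy = self._core(gamma_b, gamma_s)
        quad = max(ayy - a1y * a1y / a11, 1e-300)
        sigma2 = quad / (self.n - 1)
        return ((self.n - 1) * (1.0 + math.log(sigma2) + _LOG2PI)
                + logdet + math.log(a11))

    def solve(self, gamma_b: float, gamma_s: float) -> _REMLResult:
        g, G, L, logdet, a11, a1y, ayy = self._core(gamma_b, gamma_s)
        beta = a1y / a11
        quad = max(ayy - a1y * a1y / a11, 0.0)
        sigma2 = quad / (self.n - 1)
        neg2 = ((self.n - 1) * (1.0 + math.log(max(sigma2, 1e-300)) + _LOG2PI)
                + logdet + math.log(a11))
        r = self.y - beta
        t = self.u - beta * self.w          # Z' r
        blup = g * (t - self.C @ (G * cho_solve(L, G * t)))
        eps = r.copy()
        if self.use_batch:
            eps -= blup[:self.qb][self.bc]
        if self.use_sample:
            eps -= blup[self.qb:][self.sc]
        return _REMLResult(beta=float(beta),
                           gamma_b=gamma_b if self.use_batch else 0.0,
                           gamma_s=gamma_s if self.use_sample else 0.0,
                           sigma2=float(sigma2), neg2_reml=float(neg2),
                           residuals=eps)


def _fit_reml(solver: _CrossedREML) -> _REMLResult:
    """Minimise the REML criterion over the active variance ratios."""
    use_b, use_s = solver.use_batch, solver.use_sample

    def obj(logg):
        i = 0
        gb = gs = 0.0
        if use_b:
            gb = math.exp(min(logg[i], _LOG_G_HI)); i += 1
        if use_s:
            gs = math.exp(min(logg[i], _LOG_G_HI))
        return solver.neg2_reml(gb, gs)

    n_active = int(use_b) + int(use_s)
    if n_active == 0:
        return solver.solve(0.0, 0.0)
    best = None
    starts = [np.full(n_active, v) for v in (-2.0, 0.0)]
    for x0 in starts:
        res = optimize.minimize(
            obj, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    x = np.clip(best.x, _LOG_G_LO, _LOG_G_HI)
    i = 0
    gb = gs = 0.0
    if use_b:
        gb = math.exp(x[i]); i += 1
    if use_s:
        gs = math.exp(x[i])
    # snap boundary solutions to exact zero
    if use_b and gb < _SNAP:
        gb = 0.0
    if use_s and gs < _SNAP:
        gs = 0.0
    return solver.solve(gb, gs)


def fit_two_random_intercepts(y, batch_of, sample_of) -> LMMFit:
    """REML fit of ``y ~ 1 + (1 | batch) + (1 | sample)``.

    Falls back gracefully when a grouping factor has a single level: the
    corresponding random effect is dropped and its variance reported as 0
    (recorded in ``note``).  A constant response returns the degenerate
    zero-variance fit.

    Parameters
    ----------
    y : array-like, per-cell response (one PC).
    batch_of, sample_of : array-like, per-cell group labels.

    Returns
    -------
    LMMFit with ``tau2_batch = sigma2 * gamma_b`` etc. on the response scale.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("need at least 2 observations")
    bc, n_b = _codes(batch_of)
    sc, n_s = _codes(sample_of)
    if len(bc) != len(y) or len(sc) != len(y):
        raise ValueError("batch/sample labels must align with y")

    if np.ptp(y) == 0.0:
        return LMMFit(intercept=float(y[0]), tau2_batch=0.0, tau2_sample=0.0,
                      sigma2=0.0, residuals=np.zeros_like(y),
                      loglik=float("nan"), singular=True, note="constant response")

    notes = []
    use_b, use_s = n_b >= 2, n_s >= 2
    if not use_b:
        notes.append("single batch: batch effect dropped")
    if not use_s:
        notes.append("single sample: sample effect dropped")

    solver = _CrossedREML(bc, n_b, sc, n_s, use_batch=use_b, use_sample=use_s)
    solver.set_response(y)
    res = _fit_reml(solver)
    singular = ((use_b and res.gamma_b == 0.0) or (use_s and res.gamma_s == 0.0)
                or not (use_b and use_s))
    if singular and (use_b or use_s):
        notes.append("variance estimate on boundary" if (use_b and use_s)
                     else notes[-1] if notes else "")
    return LMMFit(
        intercept=res.beta,
        tau2_batch=res.sigma2 * res.gamma_b,
        tau2_sample=res.sigma2 * res.gamma_s,
        sigma2=res.sigma2,
        residuals=res.residuals,
        loglik=-0.5 * res.neg2_reml,
        singular=singular,
        note="; ".join(n for n in notes if n),
    )


def estimate_pc_params(data: PrototypeDataset, n_pc: int | None = None):
    """Per-cluster centroids and batch/sample/residual covariances.

    Fits ``k x n_pc`` mixed models (one per cluster per PC).  Returns a dict
    keyed by cluster label with entries ``centroid`` (n_pc,), ``batch_var``
    and ``sample_var`` (diagonals, n_pc,), and ``residual_cov``
    (n_pc x n_pc).
    """
    if n_pc is None:
        n_pc = data.n_pcs
    if n_pc > data.n_pcs:
        raise ValueError(f"n_pc={n_pc} exceeds available PCs ({data.n_pcs})")
    out = {}
    for label in data.cluster_labels:
        mask = data.clusters == label
        n_cells = int(mask.sum())
        if n_cells < 2:
            raise ValueError(
                f"cluster {label!r} has {n_cells} cell(s); need at least 2")
        bc, n_b = _codes(data.batches[mask])
        sc, n_s = _codes(data.samples[mask])
        solver = _CrossedREML(bc, n_b, sc, n_s,
                              use_batch=n_b >= 2, use_sample=n_s >= 2)
        centroid = np.zeros(n_pc)
        bvar = np.zeros(n_pc)
        svar = np.zeros(n_pc)
        resid = np.zeros((n_cells, n_pc))
        emb = data.embeddings[mask]
        for j in range(n_pc):
            y = emb[:, j]
            if np.ptp(y) == 0.0:
                centroid[j] = y[0]
                continue
            solver.set_response(y)
            res = _fit_reml(solver)
            centroid[j] = res.beta
            bvar[j] = res.sigma2 * res.gamma_b
            svar[j] = res.sigma2 * res.gamma_s
            resid[:, j] = res.residuals
        rc = np.cov(resid, rowvar=False) if n_cells > 1 else np.zeros((n_pc, n_pc))
        rc = np.atleast_2d(rc)
        out[label] = {
            "centroid": centroid,
            "batch_var": bvar,
            "sample_var": svar,
            "residual_cov": (rc + rc.T) / 2.0,
        }
    return out


def estimate_freq_params(data: PrototypeDataset):
    """Cluster-frequency mean and covariance across samples, in log space.

    Per sample, cluster counts are incremented by a pseudo-count of 1 (so a
    cluster absent from a sample still gets positive mass) and normalised to
    proportions.  Returns ``(mean_logfreq, logfreq_cov)`` ordered by sorted
    cluster label: the natural log of the across-sample mean proportions,
    and the unbiased covariance of the per-sample log proportions.
    """
    samples = data.sample_ids
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to estimate frequency covariance")
    labels = data.cluster_labels
    counts = pd.crosstab(pd.Series(data.samples, name="sample"),
                         pd.Series(data.clusters, name="cluster"))
    counts = counts.reindex(index=samples, columns=labels, fill_value=0)
    inc = counts.to_numpy(dtype=float) + 1.0
    props = inc / inc.sum(axis=1, keepdims=True)
    mean_logfreq = np.log(props.mean(axis=0))
    logp = np.log(props)
    logfreq_cov = np.cov(logp, rowvar=False, ddof=1)
    logfreq_cov = np.atleast_2d(logfreq_cov)
    return mean_logfreq, (logfreq_cov + logfreq_cov.T) / 2.0


def estimate_params(data: PrototypeDataset, n_pc: int | None = None) -> EstimatedParams:
    """Full parameter-estimation step: PC-space and frequency parameters."""
    pc = estimate_pc_params(data, n_pc=n_pc)
    mean_logfreq, logfreq_cov = estimate_freq_params(data)
    labels = data.cluster_labels
    return EstimatedParams(
        cluster_labels=labels,
        centroids=np.stack([pc[c]["centroid"] for c in labels]),
        batch_var=np.stack([pc[c]["batch_var"] for c in labels]),
        sample_var=np.stack([pc[c]["sample_var"] for c in labels]),
        residual_cov=np.stack([pc[c]["residual_cov"] for c in labels]),
        mean_logfreq=mean_logfreq,
        logfreq_cov=logfreq_cov,
    ).validate()
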