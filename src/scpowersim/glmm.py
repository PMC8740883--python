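"""Binomial logistic mixed models with crossed random intercepts.

Maximum-likelihood fitting via the Laplace approximation, matching the
behaviour of lme4's ``glmer`` at ``nAGQ = 1``: for a given set of fixed
effects and random-effect standard deviations, the random-effect modes are
found by penalised Newton iterations, and the marginal log-likelihood is

    log L(theta, beta) = f(beta, u_hat) - 0.5 * logdet(I + D Z'WZ)

where ``f`` is the penalised binomial log-likelihood at the mode of the
random effects ``u``, ``W`` the IRLS weight matrix there, and ``D`` the
random-effect covariance.  Both the variance parameters and the fixed
effects are part of the outer (derivative-free) optimisation, since the
log-determinant depends on ``beta`` through the weights.

Responses are binomial counts per row.  Because every covariate in the
differential-abundance test is constant within a (sample, batch) pair,
per-cell Bernoulli data collapse losslessly onto a handful of binomial
rows, which keeps each fit essentially instant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, gammaln

__all__ = ["GLMMFit", "fit_logistic_mixed"]

_ETA_CAP = 30.0
_LOG_SD_LO, _LOG_SD_HI = -6.0, 4.0


@dataclass
class GLMMFit:
    """A fitted binomial logistic mixed model."""

    beta: np.ndarray
    sigma_batch: float
    sigma_sample: float
    loglik: float
    converged: bool
    n_iter: int = 0
    log_sd_opt: np.ndarray | None = None  # outer optimum, reusable as x0

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik


class _Model:
    def __init__(self, y, m, X, batch_codes, n_batch, sample_codes, n_sample,
                 use_batch=True, use_sample=True):
        self.y = np.asarray(y, dtype=float)
        self.m = np.asarray(m, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.bc = np.asarray(batch_codes, dtype=np.intp)
        self.sc = np.asarray(sample_codes, dtype=np.intp)
        self.use_batch = use_batch and n_batch >= 2
        self.use_sample = use_sample and n_sample >= 2
        self.qb = n_batch if self.use_batch else 0
        self.qs = n_sample if self.use_sample else 0
        self.q = self.qb + self.qs
        self.p = self.X.shape[1]
        self.const = float(np.sum(gammaln(self.m + 1) - gammaln(self.y + 1)
                                  - gammaln(self.m - self.y + 1)))

    def _eta(self, offset, u):
        eta = offset
        if self.use_batch:
            eta = eta + u[:self.qb][self.bc]
        if self.use_sample:
            eta = eta + u[self.qb:][self.sc]
        return np.clip(eta, -_ETA_CAP, _ETA_CAP)

    def _dinv(self, sb2, ss2):
        parts = []
        if self.use_batch:
            parts.append(np.full(self.qb, 1.0 / sb2))
        if self.use_sample:
            parts.append(np.full(self.qs, 1.0 / ss2))
        return np.concatenate(parts) if parts else np.zeros(0)

    def _pen_loglik(self, offset, u, dinv):
        eta = self._eta(offset, u)
        ll = float(self.y @ eta - self.m @ np.logaddexp(0.0, eta)) + self.const
        return ll - 0.5 * float((u * dinv) @ u)

    def _zt(self, v):
        parts = []
        if self.use_batch:
            parts.append(np.bincount(self.bc, weights=v, minlength=self.qb))
        if self.use_sample:
            parts.append(np.bincount(self.sc, weights=v, minlength=self.qs))
        return np.concatenate(parts) if parts else np.zeros(0)

    def _huu(self, wt, dinv):
        """Z'WZ + D^-1 for the active random-effect blocks."""
        H = np.zeros((self.q, self.q))
        if self.use_batch:
            H[:self.qb, :self.qb] = np.diag(
                np.bincount(self.bc, weights=wt, minlength=self.qb))
        if self.use_sample:
            H[self.qb:, self.qb:] = np.diag(
                np.bincount(self.sc, weights=wt, minlength=self.qs))
        if self.use_batch and self.use_sample:
            cross = np.zeros((self.qb, self.qs))
            np.add.at(cross, (self.bc, self.sc), wt)
            H[:self.qb, self.qb:] = cross
            H[self.qb:, :self.qb] = cross.T
        H[np.diag_indices_from(H)] += dinv
        return H

    def _newton_u(self, offset, dinv, u0=None):
        """Penalised Newton over the random effects at fixed fixed effects."""
        u = np.zeros(self.q) if u0 is None else u0.copy()
        f = self._pen_loglik(offset, u, dinv)
        ok = False
        for it in range(100):
            eta = self._eta(offset, u)
            prob = expit(eta)
            wt = self.m * prob * (1.0 - prob)
            grad = self._zt(self.y - self.m * prob) - dinv * u
            H = self._huu(wt, dinv)
            try:
                step = cho_solve(cho_factor(H, lower=True), grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H + 1e-8 * np.eye(self.q), grad,
                                       rcond=None)[0]
            t = 1.0
            f_new = f
            for _ in range(40):
                u_new = u + t * step
                f_new = self._pen_loglik(offset, u_new, dinv)
                if f_new >= f - 1e-14:
                    break
                t *= 0.5
            moved = abs(f_new - f)
            u, f = u_new, f_new
            if moved < 1e-13 * (1.0 + abs(f)):
                ok = True
                break
        eta = self._eta(offset, u)
        prob = expit(eta)
        wt = self.m * prob * (1.0 - prob)
        return u, wt, f, ok, it + 1

    def laplace_loglik(self, beta, sb2, ss2, u0=None):
        """Laplace marginal log-likelihood at (beta, sigma^2's)."""
        offset = self.X @ np.atleast_1d(beta)
        if self.q == 0:
            eta = np.clip(offset, -_ETA_CAP, _ETA_CAP)
            ll = float(self.y @ eta - self.m @ np.logaddexp(0.0, eta)) + self.const
            return ll, np.zeros(0), True
        dinv = self._dinv(sb2, ss2)
        u, wt, f, ok, _ = self._newton_u(offset, dinv, u0=u0)
        H = self._huu(wt, dinv)
        d = 1.0 / dinv
        A = np.sqrt(d)[:, None] * (H - np.diag(dinv)) * np.sqrt(d)[None, :]
        A[np.diag_indices_from(A)] += 1.0
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf, u, False
        return f - 0.5 * logdet, u, ok


def _start_beta(model: _Model) -> np.ndarray:
    """Plain logistic-regression start for the fixed effects (few IRLS steps)."""
    beta = np.zeros(model.p)
    rate = (model.y.sum() + 0.5) / (model.m.sum() + 1.0)
    beta[0] = math.log(rate / (1.0 - rate))
    for _ in range(25):
        eta = np.clip(model.X @ beta, -_ETA_CAP, _ETA_CAP)
        prob = expit(eta)
        wt = model.m * prob * (1.0 - prob) + 1e-10
        grad = model.X.T @ (model.y - model.m * prob)
        H = model.X.T @ (model.X * wt[:, None]) + 1e-10 * np.eye(model.p)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def fit_logistic_mixed(y, m, X, batch_codes, n_batch, sample_codes, n_sample,
                       use_batch: bool = True, use_sample: bool = True,
                       x0: np.ndarray | None = None) -> GLMMFit:
    """Fit a binomial logistic mixed model with batch and sample intercepts.

    Parameters
    ----------
    y, m : arrays of successes and trials per row.
    X : fixed-effects design matrix (include the intercept column).
    batch_codes, sample_codes : integer group codes per row.
    use_batch, use_sample : drop a random effect entirely (also dropped
        automatically when the factor has fewer than 2 levels).
    x0 : optional start for the outer log-standard-deviation search (e.g.
        the optimum of a nested model).

    Returns
    -------
    GLMMFit with the ML (Laplace) log-likelihood; ``sigma_batch`` /
    ``sigma_sample`` are random-intercept standard deviations, 0 when the
    effect is absent or on the boundary.
    """
    model = _Model(y, m, X, batch_codes, n_batch, sample_codes, n_sample,
                   use_batch=use_batch, use_sample=use_sample)
    n_active = int(model.use_batch) + int(model.use_sample)
    beta0 = _start_beta(model)

    if n_active == 0:
        ll, _, ok = model.laplace_loglik(beta0, 1.0, 1.0)
        return GLMMFit(beta=beta0, sigma_batch=0.0, sigma_sample=0.0,
                       loglik=ll, converged=ok, log_sd_opt=np.zeros(0))

    state = {"u": None, "evals": 0}

    def unpack_sigma(x):
        x = np.clip(x, _LOG_SD_LO, _LOG_SD_HI)
        i = 0
        sb = ss = 0.0
        if model.use_batch:
            sb = math.exp(x[i]); i += 1
        if model.use_sample:
            ss = math.exp(x[i])
        return max(sb, 1e-8) ** 2, max(ss, 1e-8) ** 2

    def obj(z):
        sb2, ss2 = unpack_sigma(z[:n_active])
        beta = z[n_active:]
        ll, u, _ = model.laplace_loglik(beta, sb2, ss2, u0=state["u"])
        state["u"] = u
        state["evals"] += 1
        return -ll

    start = np.concatenate([
        np.asarray(x0, dtype=float) if x0 is not None
        else np.full(n_active, -0.7),
        beta0,
    ])
    res = optimize.minimize(
        obj, start, method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 600,
                 "adaptive": model.p + n_active > 3})
    z = res.x
    sb2, ss2 = unpack_sigma(z[:n_active])
    beta = z[n_active:]
    ll, _, ok = model.laplace_loglik(beta, sb2, ss2, u0=state["u"])
    sb, ss = math.sqrt(sb2), math.sqrt(ss2)
    # snap boundary estimates to zero
    if model.use_batch and sb < 1.5 * math.exp(_LOG_SD_LO):
        sb = 0.0
    if model.use_sample and ss < 1.5 * math.exp(_LOG_SD_LO):
        ss = 0.0
    return GLMMFit(beta=np.atleast_1d(beta),
                   sigma_batch=sb if model.use_batch else 0.0,
                   sigma_sample=ss if model.use_sample else 0.0,
                   loglik=float(ll), converged=bool(ok and res.success),
                   n_iter=state["evals"],
                   log_sd_opt=np.clip(z[:n_active], _LOG_SD_LO, _LOG_SD_HI).copy())
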