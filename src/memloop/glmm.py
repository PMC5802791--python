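"""Binomial logistic mixed model via the Laplace approximation.

The marginal likelihood of a logistic GLMM,

    L(beta, theta) = integral f(y | X beta + Z u) N(u; 0, D(theta)) du,

is approximated by Laplace's method at the joint penalized mode. Fitting
follows the classic two-level decomposition (as in lme4): an inner Newton
solve for the joint mode (beta_hat, u_hat) given the variance parameters,
and an outer derivative-free optimization over the low-dimensional vector of
log standard deviations. Random effects enter as independent blocks
(e.g. per-subject intercepts, per-subject condition slopes, per-site
intercepts and slopes), each with its own variance.

The Hessian of the joint problem is assembled from the indicator structure
of the grouping factors (bincount aggregation, O(n) per block pair), so an
inner Newton step costs O(n) plus one small dense solve.

Standard errors of the fixed effects come from the Schur complement of the
joint Hessian at the optimum, i.e. the observed information of the Laplace
objective profiled over the random effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

LOG_SD_BOUNDS = (-6.0, 2.0)  # sd in [~0.0025, ~7.4]; lower bound collapses a block


@dataclass
class RandomEffectBlock:
    """One variance component: indicator/covariate design for a grouping factor.

    ``codes[i]`` maps row i to a level (0..n_levels-1); ``covariate`` scales
    the indicator (1 for intercepts, the condition column for slopes).
    """

    name: str
    codes: np.ndarray
    n_levels: int
    covariate: Optional[np.ndarray] = None

    def values(self, n: int) -> np.ndarray:
        return np.ones(n) if self.covariate is None else np.asarray(self.covariate, float)


@dataclass
class GlmmFit:
    """Laplace-fitted logistic mixed model."""

    beta: np.ndarray
    beta_se: np.ndarray
    exog_names: list[str]
    block_names: list[str]
    block_sd: np.ndarray
    u: np.ndarray
    loglik_laplace: float
    n_obs: int
    converged: bool
    message: str = ""

    def coef(self, name: str) -> tuple[float, float]:
        i = self.exog_names.index(name)
        return float(self.beta[i]), float(self.beta_se[i])


def intercept_and_slope_blocks(
    frame: pd.DataFrame, factor: str, slope: str
) -> list[RandomEffectBlock]:
    """Random intercept + random slope blocks for one grouping factor."""
    codes, levels = pd.factorize(frame[factor])
    x = frame[slope].to_numpy(dtype=float)
    return [
        RandomEffectBlock(f"{factor}_intercept", codes.copy(), len(levels)),
        RandomEffectBlock(f"{factor}_slope", codes.copy(), len(levels), covariate=x),
    ]


class _Workspace:
    """Precomputed block structure for fast objective/gradient/Hessian."""

    def __init__(self, y: np.ndarray, X: np.ndarray, blocks: Sequence[RandomEffectBlock]):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.blocks = list(blocks)
        self.vals = [b.values(self.n) for b in blocks]
        self.codes = [np.asarray(b.codes, dtype=np.intp) for b in blocks]
        self.sizes = [b.n_levels for b in blocks]
        self.q = int(sum(self.sizes))
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)]).astype(int)
        # flattened pair keys for Z_j' W Z_k assembly
        self.pair_keys = {}
        for j in range(len(blocks)):
            for k in range(j, len(blocks)):
                self.pair_keys[(j, k)] = self.codes[j] * self.sizes[k] + self.codes[k]

    def eta(self, beta: np.ndarray, u: np.ndarray) -> np.ndarray:
        e = self.X @ beta
        for k, (c, v) in enumerate(zip(self.codes, self.vals)):
            uk = u[self.offsets[k]:self.offsets[k + 1]]
            e = e + v * uk[c]
        return e

    def grad(self, resid: np.ndarray, pen: np.ndarray, theta: np.ndarray) -> np.ndarray:
        g = np.empty(self.p + self.q)
        g[:self.p] = self.X.T @ resid
        for k, (c, v) in enumerate(zip(self.codes, self.vals)):
            g[self.p + self.offsets[k]:self.p + self.offsets[k + 1]] = np.bincount(
                c, resid * v, minlength=self.sizes[k]
            )
        return g - pen * theta

    def hessian(self, w: np.ndarray, pen: np.ndarray) -> np.ndarray:
        p, q = self.p, self.q
        H = np.zeros((p + q, p + q))
        Xw = self.X * w[:, None]
        H[:p, :p] = Xw.T @ self.X
        for k, (c, v) in enumerate(zip(self.codes, self.vals)):
            sl = slice(p + self.offsets[k], p + self.offsets[k + 1])
            wv = w * v
            for a in range(p):
                H[a, sl] = np.bincount(c, self.X[:, a] * wv, minlength=self.sizes[k])
            H[sl, :p] = H[:p, sl].T
        for (j, k), key in self.pair_keys.items():
            vals = w * self.vals[j] * self.vals[k]
            blockjk = np.bincount(
                key, vals, minlength=self.sizes[j] * self.sizes[k]
            ).reshape(self.sizes[j], self.sizes[k])
            slj = slice(p + self.offsets[j], p + self.offsets[j + 1])
            slk = slice(p + self.offsets[k], p + self.offsets[k + 1])
            H[slj, slk] += blockjk
            if j != k:
                H[slk, slj] += blockjk.T
        H[np.arange(p + q), np.arange(p + q)] += pen
        return H


def fit_logistic_glmm(
    y: np.ndarray,
    X: np.ndarray,
    blocks: Sequence[RandomEffectBlock],
    exog_names: Optional[list[str]] = None,
    fixed_log_sd: Optional[np.ndarray] = None,
    xatol: float = 1e-3,
) -> GlmmFit:
    """Maximize the Laplace-approximate marginal likelihood.

    ``fixed_log_sd`` pins the variance parameters (useful for constraining
    random effects toward zero, which collapses the model to ordinary
    logistic regression).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    ws = _Workspace(y, X, blocks)
    p, q = ws.p, ws.q

    def dinv_diag(log_sd: np.ndarray) -> np.ndarray:
        if not q:
            return np.zeros(0)
        return np.concatenate([
            np.full(m, np.exp(-2.0 * s)) for m, s in zip(ws.sizes, log_sd)
        ])

    def pen_obj(theta, pen):
        eta = ws.eta(theta[:p], theta[p:])
        return float(y @ eta - np.logaddexp(0.0, eta).sum()
                     - 0.5 * (pen * theta**2).sum()), eta

    def inner_mode(log_sd, start=None):
        """Newton solve of the joint penalized logistic problem."""
        prec = dinv_diag(log_sd)
        pen = np.concatenate([np.zeros(p), prec])
        theta = np.zeros(p + q) if start is None else start.copy()
        obj, eta = pen_obj(theta, pen)
        H = None
        for _ in range(80):
            mu = expit(eta)
            g = ws.grad(y - mu, pen, theta)
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            H = ws.hessian(w, pen)
            step = np.linalg.solve(H, g)
            t_step = 1.0
            for _ in range(30):
                cand = theta + t_step * step
                obj_c, eta_c = pen_obj(cand, pen)
                if obj_c >= obj - 1e-12:
                    break
                t_step *= 0.5
            theta, converged_inner = cand, abs(obj_c - obj) < 1e-9 * (1.0 + abs(obj_c))
            obj, eta = obj_c, eta_c
            if converged_inner:
                break
        # final-curvature Hessian at the mode
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        H = ws.hessian(w, pen)
        return theta, H, obj, prec

    def laplace_loglik(log_sd, start=None):
        theta, H, obj, prec = inner_mode(log_sd, start)
        if q:
            sign, logdet_H = np.linalg.slogdet(H[p:, p:])
            if sign <= 0:
                return -np.inf, theta, H
            ll = obj - 0.5 * (logdet_H - np.log(prec).sum())
        else:
            ll = obj
        return ll, theta, H

    warm: dict = {"theta": None}

    def objective(log_sd):
        ls = np.clip(log_sd, *LOG_SD_BOUNDS)
        ll, theta, _ = laplace_loglik(ls, warm["theta"])
        warm["theta"] = theta
        return -ll

    names = exog_names or [f"x{i}" for i in range(p)]
    if fixed_log_sd is not None or not blocks:
        best = np.asarray(fixed_log_sd if fixed_log_sd is not None else [])
        converged, message = True, "variance parameters fixed"
    else:
        x0 = np.full(len(blocks), np.log(0.3))
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": 1e-4, "maxiter": 300 * len(blocks)},
        )
        best = np.clip(res.x, *LOG_SD_BOUNDS)
        converged, message = bool(res.success), str(res.message)

    ll, theta, H = laplace_loglik(best, warm.get("theta"))
    if q:
        Hbb, Hbu, Huu = H[:p, :p], H[:p, p:], H[p:, p:]
        info = Hbb - Hbu @ np.linalg.solve(Huu, Hbu.T)
    else:
        info = H
    cov = np.linalg.inv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if not np.all(np.isfinite(theta[:p])) or not np.all(np.isfinite(se)):
        raise FloatingPointError("Laplace GLMM fit produced non-finite estimates")
    return GlmmFit(
        beta=theta[:p], beta_se=se, exog_names=names,
        block_names=[b.name for b in blocks],
        block_sd=np.exp(best) if len(best) else np.zeros(0),
        u=theta[p:], loglik_laplace=float(ll), n_obs=ws.n,
        converged=converged, message=message,
    )
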