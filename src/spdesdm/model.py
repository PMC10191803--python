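"""Bernoulli-logit latent Gaussian occurrence model.

Presence/absence labels Z(s) at presence and background sites follow

    Z(s) ~ Bernoulli(pi(s)),
    logit pi(s) = beta0 + sum_j X_j(s) beta_j + RF(s) [+ eNN(s)],

with z-scored covariates X_j, an optional Matern Gaussian random field RF
represented on a mesh (see :mod:`spdesdm.mesh`), and an optional
nearest-presence clustering covariate eNN. Inference is a Gaussian (Laplace)
approximation to the joint posterior of (beta0, beta, field) at
hyperparameters chosen by approximate marginal likelihood over a coarse
(range, sd) grid; a seeded independence-Metropolis MCMC mode is available as
a slow oracle. Model comparison uses WAIC computed from posterior draws of
the pointwise log-likelihood.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.special import expit

from .mesh import SPDEModel, spde_precision

NN_COLUMN = "nn_presence_dist"


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative defaults: Gaussian fixed effects (mean 0, sd 10);
    log-Gaussian hyperpriors with unit log-sd for field range and sd."""

    beta_sd: float = 10.0
    range_median_km: float = 10.0
    sd_median: float = 1.0


@dataclass(frozen=True)
class ModelSpec:
    """Hashable description of one candidate model: which covariates enter
    the fixed effects, and whether the spatial field / eNN term are on."""

    covariates: tuple[str, ...]
    include_rf: bool = True
    include_nn: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def formula(self) -> str:
        parts = list(self.covariates) or ["1"]
        if self.include_nn:
            parts.append("eNN")
        if self.include_rf:
            parts.append("RF")
        return " + ".join(parts)


class DesignMatrix:
    """Column-wise z-scored covariates with the scaling record retained for
    prediction-time reuse."""

    def __init__(self, values: pd.DataFrame, scaling: Mapping[str, tuple[float, float]]):
        self.values = values
        self.scaling = dict(scaling)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def apply(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Scale new raw data with the stored (mean, sd) record."""
        out = {}
        for col in raw.columns:
            mu, sd = self.scaling[col]
            out[col] = (raw[col].to_numpy(dtype=float) - mu) / sd
        return pd.DataFrame(out, index=raw.index)

    def invert(self, column: str, scaled: np.ndarray) -> np.ndarray:
        mu, sd = self.scaling[column]
        return np.asarray(scaled, dtype=float) * sd + mu


def scale_covariates(raw: pd.DataFrame) -> DesignMatrix:
    """Z-score every column (subtract mean, divide by sd); a constant column
    is an error since it cannot be scaled."""
    values, scaling = {}, {}
    for col in raw.columns:
        x = raw[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"column '{col}' contains non-finite values")
        mu, sd = float(x.mean()), float(x.std())
        if sd == 0:
            raise ValueError(f"column '{col}' is constant and cannot be scaled")
        values[col] = (x - mu) / sd
        scaling[col] = (mu, sd)
    return DesignMatrix(pd.DataFrame(values, index=raw.index), scaling)


def nn_covariate(
    points: np.ndarray,
    presence_coords: np.ndarray,
    is_presence: np.ndarray | None = None,
) -> np.ndarray:
    """Raw eNN clustering covariate: log(1 + distance to the nearest presence
    other than the point itself). Z-scoring happens with the design matrix.

    ``is_presence`` marks which query points are themselves presences (their
    own zero-distance match is skipped). When omitted, any point at zero
    distance from a presence is assumed to be that presence; pass the mask
    explicitly to distinguish a background point coincident with a presence
    (raw value 0) from the presence itself.
    """
    presence_coords = np.asarray(presence_coords, dtype=float)
    if len(presence_coords) < 2:
        raise ValueError("need at least 2 presences for the eNN covariate")
    pts = np.asarray(points, dtype=float)
    tree = cKDTree(presence_coords)
    d, _ = tree.query(pts, k=2)
    if is_presence is None:
        is_presence = d[:, 0] <= 1e-12
    else:
        is_presence = np.asarray(is_presence, dtype=bool)
    nearest = np.where(is_presence & (d[:, 0] <= 1e-12), d[:, 1], d[:, 0])
    return np.log1p(nearest)


@dataclass
class PosteriorFit:
    """Posterior summaries from one model fit."""

    spec: ModelSpec
    beta: pd.DataFrame  # index: intercept + covariates; mean, sd, q2.5, q50, q97.5
    hyperparameters: dict
    loglik_draws: np.ndarray  # (n_draws, n_obs)
    waic: float
    p_waic: float
    lppd: float
    field_mean: np.ndarray | None = None
    field_sd: np.ndarray | None = None
    eta_mean: np.ndarray | None = field(default=None, repr=False)
    log_marginal: float = np.nan
    iterations: int = 0
    grad_norm: float = np.nan
    seed: int = 0
    scaling: dict | None = None
    method: str = "laplace"

    @property
    def n_obs(self) -> int:
        return self.loglik_draws.shape[1]

    @property
    def fitted_probabilities(self) -> np.ndarray:
        return expit(self.eta_mean)


def _bernoulli_loglik(z: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return z * eta - np.logaddexp(0.0, eta)


def _newton(M: sp.spmatrix, z: np.ndarray, P: np.ndarray, u0: np.ndarray | None = None):
    """Newton ascent of the joint log posterior in the latent vector u."""
    dim = M.shape[1]
    u = np.zeros(dim) if u0 is None else u0.copy()

    def objective(u):
        eta = M @ u
        return float(np.sum(_bernoulli_loglik(z, eta)) - 0.5 * u @ P @ u)

    f = objective(u)
    cho = None
    for it in range(1, 61):
        eta = M @ u
        mu = expit(eta)
        g = M.T @ (z - mu) - P @ u
        gnorm = float(np.max(np.abs(g)))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        H = (M.T @ M.multiply(w[:, None])).toarray() + P
        cho = sla.cho_factor(H, lower=True)
        delta = sla.cho_solve(cho, g)
        if g @ delta < 1e-9 * (1.0 + abs(f)):
            return u, cho, H, it, gnorm
        step = 1.0
        for _ in range(30):
            u_new = u + step * delta
            f_new = objective(u_new)
            if f_new >= f - 1e-12:
                break
            step /= 2.0
        else:
            raise RuntimeError(
                f"Newton line search failed at iteration {it}; |grad| = {gnorm:.3e}"
            )
        u, f = u_new, f_new
        if np.max(np.abs(u[: min(dim, 64)])) > 60:
            raise RuntimeError(
                "divergent coefficients (separation?); consider tightening the "
                "fixed-effect prior"
            )
    raise RuntimeError(f"Newton did not converge in 60 iterations; |grad| = {gnorm:.3e}")


def _joint_logpost(M, z, P, u) -> float:
    eta = M @ u
    return float(np.sum(_bernoulli_loglik(z, eta)) - 0.5 * u @ P @ u)


def _logdet_chol(A: np.ndarray) -> float:
    L = np.linalg.cholesky(A)
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def _log_hyperprior(value: float, median: float) -> float:
    # log-Gaussian, unit log-sd
    lx = np.log(value)
    return -0.5 * (lx - np.log(median)) ** 2 - lx


def fit(
    spec: ModelSpec,
    design: DesignMatrix,
    z: np.ndarray,
    spde: SPDEModel | None = None,
    A: sp.spmatrix | None = None,
    *,
    priors: PriorConfig = PriorConfig(),
    hyper_grid: Sequence[tuple[float, float]] | None = None,
    refine: bool | None = None,
    n_draws: int = 200,
    seed: int = 0,
    method: str = "laplace",
    mcmc_iters: int = 6000,
    mcmc_burn: int = 1000,
) -> PosteriorFit:
    """Fit one candidate model and return posterior summaries + WAIC.

    ``hyper_grid`` is the list of (range_km, sd) candidates for the field
    hyperparameters; by default a 7 x 7 log-spaced grid around the prior
    medians, with a Nelder-Mead refinement of the best cell. Pass a single
    pair to fit at fixed hyperparameters (cheap, e.g. inside selection
    ladders on small problems).
    """
    z = np.asarray(z, dtype=float)
    if not set(np.unique(z)) <= {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    missing = [c for c in spec.covariates if c not in design.columns]
    if missing:
        raise ValueError(f"spec covariates not in design: {missing}")
    cols = list(spec.covariates)
    if spec.include_nn:
        if NN_COLUMN not in design.columns:
            raise ValueError(f"design lacks the '{NN_COLUMN}' column")
        cols.append(NN_COLUMN)
    X = np.column_stack(
        [np.ones(len(z))] + [design.values[c].to_numpy() for c in cols]
    )
    if len(X) != len(z):
        raise ValueError("design rows and labels misaligned")
    p = X.shape[1]
    names = ["intercept"] + cols
    rng = np.random.default_rng(seed)

    if spec.include_rf:
        if spde is None or A is None:
            raise ValueError("RF model requires an SPDEModel and projector A")
        if A.shape[0] != len(z):
            raise ValueError("projector rows and labels misaligned")
        M = sp.hstack([sp.csr_matrix(X), A.tocsr()]).tocsr()
        nv = A.shape[1]
        if hyper_grid is None:
            ranges = priors.range_median_km * np.exp(np.linspace(-1.5, 1.5, 7))
            sds = priors.sd_median * np.exp(np.linspace(-1.5, 1.5, 7))
            hyper_grid = list(itertools.product(ranges, sds))
        else:
            hyper_grid = [tuple(map(float, h)) for h in hyper_grid]
        if refine is None:
            refine = len(hyper_grid) > 1

        beta_prec = np.eye(p) / priors.beta_sd**2
        logdet_beta = -2 * p * np.log(priors.beta_sd)

        u_warm = None
        evals: dict[tuple[float, float], float] = {}

        def score(theta, u0=None):
            r, s = theta
            Q = spde_precision(spde.C, spde.G, r, s).toarray()
            P = np.zeros((p + nv, p + nv))
            P[:p, :p] = beta_prec
            P[p:, p:] = Q
            u_hat, cho, H, its, gnorm = _newton(M, z, P, u0)
            lml = (
                _joint_logpost(M, z, P, u_hat)
                + 0.5 * (logdet_beta + _logdet_chol(Q))
                - 0.5 * 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
                + _log_hyperprior(r, priors.range_median_km)
                + _log_hyperprior(s, priors.sd_median)
            )
            return lml, (u_hat, cho, H, P, its, gnorm)

        best = None
        for theta in hyper_grid:
            lml, state = score(theta, u_warm)
            evals[theta] = lml
            u_warm = state[0]
            if best is None or lml > best[0]:
                best = (lml, theta, state)

        if refine:
            def neg(logtheta):
                theta = tuple(np.exp(logtheta))
                try:
                    lml, _ = score(theta, best[2][0])
                except RuntimeError:
                    return 1e12
                return -lml

            res = minimize(
                neg,
                np.log(best[1]),
                method="Nelder-Mead",
                options={"maxfev": 20, "xatol": 0.05, "fatol": 0.05},
            )
            theta_ref = tuple(np.exp(res.x))
            lml_ref, state_ref = score(theta_ref, best[2][0])
            if lml_ref > best[0]:
                best = (lml_ref, theta_ref, state_ref)

        lml, (range_km, sd_field), (u_hat, cho, H, P, its, gnorm) = best
        hyper = {"range_km": float(range_km), "sd": float(sd_field)}
    else:
        M = sp.csr_matrix(X)
        P = np.eye(p) / priors.beta_sd**2
        u_hat, cho, H, its, gnorm = _newton(M, z, P)
        lml = (
            _joint_logpost(M, z, P, u_hat)
            - p * np.log(priors.beta_sd)
            - 0.5 * 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        )
        hyper = {}
        nv = 0

    if method == "mcmc":
        return _mcmc_fit(
            spec, M, z, P, u_hat, cho, names, p, nv, hyper, lml,
            n_draws=n_draws, iters=mcmc_iters, burn=mcmc_burn, rng=rng, seed=seed,
            scaling=design.scaling,
        )
    if method != "laplace":
        raise ValueError(f"unknown method '{method}'")

    L = np.linalg.cholesky(H)
    cov = sla.cho_solve((L, True), np.eye(len(H)))
    sd_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    zq = 1.959963984540054
    beta = pd.DataFrame(
        {
            "mean": u_hat[:p],
            "sd": sd_all[:p],
            "q2.5": u_hat[:p] - zq * sd_all[:p],
            "q50": u_hat[:p],
            "q97.5": u_hat[:p] + zq * sd_all[:p],
        },
        index=names,
    )

    xi = rng.standard_normal((len(H), n_draws))
    draws = u_hat[:, None] + sla.solve_triangular(L, xi, trans="T", lower=True)
    eta_draws = M @ draws  # (n_obs, n_draws)
    ll = _bernoulli_loglik(z[:, None], eta_draws).T  # (n_draws, n_obs)
    w, p_w, lppd = waic(ll)

    return PosteriorFit(
        spec=spec,
        beta=beta,
        hyperparameters=hyper,
        loglik_draws=ll,
        waic=w,
        p_waic=p_w,
        lppd=lppd,
        field_mean=u_hat[p:].copy() if spec.include_rf else None,
        field_sd=sd_all[p:].copy() if spec.include_rf else None,
        eta_mean=np.asarray(M @ u_hat),
        log_marginal=lml,
        iterations=its,
        grad_norm=gnorm,
        seed=seed,
        scaling=dict(design.scaling),
        method="laplace",
    )


def _mcmc_fit(
    spec, M, z, P, u_hat, cho, names, p, nv, hyper, lml,
    *, n_draws, iters, burn, rng, seed, scaling,
):
    """Independence-Metropolis sampler with the Laplace Gaussian as proposal
    distribution: the slow oracle for the Laplace mode."""
    # cho_factor leaves junk in the unused triangle; take the clean factor
    L = np.tril(cho[0])
    dim = len(u_hat)

    def logpost(u):
        return _joint_logpost(M, z, P, u)

    def logq(u):
        # q = N(u_hat, H^{-1}) => logq = const - 0.5 |L' (u - u_hat)|^2
        w = L.T @ (u - u_hat)
        return -0.5 * float(w @ w)

    def draw():
        xi = rng.standard_normal(dim)
        return u_hat + sla.solve_triangular(L, xi, trans="T", lower=True)

    u = u_hat.copy()
    lp, lq = logpost(u), logq(u)
    samples = np.empty((iters - burn, dim))
    accepted = 0
    for it in range(iters):
        u_star = draw()
        lp_star, lq_star = logpost(u_star), logq(u_star)
        if np.log(rng.random()) < (lp_star - lp) - (lq_star - lq):
            u, lp, lq = u_star, lp_star, lq_star
            accepted += 1
        if it >= burn:
            samples[it - burn] = u
    qs = np.percentile(samples[:, :p], [2.5, 50.0, 97.5], axis=0)
    beta = pd.DataFrame(
        {
            "mean": samples[:, :p].mean(axis=0),
            "sd": samples[:, :p].std(axis=0, ddof=1),
            "q2.5": qs[0],
            "q50": qs[1],
            "q97.5": qs[2],
        },
        index=names,
    )
    take = np.linspace(0, len(samples) - 1, min(n_draws, len(samples))).astype(int)
    eta_draws = M @ samples[take].T
    ll = _bernoulli_loglik(z[:, None], eta_draws).T
    w, p_w, lppd = waic(ll)
    u_mean = samples.mean(axis=0)
    return PosteriorFit(
        spec=spec,
        beta=beta,
        hyperparameters=hyper,
        loglik_draws=ll,
        waic=w,
        p_waic=p_w,
        lppd=lppd,
        field_mean=u_mean[p:].copy() if spec.include_rf else None,
        field_sd=samples[:, p:].std(axis=0, ddof=1) if spec.include_rf else None,
        eta_mean=np.asarray(M @ u_mean),
        log_marginal=lml,
        iterations=iters,
        grad_norm=accepted / iters,
        seed=seed,
        scaling=dict(scaling),
        method="mcmc",
    )


def waic(fit_or_draws) -> tuple[float, float, float]:
    """WAIC = -2 (lppd - p_waic) from posterior draws of pointwise
    log-likelihood; returns (waic, p_waic, lppd)."""
    ll = fit_or_draws.loglik_draws if isinstance(fit_or_draws, PosteriorFit) else np.asarray(
        fit_or_draws, dtype=float
    )
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (n_draws >= 2, n_obs) matrix of pointwise log-likelihoods")
    bad = np.flatnonzero(~np.isfinite(ll).all(axis=0))
    if len(bad):
        raise ValueError(f"non-finite pointwise log-likelihoods at observations {bad[:20].tolist()}")
    S = ll.shape[0]
    lppd = float(np.sum(sla_logsumexp(ll) - np.log(S)))
    p_w = float(np.sum(ll.var(axis=0, ddof=1)))
    w = -2.0 * (lppd - p_w)
    if not np.isfinite(w):
        raise ValueError("WAIC is non-finite")
    return w, p_w, lppd


def sla_logsumexp(ll: np.ndarray) -> np.ndarray:
    from scipy.special import logsumexp

    return logsumexp(ll, axis=0)


def significance(fit: PosteriorFit, level: float = 0.95) -> pd.DataFrame:
    """Flag each coefficient 'informative' iff the central credible interval
    at ``level`` excludes zero."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if abs(level - 0.95) < 1e-12:
        lower, upper = fit.beta["q2.5"], fit.beta["q97.5"]
    else:
        from scipy.stats import norm

        zq = norm.ppf(0.5 + level / 2.0)
        lower = fit.beta["mean"] - zq * fit.beta["sd"]
        upper = fit.beta["mean"] + zq * fit.beta["sd"]
    return pd.DataFrame(
        {
            "lower": lower,
            "upper": upper,
            "informative": (lower > 0) | (upper < 0),
        },
        index=fit.beta.index,
    )


def interval_informative(lower: float, upper: float) -> bool:
    """Does the interval (lower, upper) exclude zero?"""
    if lower > upper:
        raise ValueError("interval endpoints out of order")
    return lower > 0 or upper < 0
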