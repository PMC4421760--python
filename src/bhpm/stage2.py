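"""Level-2 Bayesian regression of spatially varying intercepts and slopes.

The stage-1 estimates (a0_hat_i, a1_hat_i) with known 2x2 sampling
covariance V_i are modelled as noisy observations of latent site effects

    a_i0 = X0_i' beta + eps_i0        (intercept equation; includes x̄_i)
    a_i1 = X1_i' gamma + eps_i1       (slope equation)

where X0/X1 hold standardized constituent and community-confounder blocks
chosen by a :class:`ModelSpec`, and the errors are independent
(eps ~ N(0, sigma^2)) or spatially correlated with exponential covariance
sigma^2 exp(-phi d) + tau^2 I.  The latent effects are integrated out
analytically, so the sampler works on the marginal Gaussian likelihood

    (a0_hat, a1_hat) ~ N((X0 beta, X1 gamma), C(theta) + V),

drawing (beta, gamma) jointly from their conjugate normal full conditional
and moving the variance/decay parameters by adaptive random-walk
Metropolis (frozen after burn-in).  Marginalization matters here: the
slope estimates carry sampling noise much larger than the slope equation's
error SD, and a centered latent-variable Gibbs scheme mixes poorly in
exactly that regime.  Model comparison uses DIC = D_bar + pD on the same
marginal likelihood, and effects are reported as 100*(exp(coef) - 1)
percent per 1 SD of covariate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .geo import pairwise_distances
from .gp import _DECAY_HI, _DECAY_LO, exponential_covariance
from .panel import CONSTITUENTS, CONFOUNDERS, CovariateProfile
from .stage1 import Stage1Estimate

logger = logging.getLogger(__name__)

COVARIATE_BLOCKS = ("none", "constituents_only", "confounders_only", "both")


@dataclass(frozen=True)
class ModelSpec:
    """Which level-2 covariate blocks are active, and the error structure.

    The same choice applies to both the intercept and slope equations; the
    mean-exposure term x̄_i enters the intercept design whenever any
    covariates do, and never the slope design.
    """

    covariate_block: str = "both"
    spatial_errors: bool = False

    def __post_init__(self) -> None:
        if self.covariate_block not in COVARIATE_BLOCKS:
            raise ValueError(f"unknown covariate block {self.covariate_block!r}")

    @property
    def label(self) -> str:
        err = "spatial" if self.spatial_errors else "iid"
        return f"{self.covariate_block}+{err}"


def all_model_specs() -> list[ModelSpec]:
    """The eight candidate model structures (4 covariate blocks x 2 error types)."""
    return [
        ModelSpec(block, spatial)
        for block, spatial in itertools.product(COVARIATE_BLOCKS, (False, True))
    ]


@dataclass
class Priors:
    """Weakly informative defaults: N(0, coef_sd^2) coefficients, half-normal
    error SDs, uniform log-decay implying 40-mile correlation in (0.01, 0.99)."""

    coef_sd: float = 10.0
    eps_sd_scale: float = 1.0
    decay_lo: float = _DECAY_LO
    decay_hi: float = _DECAY_HI


@dataclass
class PosteriorResult:
    """MCMC draws and summaries for one fitted model."""

    spec: ModelSpec
    draws: pd.DataFrame  # one row per kept draw; 'chain' column included
    summaries: pd.DataFrame  # parameter, mean, sd, q2.5, q97.5, rhat
    param_names: dict  # {'beta': [...], 'gamma': [...], 'extra': [...]}
    alpha_mean: np.ndarray  # (n, 2) posterior mean latent site effects
    chains: int
    n_iter: int
    n_burn: int
    seed: int
    converged: bool
    dic: float | None = None
    pd_eff: float | None = None
    location_ids: list = field(default_factory=list)


def build_design(
    profiles: list[CovariateProfile], spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Design matrices (X_intercept, X_slope) plus their column names.

    Column order: const, active constituent block (ec..na), active
    confounder block (income..black), then exposure_mean (intercept design
    only, present whenever any covariate block is active).
    """
    n = len(profiles)
    for p in profiles:
        if p.constituents_std is None or p.confounders_std is None:
            raise ValueError(
                "profiles are not standardized; run standardize_covariates "
                "(impute missing constituents first — see bhpm.gp.impute_all)"
            )
        if spec.covariate_block in ("constituents_only", "both") and not np.all(
            np.isfinite(p.constituents_std)
        ):
            raise ValueError(
                f"location {p.location_id} has missing constituents; "
                "impute with bhpm.gp.impute_all before building the design"
            )
    z = np.array([p.constituents_std for p in profiles])
    w = np.array([p.confounders_std for p in profiles])
    xb = np.array([p.exposure_mean_std for p in profiles])

    cols0, cols1 = [np.ones(n)], [np.ones(n)]
    names0, names1 = ["const"], ["const"]
    if spec.covariate_block in ("constituents_only", "both"):
        cols0.append(z)
        cols1.append(z)
        names0 += CONSTITUENTS
        names1 += CONSTITUENTS
    if spec.covariate_block in ("confounders_only", "both"):
        cols0.append(w)
        cols1.append(w)
        names0 += CONFOUNDERS
        names1 += CONFOUNDERS
    if spec.covariate_block != "none":
        cols0.append(xb)
        names0.append("exposure_mean")
    X0 = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols0])
    X1 = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols1])
    return X0, X1, names0, names1


def _prepare_stage1(estimates: list[Stage1Estimate]):
    use = [e for e in estimates if e.converged and np.all(np.isfinite(e.vcov))]
    if len(use) < len(estimates):
        logger.warning(
            "%d degenerate stage-1 locations excluded from stage 2",
            len(estimates) - len(use),
        )
    ids = [e.location_id for e in use]
    ahat = np.array([[e.alpha0_hat, e.alpha1_hat] for e in use])
    V = np.array([e.vcov for e in use])
    return ids, ahat, V


def _half_normal_logpdf(s2: float, scale: float) -> float:
    # density of sigma = sqrt(s2) under half-normal(0, scale), up to constants
    return -s2 / (2.0 * scale**2)


class _IidEq:
    """Independent errors for one equation: parameter sigma^2."""

    def __init__(self, sigma2: float, priors: Priors):
        self.sigma2 = max(sigma2, 1e-12)
        self.priors = priors
        self.step = 0.25
        self.accepts = 0
        self.tries = 0

    def names(self, tag: int) -> list[str]:
        return [f"sigma_eps{tag}"]

    def values(self) -> list[float]:
        return [float(np.sqrt(self.sigma2))]

    def log_prior(self, params: dict) -> float:
        return _half_normal_logpdf(params["sigma2"], self.priors.eps_sd_scale) + 0.5 * np.log(
            params["sigma2"]
        )  # Jacobian of the log-scale walk on sigma

    def current(self) -> dict:
        return {"sigma2": self.sigma2}

    def propose(self, rng) -> dict:
        return {"sigma2": self.sigma2 * np.exp(self.step * rng.normal())}

    def accept(self, params: dict) -> None:
        self.sigma2 = params["sigma2"]

    def adapt(self, accepted: bool) -> None:
        self.tries += 1
        self.accepts += accepted
        if self.tries % 50 == 0:
            rate = self.accepts / self.tries
            self.step = float(np.clip(self.step * np.exp(0.5 * (rate - 0.4)), 1e-3, 3.0))

    def cov_matrix(self, params: dict, dist) -> np.ndarray | float:
        return params["sigma2"]


class _SpatialEq:
    """Spatial errors sigma^2 exp(-phi d) + tau^2 I; joint 3-parameter walk."""

    def __init__(self, sigma2: float, priors: Priors):
        self.sigma2 = max(sigma2 / 2.0, 1e-12)
        self.tau2 = max(sigma2 / 2.0, 1e-12)
        self.phi = float(np.sqrt(priors.decay_lo * priors.decay_hi))
        self.priors = priors
        self.step = 0.2
        self.accepts = 0
        self.tries = 0

    def names(self, tag: int) -> list[str]:
        return [f"sigma_eps{tag}", f"tau_eps{tag}", f"phi{tag}"]

    def values(self) -> list[float]:
        return [float(np.sqrt(self.sigma2)), float(np.sqrt(self.tau2)), float(self.phi)]

    def log_prior(self, params: dict) -> float:
        if not (self.priors.decay_lo <= params["phi"] <= self.priors.decay_hi):
            return -np.inf
        scale = self.priors.eps_sd_scale
        jac = 0.5 * (np.log(params["sigma2"]) + np.log(params["tau2"]))
        # phi has a uniform prior on log phi: the Jacobian of the log walk cancels
        return (
            _half_normal_logpdf(params["sigma2"], scale)
            + _half_normal_logpdf(params["tau2"], scale)
            + jac
        )

    def current(self) -> dict:
        return {"sigma2": self.sigma2, "tau2": self.tau2, "phi": self.phi}

    def propose(self, rng) -> dict:
        z = rng.standard_normal(3)
        return {
            "sigma2": self.sigma2 * np.exp(self.step * z[0]),
            "tau2": self.tau2 * np.exp(self.step * z[1]),
            "phi": self.phi * np.exp(self.step * z[2]),
        }

    def accept(self, params: dict) -> None:
        self.sigma2, self.tau2, self.phi = params["sigma2"], params["tau2"], params["phi"]

    def adapt(self, accepted: bool) -> None:
        self.tries += 1
        self.accepts += accepted
        if self.tries % 50 == 0:
            rate = self.accepts / self.tries
            self.step = float(np.clip(self.step * np.exp(0.5 * (rate - 0.25)), 1e-3, 2.0))

    def cov_matrix(self, params: dict, dist: np.ndarray) -> np.ndarray:
        cov = exponential_covariance(dist, params["sigma2"], params["phi"], params["tau2"])
        cov[np.diag_indices_from(cov)] += 1e-10 * (params["sigma2"] + params["tau2"])
        return cov


def _inv2x2(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched inverse and log-determinant of (n, 2, 2) SPD matrices."""
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    inv = np.empty_like(M)
    inv[:, 0, 0] = M[:, 1, 1] / det
    inv[:, 1, 1] = M[:, 0, 0] / det
    inv[:, 0, 1] = inv[:, 1, 0] = -M[:, 0, 1] / det
    return inv, np.log(det)


class _IidKernel:
    """Marginal-likelihood machinery when both equations have iid errors."""

    def __init__(self, ahat, V, X0, X1, priors):
        self.ahat, self.V, self.X0, self.X1 = ahat, V, X0, X1
        self.priors = priors
        self.n = ahat.shape[0]
        self.p0, self.p1 = X0.shape[1], X1.shape[1]

    def set_errs(self, err0, err1):
        self.err0, self.err1 = err0, err1
        self._refresh(err0.sigma2, err1.sigma2)

    def _refresh(self, s0, s1):
        M = self.V.copy()
        M[:, 0, 0] += s0
        M[:, 1, 1] += s1
        self.Minv, self.logdet = _inv2x2(M)

    def marginal_loglik(self, coef, s0=None, s1=None) -> float:
        if s0 is None:
            Minv, logdet = self.Minv, self.logdet
        else:
            M = self.V.copy()
            M[:, 0, 0] += s0
            M[:, 1, 1] += s1
            Minv, logdet = _inv2x2(M)
        r = self.ahat - np.column_stack(
            [self.X0 @ coef[: self.p0], self.X1 @ coef[self.p0 :]]
        )
        q = np.einsum("ni,nij,nj->n", r, Minv, r)
        return float(-0.5 * np.sum(logdet + q) - self.n * np.log(2.0 * np.pi))

    def draw_coefs(self, rng) -> np.ndarray:
        Minv = self.Minv
        X0, X1 = self.X0, self.X1
        P00 = (X0 * Minv[:, 0, 0, None]).T @ X0
        P01 = (X0 * Minv[:, 0, 1, None]).T @ X1
        P11 = (X1 * Minv[:, 1, 1, None]).T @ X1
        p = self.p0 + self.p1
        P = np.empty((p, p))
        P[: self.p0, : self.p0] = P00
        P[: self.p0, self.p0 :] = P01
        P[self.p0 :, : self.p0] = P01.T
        P[self.p0 :, self.p0 :] = P11
        P[np.diag_indices(p)] += 1.0 / self.priors.coef_sd**2
        b = np.concatenate(
            [
                X0.T @ (Minv[:, 0, 0] * self.ahat[:, 0] + Minv[:, 0, 1] * self.ahat[:, 1]),
                X1.T @ (Minv[:, 0, 1] * self.ahat[:, 0] + Minv[:, 1, 1] * self.ahat[:, 1]),
            ]
        )
        cf = cho_factor(P, lower=True)
        mean = cho_solve(cf, b)
        return mean + solve_triangular(cf[0], rng.standard_normal(p), lower=True, trans="T")

    def update_variances(self, coef, rng, adapt: bool) -> None:
        for which, err in ((0, self.err0), (1, self.err1)):
            cur = err.current()
            prop = err.propose(rng)
            s_cur = (self.err0.sigma2, self.err1.sigma2)
            s_prop = (
                (prop["sigma2"], s_cur[1]) if which == 0 else (s_cur[0], prop["sigma2"])
            )
            ll_cur = self.marginal_loglik(coef)
            ll_prop = self.marginal_loglik(coef, *s_prop)
            log_acc = (ll_prop + err.log_prior(prop)) - (ll_cur + err.log_prior(cur))
            ok = np.log(rng.uniform()) < log_acc
            if ok:
                err.accept(prop)
                self._refresh(self.err0.sigma2, self.err1.sigma2)
            if adapt:
                err.adapt(bool(ok))

    def alpha_cond_mean(self, coef) -> np.ndarray:
        # E[alpha | ahat, theta] = m + C Minv (ahat - m), C = diag(s0, s1)
        m = np.column_stack([self.X0 @ coef[: self.p0], self.X1 @ coef[self.p0 :]])
        r = self.ahat - m
        s0, s1 = self.err0.sigma2, self.err1.sigma2
        out = m.copy()
        out[:, 0] += s0 * (self.Minv[:, 0, 0] * r[:, 0] + self.Minv[:, 0, 1] * r[:, 1])
        out[:, 1] += s1 * (self.Minv[:, 1, 0] * r[:, 0] + self.Minv[:, 1, 1] * r[:, 1])
        return out


class _SpatialKernel:
    """Marginal-likelihood machinery when errors are spatially correlated."""

    def __init__(self, ahat, V, X0, X1, priors, dist):
        self.ahat, self.V, self.X0, self.X1 = ahat, V, X0, X1
        self.priors = priors
        self.dist = dist
        self.n = ahat.shape[0]
        self.p0, self.p1 = X0.shape[1], X1.shape[1]
        n, p0, p1 = self.n, self.p0, self.p1
        self.Xbig = np.zeros((2 * n, p0 + p1))
        self.Xbig[:n, :p0] = X0
        self.Xbig[n:, p0:] = X1
        self.y = np.concatenate([ahat[:, 0], ahat[:, 1]])

    def set_errs(self, err0, err1):
        self.err0, self.err1 = err0, err1
        self.S0 = err0.cov_matrix(err0.current(), self.dist)
        self.S1 = err1.cov_matrix(err1.current(), self.dist)
        self._refresh()

    def _assemble(self, S0, S1) -> np.ndarray:
        n = self.n
        M = np.zeros((2 * n, 2 * n))
        M[:n, :n] = S0 if isinstance(S0, np.ndarray) else S0 * np.eye(n)
        M[n:, n:] = S1 if isinstance(S1, np.ndarray) else S1 * np.eye(n)
        idx = np.arange(n)
        M[idx, idx] += self.V[:, 0, 0]
        M[idx, n + idx] += self.V[:, 0, 1]
        M[n + idx, idx] += self.V[:, 1, 0]
        M[n + idx, n + idx] += self.V[:, 1, 1]
        return M

    def _refresh(self):
        M = self._assemble(self.S0, self.S1)
        self.chol = np.linalg.cholesky(M)
        self.logdet = 2.0 * float(np.log(np.diag(self.chol)).sum())
        self.Minv = cho_solve((self.chol, True), np.eye(2 * self.n))

    def _loglik_chol(self, coef, chol, logdet) -> float:
        r = self.y - self.Xbig @ coef
        u = solve_triangular(chol, r, lower=True)
        return float(-0.5 * (u @ u) - 0.5 * logdet - self.n * np.log(2.0 * np.pi))

    def marginal_loglik(self, coef) -> float:
        return self._loglik_chol(coef, self.chol, self.logdet)

    def draw_coefs(self, rng) -> np.ndarray:
        p = self.p0 + self.p1
        XtMi = self.Xbig.T @ self.Minv
        P = XtMi @ self.Xbig
        P[np.diag_indices(p)] += 1.0 / self.priors.coef_sd**2
        b = XtMi @ self.y
        cf = cho_factor(P, lower=True)
        mean = cho_solve(cf, b)
        return mean + solve_triangular(cf[0], rng.standard_normal(p), lower=True, trans="T")

    def update_variances(self, coef, rng, adapt: bool) -> None:
        for which, err in ((0, self.err0), (1, self.err1)):
            cur = err.current()
            prop = err.propose(rng)
            lp_prop = err.log_prior(prop)
            ok = False
            if np.isfinite(lp_prop):
                S_prop = err.cov_matrix(prop, self.dist)
                M_prop = self._assemble(
                    S_prop if which == 0 else self.S0,
                    S_prop if which == 1 else self.S1,
                )
                try:
                    chol_p = np.linalg.cholesky(M_prop)
                except np.linalg.LinAlgError:
                    chol_p = None
                if chol_p is not None:
                    logdet_p = 2.0 * float(np.log(np.diag(chol_p)).sum())
                    ll_prop = self._loglik_chol(coef, chol_p, logdet_p)
                    ll_cur = self.marginal_loglik(coef)
                    log_acc = (ll_prop + lp_prop) - (ll_cur + err.log_prior(cur))
                    if np.log(rng.uniform()) < log_acc:
                        err.accept(prop)
                        if which == 0:
                            self.S0 = S_prop
                        else:
                            self.S1 = S_prop
                        self.chol, self.logdet = chol_p, logdet_p
                        self.Minv = cho_solve((self.chol, True), np.eye(2 * self.n))
                        ok = True
            if adapt:
                err.adapt(ok)

    def alpha_cond_mean(self, coef) -> np.ndarray:
        n = self.n
        m = self.Xbig @ coef
        w = self.Minv @ (self.y - m)
        out = m.copy()
        S0 = self.S0 if isinstance(self.S0, np.ndarray) else self.S0 * np.eye(n)
        S1 = self.S1 if isinstance(self.S1, np.ndarray) else self.S1 * np.eye(n)
        out[:n] += S0 @ w[:n]
        out[n:] += S1 @ w[n:]
        return np.column_stack([out[:n], out[n:]])


def run_mcmc(
    stage1: list[Stage1Estimate],
    X0: np.ndarray,
    X1: np.ndarray,
    spec: ModelSpec,
    *,
    coords: np.ndarray | None = None,
    priors: Priors | None = None,
    n_iter: int = 10_000,
    n_burn: int = 5_000,
    n_chains: int = 3,
    seed: int = 0,
    names0: list[str] | None = None,
    names1: list[str] | None = None,
    planar: bool = False,
    rhat_threshold: float = 1.1,
) -> PosteriorResult:
    """Sample the level-2 posterior given stage-1 estimates and designs.

    ``coords`` (lon/lat, one row per converged stage-1 location, in
    location_id order) is required when ``spec.spatial_errors``.  Draws are
    reproducible under a fixed (seed, n_chains, n_iter) triple.
    """
    if n_iter <= n_burn:
        raise ValueError("n_iter must exceed n_burn")
    priors = priors or Priors()
    ids, ahat, V = _prepare_stage1(stage1)
    n = len(ids)
    if X0.shape[0] != n or X1.shape[0] != n:
        raise ValueError(
            f"design rows ({X0.shape[0]}) must match converged stage-1 locations ({n}); "
            "filter profiles to the converged locations first"
        )
    dist = None
    if spec.spatial_errors:
        if coords is None:
            raise ValueError("spatial errors require monitor coordinates")
        dist = pairwise_distances(np.asarray(coords, dtype=float), planar=planar)

    names0 = names0 or [f"x{j}" for j in range(X0.shape[1])]
    names1 = names1 or [f"x{j}" for j in range(X1.shape[1])]
    beta_cols = [f"beta_{c}" for c in names0]
    gamma_cols = [f"gamma_{c}" for c in names1]
    p0 = X0.shape[1]

    # moment-based warm start
    beta_init = np.linalg.lstsq(X0, ahat[:, 0], rcond=None)[0]
    gamma_init = np.linalg.lstsq(X1, ahat[:, 1], rcond=None)[0]
    r0 = ahat[:, 0] - X0 @ beta_init
    r1 = ahat[:, 1] - X1 @ gamma_init
    v0 = max(float(np.var(r0) - V[:, 0, 0].mean()), 1e-8)
    v1 = max(float(np.var(r1) - V[:, 1, 1].mean()), 1e-8)

    all_rows = []
    alpha_acc = np.zeros((n, 2))
    n_keep_total = 0
    children = np.random.SeedSequence(seed).spawn(n_chains)
    extra_cols = None
    for chain, child in enumerate(children):
        rng = np.random.default_rng(child)
        if spec.spatial_errors:
            err0, err1 = _SpatialEq(v0, priors), _SpatialEq(v1, priors)
            kernel = _SpatialKernel(ahat, V, X0, X1, priors, dist)
        else:
            err0, err1 = _IidEq(v0, priors), _IidEq(v1, priors)
            kernel = _IidKernel(ahat, V, X0, X1, priors)
        kernel.set_errs(err0, err1)
        extra_cols = err0.names(0) + err1.names(1)
        coef = np.concatenate([beta_init, gamma_init])
        for it in range(n_iter):
            coef = kernel.draw_coefs(rng)
            kernel.update_variances(coef, rng, adapt=it < n_burn)
            if it >= n_burn:
                all_rows.append([chain] + list(coef) + err0.values() + err1.values())
                alpha_acc += kernel.alpha_cond_mean(coef)
                n_keep_total += 1
    draws = pd.DataFrame(all_rows, columns=["chain"] + beta_cols + gamma_cols + extra_cols)

    import arviz as az

    params = beta_cols + gamma_cols + extra_cols
    keep_per_chain = n_iter - n_burn
    rows = []
    for p in params:
        v = draws[p].to_numpy()
        per_chain = v.reshape(n_chains, keep_per_chain)
        rhat = float(az.rhat(per_chain)) if keep_per_chain >= 4 and n_chains >= 2 else float("nan")
        rows.append(
            {
                "parameter": p,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)),
                "q2.5": float(np.percentile(v, 2.5)),
                "q97.5": float(np.percentile(v, 97.5)),
                "rhat": rhat,
            }
        )
    summaries = pd.DataFrame(rows).set_index("parameter")
    rhats = summaries["rhat"].to_numpy()
    max_rhat = np.nanmax(rhats) if np.isfinite(rhats).any() else np.nan
    converged = bool(np.isnan(max_rhat) or max_rhat <= rhat_threshold)
    if not converged:
        logger.warning("PSRF above %.2f (max %.3f) for %s", rhat_threshold, max_rhat, spec.label)
    return PosteriorResult(
        spec=spec,
        draws=draws,
        summaries=summaries,
        param_names={"beta": beta_cols, "gamma": gamma_cols, "extra": extra_cols},
        alpha_mean=alpha_acc / max(n_keep_total, 1),
        chains=n_chains,
        n_iter=n_iter,
        n_burn=n_burn,
        seed=seed,
        converged=converged,
        location_ids=ids,
    )


def _marginal_deviance(theta_row, spec, ahat, V, X0, X1, beta_cols, gamma_cols, dist):
    """-2 log N(ahat; X theta, C(theta) + V) with latent effects integrated out."""
    beta = np.asarray([theta_row[c] for c in beta_cols], dtype=float)
    gamma = np.asarray([theta_row[c] for c in gamma_cols], dtype=float)
    n = ahat.shape[0]
    r = np.column_stack([ahat[:, 0] - X0 @ beta, ahat[:, 1] - X1 @ gamma])
    if not spec.spatial_errors:
        s0 = float(theta_row["sigma_eps0"]) ** 2
        s1 = float(theta_row["sigma_eps1"]) ** 2
        M = V.copy()
        M[:, 0, 0] += s0
        M[:, 1, 1] += s1
        Minv, logdet = _inv2x2(M)
        q = np.einsum("ni,nij,nj->n", r, Minv, r)
        ll = -0.5 * float(np.sum(logdet + q)) - n * np.log(2.0 * np.pi)
        return -2.0 * ll
    S0 = exponential_covariance(
        dist, float(theta_row["sigma_eps0"]) ** 2, float(theta_row["phi0"]),
        float(theta_row["tau_eps0"]) ** 2,
    )
    S1 = exponential_covariance(
        dist, float(theta_row["sigma_eps1"]) ** 2, float(theta_row["phi1"]),
        float(theta_row["tau_eps1"]) ** 2,
    )
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = S0
    M[n:, n:] = S1
    idx = np.arange(n)
    M[idx, idx] += V[:, 0, 0]
    M[idx, n + idx] += V[:, 0, 1]
    M[n + idx, idx] += V[:, 1, 0]
    M[n + idx, n + idx] += V[:, 1, 1]
    M[np.diag_indices_from(M)] += 1e-10 * M.diagonal().max()
    L = np.linalg.cholesky(M)
    u = solve_triangular(L, np.concatenate([r[:, 0], r[:, 1]]), lower=True)
    ll = -0.5 * float(u @ u) - float(np.log(np.diag(L)).sum()) - n * np.log(2.0 * np.pi)
    return -2.0 * ll


def compute_dic(
    result: PosteriorResult,
    stage1: list[Stage1Estimate],
    X0: np.ndarray,
    X1: np.ndarray,
    *,
    coords: np.ndarray | None = None,
    planar: bool = False,
    max_eval: int = 200,
) -> tuple[float, float]:
    """DIC = D_bar + pD with pD = D_bar - D(theta_bar), theta_bar the posterior mean.

    The deviance is the marginal normal likelihood of the stage-1 estimates
    given (coefficients, variance parameters), averaged over an evenly
    thinned subset of draws.  A negative pD triggers a warning but the
    value is still returned (a known DIC pathology).
    """
    _, ahat, V = _prepare_stage1(stage1)
    dist = None
    if result.spec.spatial_errors:
        if coords is None:
            raise ValueError("spatial DIC needs coordinates")
        dist = pairwise_distances(np.asarray(coords, dtype=float), planar=planar)
    beta_cols = result.param_names["beta"]
    gamma_cols = result.param_names["gamma"]
    draws = result.draws
    step = max(len(draws) // max_eval, 1)
    sub = draws.iloc[::step]
    devs = [
        _marginal_deviance(row, result.spec, ahat, V, X0, X1, beta_cols, gamma_cols, dist)
        for _, row in sub.iterrows()
    ]
    d_bar = float(np.mean(devs))
    # plug-in posterior mean; positive variance/decay parameters are averaged
    # on the log scale, where their skewed posteriors are near-symmetric —
    # the natural-scale mean is an unrepresentative plug-in and deflates DIC
    theta_bar = draws.drop(columns=["chain"]).mean()
    for col in result.param_names["extra"]:
        theta_bar[col] = float(np.exp(np.log(draws[col].clip(lower=1e-300)).mean()))
    d_hat = _marginal_deviance(
        theta_bar, result.spec, ahat, V, X0, X1, beta_cols, gamma_cols, dist
    )
    p_d = d_bar - d_hat
    if p_d < 0:
        import warnings

        warnings.warn(f"negative pD ({p_d:.2f}) for {result.spec.label}", stacklevel=2)
    result.dic = d_bar + p_d
    result.pd_eff = p_d
    return result.dic, p_d


def select_model(
    stage1: list[Stage1Estimate],
    profiles: list[CovariateProfile],
    *,
    coords: np.ndarray | None = None,
    specs: list[ModelSpec] | None = None,
    n_iter: int = 10_000,
    n_burn: int = 5_000,
    n_chains: int = 3,
    seed: int = 0,
    planar: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Fit candidate model structures and rank them by DIC (ascending).

    Returns the ranked table (spec label, dic, pD, converged, failed) and a
    dict of fitted :class:`PosteriorResult` keyed by label.  A failed fit is
    ranked last rather than aborting the comparison.
    """
    specs = specs or all_model_specs()
    rows, results = [], {}
    for spec in specs:
        try:
            X0, X1, names0, names1 = build_design(profiles, spec)
            res = run_mcmc(
                stage1, X0, X1, spec, coords=coords, n_iter=n_iter, n_burn=n_burn,
                n_chains=n_chains, seed=seed, names0=names0, names1=names1, planar=planar,
            )
            dic, p_d = compute_dic(res, stage1, X0, X1, coords=coords, planar=planar)
            results[spec.label] = res
            rows.append(
                {"spec": spec.label, "dic": dic, "pD": p_d,
                 "converged": res.converged, "failed": False}
            )
        except Exception as exc:  # noqa: BLE001 — a failed spec must not abort the scan
            logger.warning("spec %s failed: %s", spec.label, exc)
            rows.append(
                {"spec": spec.label, "dic": np.inf, "pD": np.nan,
                 "converged": False, "failed": True}
            )
    table = pd.DataFrame(rows).sort_values("dic", kind="stable").reset_index(drop=True)
    table["winner"] = False
    if len(table) and np.isfinite(table.loc[0, "dic"]):
        table.loc[0, "winner"] = True
    return table, results


def summarize_effects(
    result: PosteriorResult, constants: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Effects on the reporting scale: 100*(exp(coef) - 1) percent per 1 SD.

    Covariates are standardized, so beta_k reads as the percent increase in
    the baseline mortality rate per 1-SD increase of covariate k, and
    gamma_k as the percent increase in the PM2.5-mortality rate ratio per
    1-SD of covariate k.  ``constants`` (from standardize_covariates) adds
    the SD used for each covariate when provided.
    """
    rows = []
    sd_map = {}
    if constants is not None:
        sd_map = dict(zip(constants["column"], constants["sd"]))
    for kind, cols in (("main", result.param_names["beta"]),
                       ("modifier", result.param_names["gamma"])):
        prefix = "beta_" if kind == "main" else "gamma_"
        for col in cols:
            name = col[len(prefix):]
            v = result.draws[col].to_numpy()
            pct = 100.0 * (np.exp(v) - 1.0)
            # interval endpoints transform the coefficient percentiles, so
            # they are exact monotone images of the draw quantiles
            rows.append(
                {
                    "effect": kind,
                    "covariate": name,
                    "percent": float(np.mean(pct)),
                    "q2.5": float(100.0 * (np.exp(np.percentile(v, 2.5)) - 1.0)),
                    "q97.5": float(100.0 * (np.exp(np.percentile(v, 97.5)) - 1.0)),
                    "per_sd": float(sd_map.get(name, np.nan)),
                }
            )
    return pd.DataFrame(rows)


def sv_slope_percent(result: PosteriorResult) -> pd.DataFrame:
    """Posterior-mean SV effects: baseline rate per 1,000 and % per 1 μg/m³."""
    pct = 100.0 * (np.exp(result.alpha_mean[:, 1]) - 1.0)
    rate = np.exp(result.alpha_mean[:, 0]) * 1000.0
    return pd.DataFrame(
        {
            "location_id": result.location_ids,
            "baseline_rate_per_1000": rate,
            "slope_percent_per_ugm3": pct,
        }
    )
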