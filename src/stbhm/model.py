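"""Space-time Bayesian hierarchical model for areal pollution panels.

The observation model is a two-level Normal hierarchy with a log-link linear
predictor::

    y_it  ~ Normal(mu_it, sigma0^2)          (observation layer)
    mu_it ~ Normal(theta_it, sigma1^2)       (latent local mean)
    ln(theta_it) = alpha + S_i + (b0 t* + v_t) + b1_i t* + eps_it

where ``alpha`` is the overall log level, ``exp(S_i)`` the local magnitude of
unit i relative to the overall level, ``b0`` the common annual trend on the
log scale with yearly random departures ``v_t``, ``b1_i`` the unit-level
departure from the common trend, and ``eps_it`` an optional over-dispersion
term. ``S_i`` and ``b1_i`` carry Besag-York-Mollié (BYM) priors: an intrinsic
CAR (ICAR) spatially structured component on the Queen contiguity graph plus
an unstructured iid Normal component. Location parameters ``alpha`` and ``b0``
get flat improper priors; every standard deviation gets a half-normal prior.

Inference is Metropolis-within-Gibbs: conjugate Gibbs draws for each latent
``mu_it``, adaptive random-walk Metropolis for everything else, with the ICAR
fields updated in conditionally independent graph-coloring blocks. Structured
fields are recentered each sweep (sum-to-zero; the subtracted means fold into
``alpha``/``b0``), and ``v`` is residualized against (1, t*) for trend
identifiability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import sparse

from .adjacency import AdjacencyStructure
from .panel import SpaceTimePanel

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "ModelState",
    "PosteriorDraws",
    "linear_predictor",
    "car_full_conditional",
    "log_joint_density",
    "run_mcmc",
    "gelman_rubin",
]

_LOG_2PI = math.log(2.0 * math.pi)
_SD_FLOOR = 1e-10


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the hierarchy.

    Flat improper priors on ``alpha`` and ``b0``; independent half-normal
    priors (scale per field, on the standard-deviation scale) for every sd.
    The default scale 10 is weakly informative for data on the scale of tens
    of μg/m³. ``overdispersion=False`` fixes ``eps_it = 0`` (and drops its
    layer from the model); when on, ``sigma_eps`` gets a deliberately tight
    scale because it is only weakly separable from ``sigma1``.
    """

    sigma0_scale: float = 10.0
    sigma1_scale: float = 10.0
    tau_s_scale: float = 10.0
    sd_s_unstruct_scale: float = 10.0
    tau_b1_scale: float = 10.0
    sd_b1_unstruct_scale: float = 10.0
    sd_v_scale: float = 10.0
    sigma_eps_scale: float = 0.05
    overdispersion: bool = True

    def __post_init__(self) -> None:
        for name in (
            "sigma0_scale", "sigma1_scale", "tau_s_scale", "sd_s_unstruct_scale",
            "tau_b1_scale", "sd_b1_unstruct_scale", "sd_v_scale", "sigma_eps_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 3
    n_iter: int = 5000
    n_burnin: int = 2500
    thin: int = 5
    seed: int = 0
    target_acceptance: float = 0.44
    init_step: float = 0.1
    adapt_decay: float = 0.6  # Robbins-Monro exponent, burn-in only

    def __post_init__(self) -> None:
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ModelState:
    """One full configuration of the hierarchy's parameters.

    ``S_i = S_struct_i + S_unstruct_i`` and likewise for ``b1``; ``mu`` is the
    latent (n_units, n_years) mean layer; ``tstar`` holds the centered time
    codes so the linear predictor is self-contained.
    """

    alpha: float
    b0: float
    S_struct: np.ndarray
    S_unstruct: np.ndarray
    b1_struct: np.ndarray
    b1_unstruct: np.ndarray
    v: np.ndarray
    eps: np.ndarray
    mu: np.ndarray
    tstar: np.ndarray
    sigma0: float
    sigma1: float
    sigma_eps: float
    tau_s: float
    sd_s_unstruct: float
    tau_b1: float
    sd_b1_unstruct: float
    sd_v: float

    @property
    def S(self) -> np.ndarray:
        return self.S_struct + self.S_unstruct

    @property
    def b1(self) -> np.ndarray:
        return self.b1_struct + self.b1_unstruct

    def eta(self) -> np.ndarray:
        """(n, T) matrix of log linear predictors."""
        return (
            self.alpha
            + self.S[:, None]
            + self.b0 * self.tstar[None, :]
            + self.v[None, :]
            + self.b1[:, None] * self.tstar[None, :]
            + self.eps
        )


def linear_predictor(state: ModelState, i: int, t: int) -> float:
    """log theta_it = alpha + S_i + b0 t* + v_t + b1_i t* + eps_it."""
    n, T = state.mu.shape
    if not (0 <= i < n and 0 <= t < T):
        raise IndexError(f"(i, t)=({i}, {t}) out of range for {n} units x {T} years")
    ts = state.tstar[t]
    return float(
        state.alpha
        + state.S[i]
        + state.b0 * ts
        + state.v[t]
        + state.b1[i] * ts
        + state.eps[i, t]
    )


def car_full_conditional(
    i: int, fieldvals: np.ndarray, adj: AdjacencyStructure, tau: float
) -> tuple[float, float]:
    """Full conditional of unit i under the intrinsic CAR.

    mean = average of the neighbors' values, variance = tau^2 / m_i. Isolated
    units have no ICAR conditional; callers route them to the unstructured
    component instead.
    """
    nb = adj.neighbors[i]
    if nb.size == 0:
        raise ValueError(f"unit {i} is isolated; no CAR full conditional")
    fieldvals = np.asarray(fieldvals, dtype=float)
    return float(fieldvals[nb].mean()), float(tau**2 / nb.size)


def _norm_logpdf_sum(x: np.ndarray, mean, sd: float) -> float:
    resid = np.asarray(x, dtype=float) - mean
    return float(-0.5 * np.sum(resid**2) / sd**2 - x.size * (math.log(sd) + 0.5 * _LOG_2PI))


def _halfnormal_logpdf(sd: float, scale: float) -> float:
    if sd < 0:
        return -np.inf
    return 0.5 * math.log(2.0 / math.pi) - math.log(scale) - 0.5 * (sd / scale) ** 2


def _icar_logkernel(fieldvals: np.ndarray, adj: AdjacencyStructure, tau: float) -> float:
    """Improper ICAR log-density kernel.

    -(n - c) log tau - (1 / 2 tau^2) * sum_{i<j} w_ij (x_i - x_j)^2, where c is
    the number of connected components (the rank deficiency). Isolated units
    contribute nothing.
    """
    L = adj.laplacian()
    q = float(fieldvals @ L @ fieldvals)
    rank = adj.n_units - adj.n_components
    return -rank * math.log(tau) - 0.5 * q / tau**2


def log_joint_density(
    state: ModelState,
    panel: SpaceTimePanel,
    adj: AdjacencyStructure,
    priors: PriorSpec,
) -> float:
    """Log of the unnormalized joint density of data and parameters.

    Normal layers keep their full normalizing constants; the improper ICAR
    kernels and the flat priors on alpha/b0 contribute only their kernels.
    """
    for name in ("sigma0", "sigma1", "tau_s", "sd_s_unstruct", "tau_b1",
                 "sd_b1_unstruct", "sd_v"):
        if getattr(state, name) <= 0:
            raise ValueError(f"{name} must be > 0")
    theta = np.exp(state.eta())
    lp = _norm_logpdf_sum(panel.values, state.mu, state.sigma0)
    lp += _norm_logpdf_sum(state.mu, theta, state.sigma1)
    lp += _icar_logkernel(state.S_struct, adj, state.tau_s)
    lp += _norm_logpdf_sum(state.S_unstruct, 0.0, state.sd_s_unstruct)
    lp += _icar_logkernel(state.b1_struct, adj, state.tau_b1)
    lp += _norm_logpdf_sum(state.b1_unstruct, 0.0, state.sd_b1_unstruct)
    lp += _norm_logpdf_sum(state.v, 0.0, state.sd_v)
    lp += _halfnormal_logpdf(state.sigma0, priors.sigma0_scale)
    lp += _halfnormal_logpdf(state.sigma1, priors.sigma1_scale)
    lp += _halfnormal_logpdf(state.tau_s, priors.tau_s_scale)
    lp += _halfnormal_logpdf(state.sd_s_unstruct, priors.sd_s_unstruct_scale)
    lp += _halfnormal_logpdf(state.tau_b1, priors.tau_b1_scale)
    lp += _halfnormal_logpdf(state.sd_b1_unstruct, priors.sd_b1_unstruct_scale)
    lp += _halfnormal_logpdf(state.sd_v, priors.sd_v_scale)
    if priors.overdispersion:
        if state.sigma_eps <= 0:
            raise ValueError("sigma_eps must be > 0 when overdispersion is on")
        lp += _norm_logpdf_sum(state.eps, 0.0, state.sigma_eps)
        lp += _halfnormal_logpdf(state.sigma_eps, priors.sigma_eps_scale)
    return lp


@dataclass
class PosteriorDraws:
    """MCMC output: per-parameter arrays indexed (chain, draw[, dim]).

    Scalar parameters: ``alpha``, ``b0``, the standard deviations. Vector
    parameters: ``S`` (= structured + unstructured), ``b1``, ``v``. Burn-in
    has been discarded and thinning applied.
    """

    draws: dict[str, np.ndarray]
    years: np.ndarray
    thin: int
    n_burnin: int
    acceptance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {k: v.shape[:2] for k, v in self.draws.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"inconsistent (chain, draw) shapes: {shapes}")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of ``name`` with chains concatenated along the first axis."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def names(self) -> list[str]:
        return sorted(self.draws)


def gelman_rubin(draws: PosteriorDraws | np.ndarray, parameter: str | None = None):
    """Potential scale reduction factor R-hat.

    Classic formula: with m chains of length n, within-chain variance W (mean
    of per-chain sample variances) and between-chain variance B (n times the
    variance of chain means), ``R-hat = sqrt(((n-1)/n * W + B/n) / W)``.
    Values below 1 (possible when B ~ 0) are reported as 1.0. For vector
    parameters an array of per-component R-hats is returned.
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required")
        arr = draws.draws[parameter]
    else:
        arr = np.asarray(draws, dtype=float)
    if arr.ndim < 2 or arr.shape[0] < 2:
        raise ValueError("R-hat needs >= 2 chains")
    if arr.shape[1] < 2:
        raise ValueError("R-hat needs >= 2 draws per chain")
    n = arr.shape[1]
    chain_means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    rhat = np.where(np.isfinite(rhat), rhat, 1.0)
    rhat = np.maximum(rhat, 1.0)
    return float(rhat) if rhat.ndim == 0 else rhat


# ---------------------------------------------------------------------------
# Sampler internals
# ---------------------------------------------------------------------------


class _AdaptiveStep:
    """Robbins-Monro adapted random-walk scale (scalar or per-component)."""

    def __init__(self, shape, init: float, target: float, decay: float):
        self.log_step = np.full(shape, math.log(init))
        self.target = target
        self.decay = decay

    @property
    def step(self) -> np.ndarray:
        return np.exp(self.log_step)

    def adapt(self, accepted, sweep: int) -> None:
        gamma = (sweep + 1.0) ** (-self.decay)
        self.log_step += gamma * (np.asarray(accepted, dtype=float) - self.target)


class _Sampler:
    """One chain of the Metropolis-within-Gibbs sampler."""

    def __init__(
        self,
        panel: SpaceTimePanel,
        adj: AdjacencyStructure,
        priors: PriorSpec,
        config: MCMCConfig,
        rng: np.random.Generator,
    ):
        self.y = panel.values
        self.n, self.T = self.y.shape
        if adj.n_units != self.n:
            raise ValueError("adjacency does not cover all panel units")
        self.adj = adj
        self.priors = priors
        self.config = config
        self.rng = rng
        self.tstar = panel.tstar
        self.sum_t2 = float(np.sum(self.tstar**2))
        self.W = adj.weights_sparse()
        self.degrees = adj.degrees.astype(float)
        self.colors = [c for c in adj.greedy_coloring()]
        self.connected = self.degrees > 0
        self.icar_rank = adj.n_units - adj.n_components
        self.comp_labels = adj.connected_components()

        self._init_state()
        self._init_steps()

    # -- initialization ----------------------------------------------------

    def _init_state(self) -> None:
        y = self.y
        ybar = max(float(y.mean()), 1e-6)
        logrow = np.log(np.clip(y.mean(axis=1), 1e-6, None))
        logcol = np.log(np.clip(y.mean(axis=0), 1e-6, None))
        alpha = float(logrow.mean())
        b0 = float(self.tstar @ (logcol - logcol.mean()) / self.sum_t2)
        S = logrow - alpha
        sd0 = max(0.05 * ybar, 1e-3)
        self.state = ModelState(
            alpha=alpha,
            b0=b0,
            S_struct=self._center_components(S),
            S_unstruct=np.zeros(self.n),
            b1_struct=np.zeros(self.n),
            b1_unstruct=np.zeros(self.n),
            v=np.zeros(self.T),
            eps=np.zeros((self.n, self.T)),
            mu=y.copy(),
            tstar=self.tstar,
            sigma0=sd0,
            sigma1=sd0,
            sigma_eps=0.5 * self.priors.sigma_eps_scale,
            tau_s=0.1,
            sd_s_unstruct=0.1,
            tau_b1=0.01,
            sd_b1_unstruct=0.01,
            sd_v=0.05,
        )
        self.theta = np.exp(self.state.eta())

    def _center_components(self, x: np.ndarray) -> np.ndarray:
        out = x.copy()
        labels = self.adj.connected_components()
        for c in np.unique(labels):
            sel = labels == c
            out[sel] -= out[sel].mean()
        return out

    def _init_steps(self) -> None:
        cfg = self.config
        mk = lambda shape, s: _AdaptiveStep(shape, s, cfg.target_acceptance, cfg.adapt_decay)
        self.steps = {
            "alpha": mk((), 0.2 * cfg.init_step),
            "b0": mk((), 0.02 * cfg.init_step),
            "S_struct": mk(self.n, cfg.init_step),
            "S_unstruct": mk(self.n, cfg.init_step),
            "b1_struct": mk(self.n, 0.1 * cfg.init_step),
            "b1_unstruct": mk(self.n, 0.1 * cfg.init_step),
            "v": mk(self.T, 0.5 * cfg.init_step),
            "eps": mk((self.n, self.T), 0.5 * cfg.init_step),
            "sigma0": mk((), 0.3),
            "sigma1": mk((), 0.3),
            "sigma_eps": mk((), 0.3),
            "tau_s": mk((), 0.3),
            "sd_s_unstruct": mk((), 0.3),
            "tau_b1": mk((), 0.3),
            "sd_b1_unstruct": mk((), 0.3),
            "sd_v": mk((), 0.3),
        }
        self.acc_counts: dict[str, float] = {k: 0.0 for k in self.steps}
        self.acc_trials: dict[str, float] = {k: 0.0 for k in self.steps}

    # -- likelihood pieces -------------------------------------------------

    def _ll_mu_rows(self, theta_rows: np.ndarray, rows: np.ndarray) -> np.ndarray:
        """Per-row sum of -(mu - theta)^2 / (2 sigma1^2) for the given rows."""
        resid = self.state.mu[rows] - theta_rows
        return -0.5 * np.sum(resid**2, axis=1) / self.state.sigma1**2

    def _record_acc(self, name: str, accepted, sweep: int, adapting: bool) -> None:
        acc = np.asarray(accepted, dtype=float)
        self.acc_counts[name] += float(acc.sum())
        self.acc_trials[name] += acc.size
        if adapting:
            self.steps[name].adapt(acc, sweep)

    # -- update blocks -----------------------------------------------------

    def _gibbs_mu(self) -> None:
        st = self.state
        prec = 1.0 / st.sigma0**2 + 1.0 / st.sigma1**2
        mean = (self.y / st.sigma0**2 + self.theta / st.sigma1**2) / prec
        st.mu = mean + self.rng.standard_normal((self.n, self.T)) / math.sqrt(prec)

    def _update_scalar_level(self, name: str, sweep: int, adapting: bool) -> None:
        """RW Metropolis for alpha or b0 (flat priors: likelihood only)."""
        st = self.state
        step = float(self.steps[name].step)
        delta = step * self.rng.standard_normal()
        if name == "alpha":
            theta_new = self.theta * math.exp(delta)
        else:
            theta_new = self.theta * np.exp(delta * self.tstar[None, :])
        ll_old = -0.5 * np.sum((st.mu - self.theta) ** 2) / st.sigma1**2
        ll_new = -0.5 * np.sum((st.mu - theta_new) ** 2) / st.sigma1**2
        accept = math.log(self.rng.random()) < ll_new - ll_old
        if accept:
            setattr(st, name, getattr(st, name) + delta)
            self.theta = theta_new
        self._record_acc(name, accept, sweep, adapting)

    def _update_struct_field(self, name: str, sweep: int, adapting: bool) -> None:
        """Color-blocked single-site updates of an ICAR field (S or b1)."""
        st = self.state
        fieldvals = getattr(st, name)
        tau = st.tau_s if name == "S_struct" else st.tau_b1
        trend = name == "b1_struct"
        steps = self.steps[name].step
        accepted = np.zeros(self.n)
        for cls in self.colors:
            cls_c = cls[self.connected[cls]]  # isolated units: unstructured only
            if cls_c.size == 0:
                continue
            delta = steps[cls_c] * self.rng.standard_normal(cls_c.size)
            old = fieldvals[cls_c]
            new = old + delta
            if trend:
                fac = np.exp(delta[:, None] * self.tstar[None, :])
            else:
                fac = np.exp(delta)[:, None]
            theta_new = self.theta[cls_c] * fac
            dll = self._ll_mu_rows(theta_new, cls_c) - self._ll_mu_rows(
                self.theta[cls_c], cls_c
            )
            nbr_sum = np.asarray(self.W[cls_c] @ fieldvals).ravel()
            m = self.degrees[cls_c]
            dprior = -0.5 / tau**2 * (
                m * (new**2 - old**2) - 2.0 * (new - old) * nbr_sum
            )
            acc = np.log(self.rng.random(cls_c.size)) < dll + dprior
            fieldvals[cls_c] = np.where(acc, new, old)
            self.theta[cls_c] = np.where(acc[:, None], theta_new, self.theta[cls_c])
            accepted[cls_c] = acc
        self._record_acc(name, accepted[self.connected], sweep, adapting)

    def _update_unstruct_field(self, name: str, sweep: int, adapting: bool) -> None:
        """Simultaneous independent RW updates of an iid-Normal field."""
        st = self.state
        fieldvals = getattr(st, name)
        sd = st.sd_s_unstruct if name == "S_unstruct" else st.sd_b1_unstruct
        trend = name == "b1_unstruct"
        delta = self.steps[name].step * self.rng.standard_normal(self.n)
        old = fieldvals
        new = old + delta
        if trend:
            fac = np.exp(delta[:, None] * self.tstar[None, :])
        else:
            fac = np.exp(delta)[:, None]
        theta_new = self.theta * fac
        rows = np.arange(self.n)
        dll = self._ll_mu_rows(theta_new, rows) - self._ll_mu_rows(self.theta, rows)
        dprior = -0.5 * (new**2 - old**2) / sd**2
        acc = np.log(self.rng.random(self.n)) < dll + dprior
        setattr(st, name, np.where(acc, new, old))
        self.theta = np.where(acc[:, None], theta_new, self.theta)
        self._record_acc(name, acc, sweep, adapting)

    def _update_v(self, sweep: int, adapting: bool) -> None:
        st = self.state
        delta = self.steps["v"].step * self.rng.standard_normal(self.T)
        new = st.v + delta
        theta_new = self.theta * np.exp(delta)[None, :]
        resid_old = st.mu - self.theta
        resid_new = st.mu - theta_new
        dll = -0.5 * (np.sum(resid_new**2, axis=0) - np.sum(resid_old**2, axis=0)) / st.sigma1**2
        dprior = -0.5 * (new**2 - st.v**2) / st.sd_v**2
        acc = np.log(self.rng.random(self.T)) < dll + dprior
        st.v = np.where(acc, new, st.v)
        self.theta = np.where(acc[None, :], theta_new, self.theta)
        self._record_acc("v", acc, sweep, adapting)

    def _update_eps(self, sweep: int, adapting: bool) -> None:
        st = self.state
        delta = self.steps["eps"].step * self.rng.standard_normal((self.n, self.T))
        new = st.eps + delta
        theta_new = self.theta * np.exp(delta)
        dll = (
            -0.5 * ((st.mu - theta_new) ** 2 - (st.mu - self.theta) ** 2) / st.sigma1**2
        )
        dprior = -0.5 * (new**2 - st.eps**2) / st.sigma_eps**2
        acc = np.log(self.rng.random((self.n, self.T))) < dll + dprior
        st.eps = np.where(acc, new, st.eps)
        self.theta = np.where(acc, theta_new, self.theta)
        self._record_acc("eps", acc, sweep, adapting)

    def _update_sd(self, name: str, scale: float, loglik, sweep: int, adapting: bool) -> None:
        """Log-scale RW Metropolis for a standard deviation.

        Target includes the half-normal prior and the log-scale Jacobian.
        ``loglik(sd)`` returns the log-likelihood terms governed by this sd.
        """
        st = self.state
        old = getattr(st, name)
        step = float(self.steps[name].step)
        new = old * math.exp(step * self.rng.standard_normal())
        new = max(new, _SD_FLOOR)
        dtarget = (
            loglik(new)
            - loglik(old)
            + _halfnormal_logpdf(new, scale)
            - _halfnormal_logpdf(old, scale)
            + math.log(new)
            - math.log(old)
        )
        accept = math.log(self.rng.random()) < dtarget
        if accept:
            setattr(st, name, new)
        self._record_acc(name, accept, sweep, adapting)

    def _update_all_sds(self, sweep: int, adapting: bool) -> None:
        st, pr = self.state, self.priors
        y, NT = self.y, self.n * self.T

        sse_y = float(np.sum((y - st.mu) ** 2))
        self._update_sd(
            "sigma0", pr.sigma0_scale,
            lambda s: -NT * math.log(s) - 0.5 * sse_y / s**2, sweep, adapting,
        )
        sse_mu = float(np.sum((st.mu - self.theta) ** 2))
        self._update_sd(
            "sigma1", pr.sigma1_scale,
            lambda s: -NT * math.log(s) - 0.5 * sse_mu / s**2, sweep, adapting,
        )
        L = self.degrees * st.S_struct - np.asarray(self.W @ st.S_struct).ravel()
        q_s = float(st.S_struct @ L)
        self._update_sd(
            "tau_s", pr.tau_s_scale,
            lambda s: -self.icar_rank * math.log(s) - 0.5 * q_s / s**2, sweep, adapting,
        )
        ss = float(np.sum(st.S_unstruct**2))
        self._update_sd(
            "sd_s_unstruct", pr.sd_s_unstruct_scale,
            lambda s: -self.n * math.log(s) - 0.5 * ss / s**2, sweep, adapting,
        )
        Lb = self.degrees * st.b1_struct - np.asarray(self.W @ st.b1_struct).ravel()
        q_b = float(st.b1_struct @ Lb)
        self._update_sd(
            "tau_b1", pr.tau_b1_scale,
            lambda s: -self.icar_rank * math.log(s) - 0.5 * q_b / s**2, sweep, adapting,
        )
        sb = float(np.sum(st.b1_unstruct**2))
        self._update_sd(
            "sd_b1_unstruct", pr.sd_b1_unstruct_scale,
            lambda s: -self.n * math.log(s) - 0.5 * sb / s**2, sweep, adapting,
        )
        sv = float(np.sum(st.v**2))
        self._update_sd(
            "sd_v", pr.sd_v_scale,
            lambda s: -self.T * math.log(s) - 0.5 * sv / s**2, sweep, adapting,
        )
        if pr.overdispersion:
            se = float(np.sum(st.eps**2))
            self._update_sd(
                "sigma_eps", pr.sigma_eps_scale,
                lambda s: -NT * math.log(s) - 0.5 * se / s**2, sweep, adapting,
            )

    def _recenter(self) -> None:
        """Identifiability sweep: eta-preserving reparameterization.

        Means of the structured fields fold into alpha / b0; v is residualized
        against (1, t*) with the fitted line folded into (alpha, b0).
        """
        st = self.state
        # Global shifts leave eta and the ICAR kernels invariant; they are the
        # flat directions the improper priors cannot identify.
        m = float(st.S_struct.mean())
        st.S_struct -= m
        st.alpha += m
        mb = float(st.b1_struct.mean())
        st.b1_struct -= mb
        st.b0 += mb
        a = float(st.v.mean())
        b = float(st.v @ self.tstar / self.sum_t2)
        st.v = st.v - a - b * self.tstar
        st.alpha += a
        st.b0 += b
        self.theta = np.exp(st.eta())

    # -- main loop ---------------------------------------------------------

    def run(self) -> dict[str, np.ndarray]:
        cfg = self.config
        n_keep = (cfg.n_iter - cfg.n_burnin) // cfg.thin
        rec: dict[str, np.ndarray] = {
            "alpha": np.empty(n_keep),
            "b0": np.empty(n_keep),
            "S": np.empty((n_keep, self.n)),
            "b1": np.empty((n_keep, self.n)),
            "v": np.empty((n_keep, self.T)),
            "sigma0": np.empty(n_keep),
            "sigma1": np.empty(n_keep),
            "tau_s": np.empty(n_keep),
            "sd_s_unstruct": np.empty(n_keep),
            "tau_b1": np.empty(n_keep),
            "sd_b1_unstruct": np.empty(n_keep),
            "sd_v": np.empty(n_keep),
        }
        if self.priors.overdispersion:
            rec["sigma_eps"] = np.empty(n_keep)
        k = 0
        for sweep in range(cfg.n_iter):
            adapting = sweep < cfg.n_burnin
            self._gibbs_mu()
            self._update_scalar_level("alpha", sweep, adapting)
            self._update_scalar_level("b0", sweep, adapting)
            self._update_struct_field("S_struct", sweep, adapting)
            self._update_unstruct_field("S_unstruct", sweep, adapting)
            self._update_struct_field("b1_struct", sweep, adapting)
            self._update_unstruct_field("b1_unstruct", sweep, adapting)
            self._update_v(sweep, adapting)
            if self.priors.overdispersion:
                self._update_eps(sweep, adapting)
            self._update_all_sds(sweep, adapting)
            self._recenter()
            if not np.isfinite(self.state.alpha) or not np.all(np.isfinite(self.theta)):
                raise FloatingPointError(
                    f"NaN/inf in sampler state at sweep {sweep}: "
                    f"alpha={self.state.alpha}, sigma1={self.state.sigma1}"
                )
            if sweep >= cfg.n_burnin and (sweep - cfg.n_burnin) % cfg.thin == 0 and k < n_keep:
                st = self.state
                rec["alpha"][k] = st.alpha
                rec["b0"][k] = st.b0
                rec["S"][k] = st.S
                rec["b1"][k] = st.b1
                rec["v"][k] = st.v
                rec["sigma0"][k] = st.sigma0
                rec["sigma1"][k] = st.sigma1
                rec["tau_s"][k] = st.tau_s
                rec["sd_s_unstruct"][k] = st.sd_s_unstruct
                rec["tau_b1"][k] = st.tau_b1
                rec["sd_b1_unstruct"][k] = st.sd_b1_unstruct
                rec["sd_v"][k] = st.sd_v
                if self.priors.overdispersion:
                    rec["sigma_eps"][k] = st.sigma_eps
                k += 1
        return rec

    def acceptance_rates(self) -> dict[str, float]:
        return {
            k: self.acc_counts[k] / self.acc_trials[k]
            for k in self.acc_counts
            if self.acc_trials[k] > 0
        }


def run_mcmc(
    panel: SpaceTimePanel,
    adj: AdjacencyStructure,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Fit the hierarchy by Metropolis-within-Gibbs MCMC.

    Chains are independently seeded from ``config.seed`` and run sequentially;
    identical inputs give bit-identical draws. Burn-in is discarded and
    thinning applied before draws are returned.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    per_chain: list[dict[str, np.ndarray]] = []
    acc: dict[str, float] = {}
    for c in range(config.n_chains):
        sampler = _Sampler(panel, adj, priors, config, np.random.Generator(np.random.PCG64(seeds[c])))
        per_chain.append(sampler.run())
        for k, v in sampler.acceptance_rates().items():
            acc[k] = acc.get(k, 0.0) + v / config.n_chains
    draws = {
        name: np.stack([chain[name] for chain in per_chain], axis=0)
        for name in per_chain[0]
    }
    return PosteriorDraws(
        draws=draws,
        years=panel.years,
        thin=config.thin,
        n_burnin=config.n_burnin,
        acceptance=acc,
    )
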