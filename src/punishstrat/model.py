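"""Bayesian latent-state mixture model for punishment strategies.

The model assumes each participant follows one of S latent strategies: the
deterministic strategies of the prescription matrix plus a random-choice
strategy. A deterministic strategy s prescribes a binary decision for each
of the twelve contexts j; with implementation error rate delta the
conditional probability of punishing is 1 - delta where the strategy
prescribes punishment and delta where it does not. Random choice punishes
with probability 1/2 everywhere.

Membership probabilities are modelled with a softmax over per-strategy
linear predictors. In the base model each country c has its own intercept
vector:

    y_ij ~ Bernoulli(theta_j)
    theta_j = sum_s p_s Pr(punish | s, j)
    p = softmax(alpha_c[i])        alpha_sc ~ Normal(0, 1)

A continuous covariate x enters through per-country, per-strategy slopes,
p_i = softmax(alpha_c[i] + beta_c[i] * x_i) with beta_sc ~ Normal(0, 0.2);
a categorical covariate gets its own intercept vector per (country, level).
The softmax runs over all S strategies with no reference category; the
additive non-identifiability is handled by the Normal(0, 1) prior and only
p (never alpha) is reported.

Two likelihood factorizations are provided. The default, participant-level
mode marginalizes the latent strategy once per participant,

    L_i = sum_s p_si  prod_j Bernoulli(y_ij | Pr(punish | s, j)),

respecting within-participant dependence — the canonical treatment of a
latent discrete state. The decision-level alternative mixes over strategies
independently at every decision, exactly as the display above reads; it is
kept because the display is how the model is usually written, but it
identifies the simplex only up to a 2-dimensional null space (the
delta-contaminated kernel has affine rank 7, so the twelve marginal punish
rates cannot pin down ten strategy weights) and is therefore unsuitable
for estimation. The two modes coincide for point-mass mixtures and are
compared empirically in the validation module.

Posterior inference uses an affine-invariant ensemble MCMC sampler
(``emcee``) on fully vectorized log-posteriors; walkers are grouped into
pseudo-chains for R-hat and effective-sample-size diagnostics (``arviz``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import logsumexp, xlogy

from .classify import DECISION_COLUMNS
from .strategies import PredictionMatrix, RANDOM_CHOICE, base_matrix

__all__ = [
    "ConditionalProbTable",
    "ModelConfig",
    "PosteriorDraws",
    "ConvergenceWarning",
    "conditional_probs",
    "mixture_theta",
    "log_likelihood",
    "fit_base",
    "fit_predictor",
    "fit_free_delta",
    "membership_probabilities",
    "summarize",
]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when MCMC diagnostics fail their gates."""


# ---------------------------------------------------------------------------
# Conditional probability table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionalProbTable:
    """Pr(punish | strategy, decision) after delta-contamination.

    Rows are the deterministic strategies of the source matrix followed by
    the random-choice strategy, whose row is exactly 1/2 everywhere.
    """

    labels: tuple[str, ...]
    probs: np.ndarray  # (S, 12)
    delta: float
    prescriptions: np.ndarray  # (S-1, 12) binary rows of the source matrix

    @property
    def n_strategies(self) -> int:
        return len(self.labels)

    def row(self, label: str) -> np.ndarray:
        return self.probs[self.labels.index(label)]


def conditional_probs(matrix: PredictionMatrix, delta: float) -> ConditionalProbTable:
    """Contaminate a prescription matrix with implementation error *delta*.

    Prescribed punishments become probability ``1 - delta``, prescribed
    abstentions ``delta``, and a random-choice row fixed at 1/2 is
    appended. ``delta`` must lie in [0, 0.5): at 0.5 every deterministic
    row would equal the random row and the strategies would be
    unidentifiable.
    """
    if not 0 <= delta < 0.5:
        raise ValueError(f"delta must lie in [0, 0.5), got {delta}")
    pres = matrix.values.astype(float)
    probs = pres * (1 - delta) + (1 - pres) * delta
    probs = np.vstack([probs, np.full(matrix.n_decisions, 0.5)])
    return ConditionalProbTable(
        labels=tuple(matrix.labels) + (RANDOM_CHOICE,),
        probs=probs,
        delta=float(delta),
        prescriptions=matrix.values.copy(),
    )


def mixture_theta(p: Sequence[float] | np.ndarray, table: ConditionalProbTable,
                  j: int | None = None) -> float | np.ndarray:
    """Marginal punish probability theta_j = sum_s p_s Pr(punish | s, j).

    With ``j`` given, returns the scalar for that decision; otherwise the
    full 12-vector.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (table.n_strategies,):
        raise ValueError(
            f"p must have length {table.n_strategies}, got {p.shape}"
        )
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("p must sum to 1")
    theta = p @ table.probs
    return float(theta[j]) if j is not None else theta


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _participant_probs(data: pd.DataFrame, p, n_strat: int) -> np.ndarray:
    """Resolve a p argument to an (n, S) per-participant membership array."""
    n = len(data)
    if isinstance(p, Mapping):
        countries = data["country"].to_numpy()
        out = np.empty((n, n_strat))
        for c in np.unique(countries):
            try:
                vec = np.asarray(p[c], dtype=float)
            except KeyError:
                raise ValueError(f"no membership simplex for country {c!r}") from None
            out[countries == c] = vec
        return out
    arr = np.asarray(p, dtype=float)
    if arr.ndim == 1:
        return np.broadcast_to(arr, (n, n_strat)).copy()
    if arr.shape != (n, n_strat):
        raise ValueError(f"p has shape {arr.shape}, expected ({n}, {n_strat})")
    return arr


def _strategy_loglik(y: np.ndarray, table: ConditionalProbTable) -> np.ndarray:
    """(n, S) log-likelihood of each participant's vector under each strategy.

    Missing decisions (NaN) contribute nothing.
    """
    obs = ~np.isnan(y)
    y0 = np.nan_to_num(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = xlogy(y0[:, None, :], table.probs[None, :, :]) \
            + xlogy(1 - y0[:, None, :], 1 - table.probs[None, :, :])
    ll = np.where(obs[:, None, :], ll, 0.0)
    return ll.sum(axis=2)


def log_likelihood(data: pd.DataFrame, p, table: ConditionalProbTable,
                   mode: str = "decision") -> float:
    """Log-likelihood of a decision dataset under membership probabilities.

    Parameters
    ----------
    data : DataFrame
        Wide decision table (``id``, ``country``, twelve decision columns;
        NaN marks missing decisions, which contribute nothing).
    p : mapping, 1-d array or (n, S) array
        Membership simplex per country, a single simplex shared by all
        participants, or one simplex per participant (as produced by the
        covariate model).
    table : ConditionalProbTable
        The delta-contaminated mixture kernel.
    mode : {"decision", "participant"}
        Decision-level mixes over strategies at every decision
        independently; participant-level marginalizes the strategy once
        per participant.
    """
    y = data[DECISION_COLUMNS].to_numpy(dtype=float)
    P = _participant_probs(data, p, table.n_strategies)
    if mode == "decision":
        theta = P @ table.probs  # (n, 12)
        obs = ~np.isnan(y)
        y0 = np.nan_to_num(y)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = xlogy(y0, theta) + xlogy(1 - y0, 1 - theta)
        return float(np.where(obs, ll, 0.0).sum())
    if mode == "participant":
        L = _strategy_loglik(y, table)  # (n, S)
        with np.errstate(divide="ignore"):
            logP = np.log(P)
        return float(logsumexp(logP + L, axis=1).sum())
    raise ValueError(f"unknown likelihood mode {mode!r}")


# ---------------------------------------------------------------------------
# Configuration and posterior container
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Sampler and prior settings.

    ``samples`` is the total iterations per chain including ``warmup``
    (default 2000 with 1000 warmup). ``delta`` is either a fixed error
    rate or the string ``"free"``; the free-delta variant places a
    Uniform(0, 0.5) prior on delta. ``mode`` selects the likelihood
    factorization.
    """

    delta: float | str = 0.05
    samples: int = 2000
    warmup: int = 1000
    chains: int = 4
    seed: int = 0
    mode: str = "participant"
    prior_alpha: float = 1.0
    prior_beta: float = 0.2
    rhat_max: float = 1.01
    ess_min: float = 400.0

    def __post_init__(self) -> None:
        if self.warmup >= self.samples:
            raise ValueError("warmup must be smaller than samples")
        if self.prior_alpha <= 0 or self.prior_beta <= 0:
            raise ValueError("prior scales must be positive")
        if self.mode not in ("decision", "participant"):
            raise ValueError(f"unknown likelihood mode {self.mode!r}")
        if self.delta != "free" and not 0 <= float(self.delta) < 0.5:
            raise ValueError("fixed delta must lie in [0, 0.5)")


@dataclass
class PosteriorDraws:
    """Posterior draws and diagnostics from one model fit.

    ``p`` has shape (chains, draws, groups, strategies); ``alpha`` matches,
    ``beta`` is present for continuous-covariate fits and ``delta_draws``
    (chains, draws) for free-delta fits. ``groups`` are countries, or
    country:level cells for a categorical covariate.
    """

    strategy_labels: list[str]
    groups: list[str]
    alpha: np.ndarray
    p: np.ndarray
    diagnostics: dict
    config: ModelConfig
    matrix: PredictionMatrix
    beta: np.ndarray | None = None
    delta_draws: np.ndarray | None = None
    covariate: str | None = None
    covariate_scaling: tuple[float, float] | None = None  # (mean, sd)
    converged: bool = True

    @property
    def n_draws(self) -> int:
        return self.p.shape[0] * self.p.shape[1]

    def p_flat(self) -> np.ndarray:
        """All p draws pooled over chains: (total draws, groups, strategies)."""
        return self.p.reshape(-1, *self.p.shape[2:])

    def table(self) -> ConditionalProbTable:
        """Mixture kernel at the fixed delta (or the posterior median delta)."""
        if self.delta_draws is not None:
            d = float(np.median(self.delta_draws))
        else:
            d = float(self.config.delta)
        return conditional_probs(self.matrix, d)

    def to_frame(self) -> pd.DataFrame:
        """Long-format draw table (one row per chain, draw, group, strategy)."""
        chains, draws, G, S = self.p.shape
        idx = pd.MultiIndex.from_product(
            [range(chains), range(draws), self.groups, self.strategy_labels],
            names=["chain", "draw", "group", "strategy"],
        )
        frame = pd.DataFrame({"p": self.p.ravel(), "alpha": self.alpha.ravel()},
                             index=idx).reset_index()
        if self.beta is not None:
            frame["beta"] = self.beta.ravel()
        if self.delta_draws is not None:
            frame["delta"] = np.repeat(self.delta_draws.ravel(), G * S)
        return frame

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Log-posterior construction (vectorized over walkers)
# ---------------------------------------------------------------------------

def _softmax(eta: np.ndarray) -> np.ndarray:
    eta = eta - eta.max(axis=-1, keepdims=True)
    p = np.exp(eta)
    return p / p.sum(axis=-1, keepdims=True)


class _SufficientStats:
    """Per-group punish / no-punish counts for the decision-level likelihood."""

    def __init__(self, data: pd.DataFrame, group_codes: np.ndarray, n_groups: int):
        y = data[DECISION_COLUMNS].to_numpy(dtype=float)
        J = y.shape[1]
        self.n1 = np.zeros((n_groups, J))
        self.n0 = np.zeros((n_groups, J))
        for g in range(n_groups):
            block = y[group_codes == g]
            self.n1[g] = np.nansum(block, axis=0)
            self.n0[g] = np.sum(~np.isnan(block), axis=0) - self.n1[g]


def _delta_probs(prescriptions: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """(W, S, J) conditional-probability tables for per-walker deltas."""
    d = delta[:, None, None]
    pres = prescriptions[None, :, :]
    det = pres * (1 - d) + (1 - pres) * d  # (W, S-1, J)
    rand = np.full((delta.shape[0], 1, prescriptions.shape[1]), 0.5)
    return np.concatenate([det, rand], axis=1)


class _LogPosterior:
    """Vectorized log-posterior over an ensemble of walkers.

    Parameter layout per walker: alpha (G*S,), then beta (G*S,) if a
    continuous covariate is present, then delta if free.
    """

    def __init__(self, data: pd.DataFrame, matrix: PredictionMatrix,
                 config: ModelConfig, groups: list[str],
                 group_codes: np.ndarray, x: np.ndarray | None = None):
        self.config = config
        self.matrix = matrix
        self.G = len(groups)
        self.S = matrix.n_strategies + 1
        self.x = x
        self.free_delta = config.delta == "free"
        self.group_codes = group_codes
        self.ndim = self.G * self.S * (2 if x is not None else 1) \
            + (1 if self.free_delta else 0)
        if not self.free_delta:
            self.fixed_table = conditional_probs(matrix, float(config.delta))
        y = data[DECISION_COLUMNS].to_numpy(dtype=float)
        self.obs = ~np.isnan(y)
        self.y0 = np.nan_to_num(y)
        if config.mode == "decision" and x is None:
            self.stats = _SufficientStats(data, group_codes, self.G)
        if config.mode == "participant":
            # Per-strategy likelihoods depend on y only through the count of
            # decisions agreeing with each deterministic prescription (plus
            # the number observed), so participants sharing those counts and
            # a group are collapsed into weighted pattern classes. With a
            # covariate each participant is its own class.
            pres = matrix.values
            agree = (self.y0[:, None, :] == pres[None, :, :]) & self.obs[:, None, :]
            match = agree.sum(axis=2)                 # (n, S-1)
            n_obs = self.obs.sum(axis=1)              # (n,)
            if x is None:
                key = np.column_stack([group_codes, match, n_obs])
                uniq, counts = np.unique(key, axis=0, return_counts=True)
                self.c_group = uniq[:, 0]
                self.c_match = uniq[:, 1:-1]
                self.c_nobs = uniq[:, -1]
                self.c_weight = counts.astype(float)
            else:
                self.c_group = group_codes
                self.c_match = match
                self.c_nobs = n_obs
                self.c_weight = np.ones(len(data))
            if not self.free_delta:
                d = float(config.delta)
                det = xlogy(self.c_match, 1 - d) \
                    + xlogy(self.c_nobs[:, None] - self.c_match, d)
                rand = self.c_nobs[:, None] * np.log(0.5)
                self.cL = np.concatenate([det, rand], axis=1)  # (U, S)

    # -- pieces -----------------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        W = theta.shape[0]
        G, S = self.G, self.S
        alpha = theta[:, : G * S].reshape(W, G, S)
        pos = G * S
        beta = None
        if self.x is not None:
            beta = theta[:, pos: pos + G * S].reshape(W, G, S)
            pos += G * S
        delta = theta[:, pos] if self.free_delta else None
        return alpha, beta, delta

    def _tables(self, delta: np.ndarray | None, W: int) -> np.ndarray:
        if delta is None:
            return np.broadcast_to(self.fixed_table.probs, (W, self.S, self.y0.shape[1]))
        return _delta_probs(self.matrix.values.astype(float), delta)

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        alpha, beta, delta = self._unpack(theta)
        logp = -0.5 * (alpha ** 2).sum(axis=(1, 2)) / self.config.prior_alpha ** 2
        if beta is not None:
            logp += -0.5 * (beta ** 2).sum(axis=(1, 2)) / self.config.prior_beta ** 2
        bad = np.zeros(W, dtype=bool)
        if delta is not None:
            bad = (delta <= 0) | (delta >= 0.5)
            delta = np.clip(delta, 1e-9, 0.5 - 1e-9)
        probs = self._tables(delta, W)  # (W, S, J)
        if self.x is None:
            p = _softmax(alpha)  # (W, G, S)
            if self.config.mode == "decision":
                theta_gj = np.einsum("wgs,wsj->wgj", p, probs)
                ll = (self.stats.n1 * np.log(theta_gj)
                      + self.stats.n0 * np.log1p(-theta_gj)).sum(axis=(1, 2))
            else:
                ll = self._participant_ll(np.log(p)[:, self.c_group, :], delta, W)
        else:
            eta = alpha[:, self.group_codes, :] \
                + beta[:, self.group_codes, :] * self.x[None, :, None]
            p_i = _softmax(eta)  # (W, n, S)
            if self.config.mode == "decision":
                theta_ij = np.einsum("wns,wsj->wnj", p_i, probs)
                with np.errstate(divide="ignore", invalid="ignore"):
                    term = self.y0 * np.log(theta_ij) \
                        + (1 - self.y0) * np.log1p(-theta_ij)
                ll = np.where(self.obs[None], term, 0.0).sum(axis=(1, 2))
            else:
                with np.errstate(divide="ignore"):
                    ll = self._participant_ll(np.log(p_i), delta, W)
        out = logp + ll
        out[bad] = -np.inf
        return out if theta.shape[0] > 1 else out

    def _participant_ll(self, logp_u: np.ndarray, delta, W: int) -> np.ndarray:
        """logp_u: (W, U, S) log membership per pattern class; returns (W,)."""
        if delta is None:
            L = self.cL[None]  # (1, U, S)
        else:
            d = delta[:, None, None]
            det = self.c_match[None] * np.log1p(-d) \
                + (self.c_nobs[None, :, None] - self.c_match[None]) * np.log(d)
            rand = (self.c_nobs * np.log(0.5))[None, :, None]
            L = np.concatenate(
                [det, np.broadcast_to(rand, (W, rand.shape[1], 1))], axis=2)
        return (logsumexp(logp_u + L, axis=2) * self.c_weight[None]).sum(axis=1)


# ---------------------------------------------------------------------------
# Sampling driver
# ---------------------------------------------------------------------------

def _n_walkers(ndim: int, chains: int) -> int:
    w = max(2 * ndim + 2, 4 * ndim if ndim >= 16 else 64, 64)
    return int(np.ceil(w / chains) * chains)


_MAX_BLOCKS = 8  # sampling extensions before giving up on the gates
_MAX_STORED_ITERS = 2000  # thin stored draws beyond this (diagnostics use all)


def _map_estimate(logpost: _LogPosterior) -> np.ndarray:
    """Posterior mode used to initialize the walker ball."""
    from scipy.optimize import minimize

    x0 = np.zeros(logpost.ndim)
    bounds = None
    if logpost.free_delta:
        x0[-1] = 0.1
        bounds = [(None, None)] * (logpost.ndim - 1) + [(1e-3, 0.499)]

    def objective(theta):
        val = logpost(theta[None])[0]
        return -val if np.isfinite(val) else 1e12

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
    return res.x


def _reshape_chain(chain: np.ndarray, chains: int) -> np.ndarray:
    """(iters, nwalkers, ndim) -> (chains, draws, ndim), walkers grouped."""
    iters, nwalkers, ndim = chain.shape
    per_chain = nwalkers // chains
    return chain.transpose(1, 0, 2).reshape(chains, per_chain * iters, ndim)


def _chain_diagnostics(chain: np.ndarray, logpost: _LogPosterior,
                       config: ModelConfig) -> dict:
    G, S = logpost.G, logpost.S
    reshaped = _reshape_chain(chain, config.chains)
    named = {"p": _softmax(
        reshaped[:, :, : G * S].reshape(config.chains, -1, G, S))}
    if logpost.x is not None:
        named["beta"] = reshaped[:, :, G * S: 2 * G * S].reshape(
            config.chains, -1, G, S)
    if logpost.free_delta:
        named["delta"] = reshaped[:, :, -1]
    return _diagnose(named, config)


def _run_mcmc(logpost: _LogPosterior, config: ModelConfig) -> np.ndarray:
    """Sample the posterior; returns (chains, draws, ndim) post-warmup.

    The ensemble is initialized in a small ball around the posterior mode,
    warmed up for ``config.warmup`` iterations, and then run in blocks of
    ``config.samples - config.warmup`` iterations until the R-hat and ESS
    gates pass (or a fixed cap of extensions is hit, in which case the
    caller's diagnostics will carry the failure). Stored draws are thinned
    to bound memory; diagnostics are computed on the unthinned chain.
    """
    ndim = logpost.ndim
    nwalkers = _n_walkers(ndim, config.chains)
    rng = np.random.default_rng(config.seed)
    center = _map_estimate(logpost)
    p0 = center[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))
    if logpost.free_delta:
        p0[:, -1] = np.clip(p0[:, -1], 1e-3, 0.499)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, logpost, vectorize=True,
                                    moves=moves)
    sampler.random_state = np.random.RandomState(
        int(rng.integers(0, 2**31 - 1))).get_state()
    state = sampler.run_mcmc(p0, config.warmup, progress=False,
                             skip_initial_state_check=True)
    block = config.samples - config.warmup
    for _ in range(_MAX_BLOCKS):
        state = sampler.run_mcmc(state, block, progress=False,
                                 skip_initial_state_check=True)
        chain = sampler.get_chain(discard=config.warmup)
        diag = _chain_diagnostics(chain, logpost, config)
        if diag["converged"]:
            break
    iters = chain.shape[0]
    if iters > _MAX_STORED_ITERS:
        chain = chain[:: int(np.ceil(iters / _MAX_STORED_ITERS))]
    out = _reshape_chain(chain, config.chains)
    return out, diag


def _diagnose(named_draws: dict[str, np.ndarray], config: ModelConfig) -> dict:
    idata = az.from_dict(posterior=named_draws)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rhat_max = float(max(rhat[v].values.max() for v in named_draws))
    ess_min = float(min(ess[v].values.min() for v in named_draws))
    converged = rhat_max <= config.rhat_max and ess_min >= config.ess_min
    return {"rhat_max": rhat_max, "ess_min": ess_min, "converged": converged}


def _finalize(chain: np.ndarray, diag: dict, logpost: _LogPosterior,
              config: ModelConfig, matrix: PredictionMatrix,
              groups: list[str], covariate: str | None = None,
              scaling: tuple[float, float] | None = None) -> PosteriorDraws:
    chains, draws, _ = chain.shape
    G, S = logpost.G, logpost.S
    alpha = chain[:, :, : G * S].reshape(chains, draws, G, S)
    pos = G * S
    beta = None
    if logpost.x is not None:
        beta = chain[:, :, pos: pos + G * S].reshape(chains, draws, G, S)
        pos += G * S
    delta_draws = chain[:, :, pos] if logpost.free_delta else None
    p = _softmax(alpha)
    if not diag["converged"]:
        warnings.warn(
            f"MCMC diagnostics failed their gates: max R-hat "
            f"{diag['rhat_max']:.4f} (gate {config.rhat_max}), min bulk ESS "
            f"{diag['ess_min']:.0f} (gate {config.ess_min:.0f})",
            ConvergenceWarning,
            stacklevel=3,
        )
    labels = list(matrix.labels) + [RANDOM_CHOICE]
    return PosteriorDraws(
        strategy_labels=labels, groups=list(groups), alpha=alpha, p=p,
        diagnostics=diag, config=config, matrix=matrix, beta=beta,
        delta_draws=delta_draws, covariate=covariate,
        covariate_scaling=scaling, converged=diag["converged"],
    )


def _group_codes(data: pd.DataFrame, column: str = "country"):
    groups = sorted(data[column].astype(str).unique())
    codes = pd.Categorical(data[column].astype(str), categories=groups).codes
    return groups, np.asarray(codes)


# ---------------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------------

def fit_base(data: pd.DataFrame, config: ModelConfig | None = None,
             matrix: PredictionMatrix | None = None) -> PosteriorDraws:
    """Fit the intercept-only latent-state model, one alpha vector per country."""
    if data.empty:
        raise ValueError("empty dataset")
    config = config or ModelConfig()
    if config.delta == "free":
        return fit_free_delta(data, config, matrix)
    matrix = matrix or base_matrix()
    groups, codes = _group_codes(data)
    logpost = _LogPosterior(data, matrix, config, groups, codes)
    chain, diag = _run_mcmc(logpost, config)
    return _finalize(chain, diag, logpost, config, matrix, groups)


def fit_free_delta(data: pd.DataFrame, config: ModelConfig | None = None,
                   matrix: PredictionMatrix | None = None) -> PosteriorDraws:
    """Base model with the implementation error rate as a free parameter.

    delta gets a Uniform(0, 0.5) prior: the upper bound preserves
    identifiability against the random-choice strategy.
    """
    if data.empty:
        raise ValueError("empty dataset")
    config = replace(config or ModelConfig(), delta="free")
    matrix = matrix or base_matrix()
    groups, codes = _group_codes(data)
    logpost = _LogPosterior(data, matrix, config, groups, codes)
    chain, diag = _run_mcmc(logpost, config)
    return _finalize(chain, diag, logpost, config, matrix, groups)


def fit_predictor(data: pd.DataFrame, covariate: str,
                  config: ModelConfig | None = None,
                  matrix: PredictionMatrix | None = None,
                  categorical: bool | None = None) -> PosteriorDraws:
    """Fit the covariate extension with one predictor.

    A continuous covariate is z-standardized and enters through per-country,
    per-strategy slopes with the regularizing Normal(0, 0.2) prior. A
    categorical covariate instead gets a separate intercept vector for every
    (country, level) cell. Rows with a missing covariate are dropped (and
    counted in the returned diagnostics).
    """
    if config is not None and config.delta == "free":
        raise ValueError("free delta is not supported in covariate models")
    config = config or ModelConfig()
    matrix = matrix or base_matrix()
    if covariate not in data.columns:
        raise ValueError(f"covariate column {covariate!r} not in data")
    keep = data[covariate].notna()
    n_dropped = int((~keep).sum())
    data = data.loc[keep]
    if data.empty:
        raise ValueError("no rows with a non-missing covariate")
    values = data[covariate]
    if categorical is None:
        categorical = not pd.api.types.is_numeric_dtype(values)
    if categorical:
        cells = data["country"].astype(str) + ":" + values.astype(str)
        work = data.copy()
        work["_cell"] = cells
        groups, codes = _group_codes(work, "_cell")
        logpost = _LogPosterior(data, matrix, config, groups, codes)
        chain, diag = _run_mcmc(logpost, config)
        out = _finalize(chain, diag, logpost, config, matrix, groups,
                        covariate=covariate)
    else:
        x = values.to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"covariate {covariate!r} has zero variance")
        mean = float(x.mean())
        xz = (x - mean) / sd
        groups, codes = _group_codes(data)
        logpost = _LogPosterior(data, matrix, config, groups, codes, x=xz)
        chain, diag = _run_mcmc(logpost, config)
        out = _finalize(chain, diag, logpost, config, matrix, groups,
                        covariate=covariate, scaling=(mean, float(sd)))
    out.diagnostics["n_dropped_missing_covariate"] = n_dropped
    return out


# ---------------------------------------------------------------------------
# Posterior post-processing
# ---------------------------------------------------------------------------

def membership_probabilities(decisions: Sequence[float] | np.ndarray,
                             draws: PosteriorDraws,
                             group: str | None = None) -> pd.Series:
    """Posterior strategy-membership probabilities for one decision vector.

    Applies Bayes' rule per posterior draw — weights proportional to
    p_s x Pr(decisions | s) — and averages the normalized weights over
    draws. Missing decisions are ignored in the likelihood. Free-delta
    fits use each draw's own delta.
    """
    vec = np.asarray(decisions, dtype=float)[None, :]
    if group is None:
        if len(draws.groups) != 1:
            raise ValueError("fit has several groups; pass group=...")
        g = 0
    else:
        g = draws.groups.index(group)
    p = draws.p_flat()[:, g, :]  # (D, S)
    if draws.delta_draws is None:
        L = _strategy_loglik(vec, draws.table())[0]  # (S,)
        logw = np.log(np.clip(p, 1e-300, None)) + L[None, :]
    else:
        deltas = draws.delta_draws.reshape(-1)
        obs = ~np.isnan(vec[0])
        y0 = np.nan_to_num(vec[0])
        match = ((y0 == draws.matrix.values) & obs).sum(axis=1)  # (S-1,)
        n_obs = int(obs.sum())
        d = deltas[:, None]
        det = match[None, :] * np.log1p(-d) + (n_obs - match[None, :]) * np.log(
            np.clip(d, 1e-12, None))
        rand = np.full((deltas.size, 1), n_obs * np.log(0.5))
        L = np.concatenate([det, rand], axis=1)
        logw = np.log(np.clip(p, 1e-300, None)) + L
    w = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    post = w.mean(axis=0)
    return pd.Series(post, index=draws.strategy_labels, name="membership")


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior medians with 50% and 95% credible intervals.

    One row per (group, strategy) for the membership probabilities, plus
    slope rows for covariate fits and a delta row for free-delta fits.
    """
    qs = (0.025, 0.25, 0.5, 0.75, 0.975)
    names = ["q2.5", "q25", "median", "q75", "q97.5"]
    rows = []

    def add(param: str, group: str, strategy: str, samples: np.ndarray):
        quants = np.quantile(samples, qs)
        rows.append({"param": param, "group": group, "strategy": strategy,
                     **dict(zip(names, quants))})

    flat_p = draws.p_flat()
    for gi, g in enumerate(draws.groups):
        for si, s in enumerate(draws.strategy_labels):
            add("p", g, s, flat_p[:, gi, si])
    if draws.beta is not None:
        flat_b = draws.beta.reshape(-1, *draws.beta.shape[2:])
        for gi, g in enumerate(draws.groups):
            for si, s in enumerate(draws.strategy_labels):
                add("beta", g, s, flat_b[:, gi, si])
    if draws.delta_draws is not None:
        add("delta", "", "", draws.delta_draws.reshape(-1))
    return pd.DataFrame(rows)
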