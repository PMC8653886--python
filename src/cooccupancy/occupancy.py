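"""Multivariate-Bernoulli multi-species occupancy model.

The joint presence/absence state of S species at a site is a vector
``z in {0,1}^S`` with probability

    psi(z) ∝ exp( sum_s z_s f_s  +  sum_{s<t} z_s z_t f_st )

where the first-order natural parameters ``f_s`` and (optional) pairwise
second-order parameters ``f_st`` are linear in site covariates.  Third- and
higher-order interactions are identically zero.  Detection of species ``s``
at site ``i`` on night ``j`` is Bernoulli with a logit-linear probability
``p_sij`` (trail placement and per-night dog activity are the supported
night-level covariates; the dog's own detection never depends on dog
activity).  Sites are the independent likelihood units; nights without camera
activity contribute no detection factor.

Fitting is Bayesian with independent Normal(0, 10) priors on every
coefficient; the sampler is an affine-invariant ensemble (emcee) run as
several independent "chains" whose agreement is checked with rank-normalized
split R-hat.  WAIC uses per-site pointwise log-likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm

__all__ = [
    "enumerate_states",
    "species_pairs",
    "state_probs",
    "ModelSpec",
    "StudyData",
    "natural_params",
    "detection_probs",
    "site_loglik",
    "log_likelihood",
    "log_posterior",
    "fit",
    "FitResult",
    "gelman_rubin",
    "waic",
]

PRIOR_SD = 10.0

OCC_INTERCEPT = "Intercept"
DETECTION_TERMS = ("Intercept", "trail", "dog_activity")


# ---------------------------------------------------------------------------
# latent states
# ---------------------------------------------------------------------------

def enumerate_states(n_species: int) -> np.ndarray:
    """All ``2**S`` presence/absence vectors, in binary-counting order.

    Species 1 is the least-significant bit, so the first row is all-absent
    and for S=2 the order is (0,0), (1,0), (0,1), (1,1).
    """
    if not 1 <= n_species <= 10:
        raise ValueError("n_species must be in 1..10")
    idx = np.arange(2 ** n_species)
    return ((idx[:, None] >> np.arange(n_species)[None, :]) & 1).astype(np.int8)


def species_pairs(species: Sequence[str]) -> list[tuple[str, str]]:
    """Canonical (s, t) pair order: s before t in the species list."""
    return [
        (species[i], species[j])
        for i in range(len(species))
        for j in range(i + 1, len(species))
    ]


def _pair_products(Z: np.ndarray) -> np.ndarray:
    """Column z_s * z_t for every canonical pair; shape (2^S, S*(S-1)/2)."""
    S = Z.shape[1]
    cols = [Z[:, i] * Z[:, j] for i in range(S) for j in range(i + 1, S)]
    return np.stack(cols, axis=1) if cols else np.zeros((Z.shape[0], 0), dtype=np.int8)


def state_probs(f1, f2=None) -> np.ndarray:
    """State probabilities psi(z) from natural parameters.

    ``f1``: first-order parameters, shape (..., S).  ``f2``: pairwise
    parameters in canonical pair order (see :func:`species_pairs`), shape
    (..., S*(S-1)/2); omitted means independence.  Returns psi of shape
    (..., 2**S), non-negative and summing to 1 along the last axis (computed
    through a log-sum-exp guard).
    """
    f1 = np.asarray(f1, dtype=float)
    if not np.all(np.isfinite(f1)):
        raise ValueError("non-finite first-order natural parameter")
    S = f1.shape[-1]
    Z = enumerate_states(S).astype(float)
    logw = f1 @ Z.T
    if f2 is not None:
        f2 = np.asarray(f2, dtype=float)
        if not np.all(np.isfinite(f2)):
            raise ValueError("non-finite pairwise natural parameter")
        logw = logw + f2 @ _pair_products(enumerate_states(S)).astype(float).T
    logw = logw - logsumexp(logw, axis=-1, keepdims=True)
    return np.exp(logw)


# ---------------------------------------------------------------------------
# model specification and data container
# ---------------------------------------------------------------------------

def _norm_pair(pair: tuple[str, str], species: Sequence[str]) -> tuple[str, str]:
    s, t = pair
    if s not in species or t not in species or s == t:
        raise ValueError(f"bad species pair {pair}")
    return (s, t) if species.index(s) < species.index(t) else (t, s)


@dataclass(frozen=True)
class ModelSpec:
    """Maps covariates to occupancy natural parameters and detection logits.

    ``occupancy[s]`` / ``pairs[(s,t)]`` are term tuples ("Intercept" plus
    covariate column names); a species absent from ``occupancy`` gets an
    intercept only.  ``detection[s]`` draws from ("Intercept", "trail",
    "dog_activity"); dog activity is disallowed in the dog's own design.
    """

    species: tuple[str, ...]
    occupancy: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    pairs: Mapping[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    detection: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    scale: str = ""
    dog_species: str = "dog"

    def __post_init__(self):
        occ = {s: tuple(self.occupancy.get(s, (OCC_INTERCEPT,))) for s in self.species}
        for s in self.occupancy:
            if s not in self.species:
                raise ValueError(f"occupancy design for unknown species {s!r}")
        prs = {}
        for pair, terms in self.pairs.items():
            prs[_norm_pair(tuple(pair), self.species)] = tuple(terms)
        det = {s: tuple(self.detection.get(s, (OCC_INTERCEPT,))) for s in self.species}
        for s, terms in det.items():
            for t in terms:
                if t not in DETECTION_TERMS:
                    raise ValueError(f"unknown detection term {t!r}")
            if s == self.dog_species and "dog_activity" in terms:
                raise ValueError("dog activity cannot enter the dog's own detection design")
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "pairs", prs)
        object.__setattr__(self, "detection", det)

    @property
    def param_names(self) -> list[str]:
        names = []
        for s in self.species:
            names += [f"occ[{s}]:{t}" for t in self.occupancy[s]]
        for (s, t), terms in self.pairs.items():
            names += [f"pair[{s}|{t}]:{term}" for term in terms]
        for s in self.species:
            names += [f"det[{s}]:{t}" for t in self.detection[s]]
        return names

    @property
    def k(self) -> int:
        """Total number of coefficients (reported as model size)."""
        return len(self.param_names)

    def with_occupancy(self, species: str, terms: tuple[str, ...]) -> "ModelSpec":
        occ = dict(self.occupancy)
        occ[species] = tuple(terms)
        return ModelSpec(self.species, occ, self.pairs, self.detection,
                         self.scale, self.dog_species)

    def with_pairs(self, pairs: Mapping[tuple[str, str], tuple[str, ...]]) -> "ModelSpec":
        return ModelSpec(self.species, self.occupancy, dict(pairs), self.detection,
                         self.scale, self.dog_species)


@dataclass
class StudyData:
    """Detection histories plus covariates, aligned on sites.

    ``y``: (S, N, J) float with NaN for inactive nights.  ``covariates``: one
    row per site (standardized continuous columns).  ``trail``: (N,) binary.
    ``dog_activity``: (N, J) counts, zero where inactive.
    """

    y: np.ndarray
    species: tuple[str, ...]
    sites: tuple[str, ...]
    covariates: pd.DataFrame
    trail: np.ndarray
    dog_activity: np.ndarray

    def __post_init__(self):
        S, N, J = self.y.shape
        if len(self.species) != S or len(self.sites) != N:
            raise ValueError("y shape inconsistent with species/sites")
        if self.dog_activity.shape != (N, J) or self.trail.shape != (N,):
            raise ValueError("covariate array shapes inconsistent with y")
        all_missing = ~np.isfinite(self.y[0]).any(axis=1)
        if all_missing.any():
            keep = ~all_missing
            warnings.warn(
                f"dropping {int(all_missing.sum())} site(s) with no active nights"
            )
            self.y = self.y[:, keep]
            self.sites = tuple(np.asarray(self.sites)[keep])
            self.covariates = self.covariates.loc[keep].reset_index(drop=True)
            self.trail = self.trail[keep]
            self.dog_activity = self.dog_activity[keep]

    @property
    def n_sites(self) -> int:
        return self.y.shape[1]


# ---------------------------------------------------------------------------
# design: precomputed matrices for fast batched likelihood evaluation
# ---------------------------------------------------------------------------

class _Design:
    """Precomputed design matrices and parameter layout for one (spec, data)."""

    def __init__(self, spec: ModelSpec, data: StudyData):
        if tuple(data.species) != tuple(spec.species):
            raise ValueError("spec and data species lists differ")
        self.spec, self.data = spec, data
        N = data.n_sites
        cov = data.covariates
        names = spec.param_names
        self.names = names
        self.k = len(names)
        pos = {n: i for i, n in enumerate(names)}

        def col(term):
            if term == OCC_INTERCEPT:
                return np.ones(N)
            if term not in cov.columns:
                raise KeyError(f"covariate {term!r} not in table")
            return cov[term].to_numpy(dtype=float)

        self.occ_X = []   # per species: (N, k_s)
        self.occ_ix = []  # per species: param indices
        for s in spec.species:
            terms = spec.occupancy[s]
            self.occ_X.append(np.column_stack([col(t) for t in terms]))
            self.occ_ix.append([pos[f"occ[{s}]:{t}"] for t in terms])

        S = len(spec.species)
        Z = enumerate_states(S).astype(float)
        self.Z = Z
        all_pairs = species_pairs(spec.species)
        Zp = _pair_products(enumerate_states(S)).astype(float)
        self.pair_X, self.pair_ix, self.pair_Zcol = [], [], []
        for pair, terms in spec.pairs.items():
            if not terms:
                continue
            self.pair_X.append(np.column_stack([col(t) for t in terms]))
            self.pair_ix.append([pos[f"pair[{pair[0]}|{pair[1]}]:{t}"] for t in terms])
            self.pair_Zcol.append(Zp[:, all_pairs.index(pair)])

        # detection: per species a list of (param index, (N,J) covariate array)
        J = data.y.shape[2]
        ones = np.ones((N, J))
        trail = np.broadcast_to(data.trail[:, None].astype(float), (N, J))
        dog = data.dog_activity.astype(float)
        det_cov = {"Intercept": ones, "trail": trail, "dog_activity": dog}
        self.det_terms = []
        for s in spec.species:
            self.det_terms.append(
                [(pos[f"det[{s}]:{t}"], det_cov[t]) for t in spec.detection[s]]
            )

        self.obs = np.isfinite(data.y)                     # (S, N, J)
        self.y0 = np.nan_to_num(data.y)                    # NaN -> 0

        # Sufficient statistics for the detection term.  With the logit link,
        #   A[s,i] = sum_j obs (y*logit - log1pexp(logit))
        # is linear in theta up to log1pexp evaluated on the few *unique*
        # nightly design rows, so we precompute per species: the linear
        # weights v1 (N, T), the unique rows U (n_u, T) and per-site counts
        # W (N, n_u) of observed nights with each row.
        self._det_suff = []
        for s, terms in enumerate(self.det_terms):
            T = len(terms)
            Xstack = np.stack([X for _, X in terms], axis=2)       # (N, J, T)
            ix = np.array([i for i, _ in terms])
            obs_s, y_s = self.obs[s], self.y0[s]
            v1 = np.einsum("nj,njt->nt", obs_s * y_s, Xstack)
            rows = Xstack[obs_s]                                   # (cells, T)
            site_of_cell = np.nonzero(obs_s)[0]
            U, inv = np.unique(rows, axis=0, return_inverse=True)
            W = np.zeros((N, len(U)))
            np.add.at(W, (site_of_cell, inv), 1.0)
            self._det_suff.append((ix, v1, U, W))
        anydet = (self.y0 == 1).any(axis=2)                # (S, N)
        # feasible[i, z]: every detected species is present under state z
        self.feasible = ~(
            anydet.T[:, None, :] & (self.Z[None, :, :] == 0)
        ).any(axis=2)                                      # (N, 2^S)

    # -- batched pieces ----------------------------------------------------

    def f1(self, theta: np.ndarray) -> np.ndarray:
        """First-order natural parameters, (B, N, S)."""
        B = theta.shape[0]
        N = self.data.n_sites
        out = np.empty((B, N, len(self.spec.species)))
        for s, (X, ix) in enumerate(zip(self.occ_X, self.occ_ix)):
            out[:, :, s] = theta[:, ix] @ X.T
        return out

    def log_state_weights(self, theta: np.ndarray) -> np.ndarray:
        """Unnormalized log psi over states, (B, N, 2^S)."""
        logw = self.f1(theta) @ self.Z.T
        for X, ix, zcol in zip(self.pair_X, self.pair_ix, self.pair_Zcol):
            f2 = theta[:, ix] @ X.T                         # (B, N)
            logw = logw + f2[:, :, None] * zcol[None, None, :]
        return logw

    def det_logits(self, theta: np.ndarray) -> np.ndarray:
        """Detection logits, (B, S, N, J)."""
        B = theta.shape[0]
        S, N, J = self.data.y.shape
        out = np.zeros((B, S, N, J))
        for s, terms in enumerate(self.det_terms):
            for ix, X in terms:
                out[:, s] += theta[:, ix, None, None] * X[None]
        return out

    def site_logliks(self, theta: np.ndarray) -> np.ndarray:
        """Per-site log-likelihood for a batch of parameter vectors, (B, N)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        B = theta.shape[0]
        S, N, _ = self.data.y.shape
        # A[b,s,i]: log-lik of species s's detection row given presence
        A = np.empty((B, S, N))
        for s, (ix, v1, U, W) in enumerate(self._det_suff):
            th = theta[:, ix]                                 # (B, T)
            lam = th @ U.T                                    # (B, n_u)
            A[:, s, :] = th @ v1.T - np.logaddexp(0.0, lam) @ W.T
        ll_state = np.einsum("bsi,zs->biz", A, self.Z)        # (B, N, 2^S)
        logw = self.log_state_weights(theta)
        tot = logw + np.where(self.feasible[None], ll_state, -np.inf)
        m = tot.max(axis=2)
        num = m + np.log(np.exp(tot - m[:, :, None]).sum(axis=2))
        m2 = logw.max(axis=2)
        den = m2 + np.log(np.exp(logw - m2[:, :, None]).sum(axis=2))
        return num - den

    def log_posterior(self, theta: np.ndarray, prior_sd: float = PRIOR_SD) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        lp = (
            -0.5 * ((theta / prior_sd) ** 2).sum(axis=1)
            - theta.shape[1] * (np.log(prior_sd) + 0.5 * np.log(2 * np.pi))
        )
        return self.site_logliks(theta).sum(axis=1) + lp


# ---------------------------------------------------------------------------
# public functional surface
# ---------------------------------------------------------------------------

def natural_params(
    spec: ModelSpec, theta: np.ndarray, data: StudyData
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Per-site natural parameters (f1 (N,S), f2 (N,P), declared pair list).

    ``f2`` columns follow the order of ``spec.pairs``; pairs not declared in
    the spec are simply absent (independence).
    """
    d = _Design(spec, data)
    theta = np.asarray(theta, dtype=float)[None]
    f1 = d.f1(theta)[0]
    pairs = [p for p, terms in spec.pairs.items() if terms]
    f2 = np.zeros((data.n_sites, len(pairs)))
    for j, (X, ix) in enumerate(zip(d.pair_X, d.pair_ix)):
        f2[:, j] = (theta[:, ix] @ X.T)[0]
    return f1, f2, pairs


def detection_probs(spec: ModelSpec, theta: np.ndarray, data: StudyData) -> np.ndarray:
    """Detection probabilities p_sij, shape (S, N, J), strictly in (0, 1)."""
    d = _Design(spec, data)
    return expit(d.det_logits(np.asarray(theta, dtype=float)[None])[0])


def site_loglik(y_i: np.ndarray, psi_i: np.ndarray, p_i: np.ndarray) -> float:
    """Log-likelihood of one site's histories given state probabilities.

    ``y_i``: (S, J) with NaN for missing nights; ``psi_i``: (2^S,) state
    probabilities in binary-counting order; ``p_i``: (S, J) nightly detection
    probabilities.  Missing nights contribute no factor; a state in which a
    detected species is absent contributes zero likelihood.
    """
    y_i = np.asarray(y_i, dtype=float)
    p_i = np.asarray(p_i, dtype=float)
    S, J = y_i.shape
    Z = enumerate_states(S)
    if psi_i.shape != (2 ** S,):
        raise ValueError("psi_i length must be 2**S")
    obs = np.isfinite(y_i)
    y0 = np.nan_to_num(y_i)
    A = np.where(obs, y0 * np.log(p_i) + (1 - y0) * np.log1p(-p_i), 0.0).sum(axis=1)
    anydet = (y0 == 1).any(axis=1)
    feasible = ~((anydet[None, :]) & (Z == 0)).any(axis=1)
    llz = Z.astype(float) @ A
    with np.errstate(divide="ignore"):
        terms = np.where(feasible, np.log(psi_i) + llz, -np.inf)
    return float(logsumexp(terms))


def log_likelihood(spec: ModelSpec, theta: np.ndarray, data: StudyData) -> np.ndarray:
    """Pointwise (per-site) log-likelihood vector for one parameter vector."""
    return _Design(spec, data).site_logliks(theta)[0]


def log_posterior(
    theta: np.ndarray, spec: ModelSpec, data: StudyData, prior_sd: float = PRIOR_SD
) -> float:
    """Log joint density: site log-likelihoods plus Normal(0, prior_sd) priors."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter vector")
    return float(_Design(spec, data).log_posterior(theta[None], prior_sd)[0])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Posterior draws plus the quantities needed for diagnostics and WAIC."""

    draws: np.ndarray              # (chains, draws_per_chain, k)
    param_names: list[str]
    spec: ModelSpec
    seed: int
    rhat: np.ndarray               # (k,)
    pointwise: np.ndarray          # (total draws used for WAIC, n_sites)
    waic: dict
    meta: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.param_names)

    def draws_flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def samples(self, name: str) -> np.ndarray:
        return self.draws_flat()[:, self.param_names.index(name)]

    def summary(self, level: float = 0.80) -> pd.DataFrame:
        flat = self.draws_flat()
        a = (1 - level) / 2
        lo, hi = np.quantile(flat, [a, 1 - a], axis=0)
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "mean": flat.mean(axis=0),
                "lo": lo,
                "hi": hi,
                "rhat": self.rhat,
            }
        )


def _chain_seed(seed: int, chain: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(chain,)).generate_state(1)[0] % (2 ** 31))


def fit(
    spec: ModelSpec,
    data: StudyData,
    chains: int = 3,
    iterations: int = 6000,
    warmup: int = 2000,
    seed: int = 0,
    nwalkers: int | None = None,
    draws_per_chain: int = 500,
    prior_sd: float = PRIOR_SD,
    waic_draws: int = 600,
) -> FitResult:
    """Sample the posterior with an affine-invariant ensemble sampler.

    Each "chain" is an independent ensemble run of ``iterations`` steps whose
    first ``warmup`` steps are discarded; retained (step, walker) samples are
    thinned to ``draws_per_chain`` per chain.  Per-site pointwise
    log-likelihoods are stored (on a thinned subset of ``waic_draws`` draws)
    so WAIC can be computed, and rank-normalized split R-hat is attached per
    parameter.  Identical seeds give identical draws.
    """
    import emcee

    design = _Design(spec, data)
    k = design.k
    if iterations <= warmup:
        raise ValueError("iterations must exceed warmup")
    if nwalkers is None:
        nwalkers = max(2 * k + 2, 24)
    nwalkers += nwalkers % 2

    def logp(batch):
        return design.log_posterior(batch, prior_sd)

    # Start every walker near the posterior mode: burn-in is then spent
    # adapting the ensemble's shape rather than finding the mass.
    from scipy.optimize import minimize

    opt = minimize(
        lambda th: -design.log_posterior(th[None], prior_sd)[0],
        np.zeros(k),
        method="L-BFGS-B",
    )
    center = opt.x if opt.success or np.isfinite(opt.fun) else np.zeros(k)

    chain_draws = []
    accept = []
    for c in range(chains):
        rng = np.random.RandomState(_chain_seed(seed, c))
        sampler = emcee.EnsembleSampler(nwalkers, k, logp, vectorize=True)
        sampler.random_state = rng.get_state()
        p0 = center[None, :] + rng.normal(0.0, 0.1, size=(nwalkers, k))
        sampler.run_mcmc(p0, iterations, progress=False)
        chain = sampler.get_chain(discard=warmup)            # (steps, W, k)
        flat = chain.reshape(-1, k)                          # step-major
        take = np.unique(np.linspace(0, len(flat) - 1, min(draws_per_chain, len(flat))).astype(int))
        chain_draws.append(flat[take])
        accept.append(float(np.mean(sampler.acceptance_fraction)))

    ndraw = min(len(c) for c in chain_draws)
    draws = np.stack([c[:ndraw] for c in chain_draws])       # (C, D, k)
    rhat = gelman_rubin(draws)

    flat = draws.reshape(-1, k)
    take = np.unique(np.linspace(0, len(flat) - 1, min(waic_draws, len(flat))).astype(int))
    sub = flat[take]
    pointwise = np.vstack(
        [design.site_logliks(sub[i : i + 64]) for i in range(0, len(sub), 64)]
    )
    w = waic(pointwise)

    warns = []
    if np.any(rhat > 1.1):
        bad = [n for n, r in zip(design.names, rhat) if r > 1.1]
        warns.append(f"R-hat above 1.1 for: {', '.join(bad)}")
    if np.mean(accept) < 0.1:
        warns.append(f"low ensemble acceptance fraction ({np.mean(accept):.2f})")

    return FitResult(
        draws=draws,
        param_names=list(design.names),
        spec=spec,
        seed=seed,
        rhat=rhat,
        pointwise=pointwise,
        waic=w,
        meta={
            "sampler": "emcee.EnsembleSampler",
            "chains": chains,
            "iterations": iterations,
            "warmup": warmup,
            "nwalkers": nwalkers,
            "acceptance_fraction": accept,
        },
        warnings=warns,
    )


def gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Rank-normalized split R-hat per parameter.

    ``draws``: (chains, draws, k).  A single chain falls back to split-chain
    R-hat with a warning (the split is what makes one chain usable at all).
    """
    import arviz as az

    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3:
        raise ValueError("draws must be (chains, draws, k)")
    if draws.shape[0] < 2:
        warnings.warn("single chain: falling back to split-chain R-hat")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.rhat(az.convert_to_dataset(draws))["x"].to_numpy()
    return np.asarray(r, dtype=float)


def waic(pointwise: np.ndarray) -> dict:
    """WAIC from a (draws, sites) pointwise log-likelihood matrix.

    lppd = sum_i log mean_d exp(ll_di);  p_waic = sum_i var_d(ll_di);
    waic = -2 (lppd - p_waic).  Requires at least two draws.
    """
    ll = np.asarray(pointwise, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws >= 2, sites) pointwise matrix")
    n = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(n)
    p_i = ll.var(axis=0, ddof=1)
    lppd, p = float(lppd_i.sum()), float(p_i.sum())
    return {
        "waic": -2.0 * (lppd - p),
        "lppd": lppd,
        "p_waic": p,
        "pointwise_lppd": lppd_i,
        "pointwise_p": p_i,
    }
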