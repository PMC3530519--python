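"""Coalescent-based Bayesian inference of a single change in Ne.

The model: an ancestral effective size N1 changed to the current size
N0 at T generations before sampling, with N(t) interpolating linearly
or exponentially in between.  Microsatellite loci evolve by strict
stepwise mutation at per-locus rate mu_i, scaled as theta_i = 2*N0*mu_i.
Each locus carries a latent genealogy (topology, node times in
generations, integer ancestral allele states); the posterior over
(N0, N1, T, theta_1..L) and the genealogies is explored by
Metropolis-Hastings with alternating genealogy and parameter moves.

All demographic parameters live on the log10 scale under hierarchical
normal priors: x ~ N(alpha, sigma) with alpha ~ N(am, as) and
sigma ~ N(sm, ss) truncated at zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import genealogy_loglik, log_skellam, mcmc_kernel
from .dataset import GenotypeDataset
from .trajectory import DemographicTrajectory

logger = logging.getLogger(__name__)

_SHAPE_CODE = {"constant": 0, "exponential": 1, "linear": 2}
PARAM_NAMES = ("N0", "N1", "T", "theta")


# ----------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class BlockPrior:
    """Hierarchical log10-normal prior for one parameter block.

    x ~ N(alpha, sigma); alpha ~ N(alpha_mean, alpha_sd);
    sigma ~ N(sigma_mean, sigma_sd) truncated at 0.  Zero hyper-SDs pin
    alpha and/or sigma (non-hierarchical mode).
    """

    alpha_mean: float
    alpha_sd: float
    sigma_mean: float
    sigma_sd: float

    def __post_init__(self) -> None:
        if self.sigma_mean <= 0 and self.sigma_sd == 0:
            raise ValueError("prior SD must be positive")
        if self.alpha_sd < 0 or self.sigma_sd < 0:
            raise ValueError("hyperprior SDs must be >= 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """iid draws of x from the compound (marginal) prior."""
        alpha = self.alpha_mean + self.alpha_sd * rng.standard_normal(n)
        sigma = self.sigma_mean + self.sigma_sd * rng.standard_normal(n)
        sigma = np.abs(sigma)  # truncation at zero, reflected
        return alpha + sigma * rng.standard_normal(n)


@dataclass(frozen=True)
class PriorSpec:
    """Priors for log10(N0), log10(N1), log10(T), log10(theta)."""

    N0: BlockPrior
    N1: BlockPrior
    T: BlockPrior
    theta: BlockPrior

    @classmethod
    def default(cls) -> "PriorSpec":
        """Wide desk defaults: sizes centred at 10^3, time at 10^3
        generations, theta at 10^0, all with unit prior SD and modest
        hyper spread."""
        return cls(
            N0=BlockPrior(3.0, 0.5, 1.0, 0.25),
            N1=BlockPrior(3.0, 0.5, 1.0, 0.25),
            T=BlockPrior(3.0, 0.5, 1.0, 0.25),
            theta=BlockPrior(0.0, 0.5, 1.0, 0.25),
        )

    def block(self, name: str) -> BlockPrior:
        return getattr(self, name)


# ----------------------------------------------------------------------
# chain state


@dataclass
class Genealogy:
    """Latent labelled history for one locus.

    parent[i] is the parent node of i (-1 for the root), node_time in
    generations (0 for leaves), state the integer allele size; leaves
    occupy indices [0, n_leaves) and their states are the observed
    allele sizes (fixed).
    """

    parent: np.ndarray
    node_time: np.ndarray
    state: np.ndarray
    n_leaves: int

    def children_of(self, node: int) -> list[int]:
        return [i for i, p in enumerate(self.parent) if p == node]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def copy(self) -> "Genealogy":
        return Genealogy(
            self.parent.copy(), self.node_time.copy(), self.state.copy(), self.n_leaves
        )


@dataclass
class ChainState:
    """Full MCMC state: log10 parameters, hyperparameters, genealogies."""

    log_params: dict  # name -> scalar (N0, N1, T) ; "theta" -> np.ndarray per locus
    alpha: dict  # block name -> scalar
    sigma: dict  # block name -> scalar
    genealogies: list
    shape: str

    def trajectory(self) -> DemographicTrajectory:
        return DemographicTrajectory(
            N0=10.0 ** self.log_params["N0"],
            N1=10.0 ** self.log_params["N1"],
            T=10.0 ** self.log_params["T"],
            shape=self.shape,
        )

    def mu(self, locus: int) -> float:
        # theta = 2 * N0 * mu
        return 10.0 ** self.log_params["theta"][locus] / (
            2.0 * 10.0 ** self.log_params["N0"]
        )


@dataclass
class PosteriorChains:
    """Thinned parameter records (log10 scale) plus run metadata."""

    records: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


# ----------------------------------------------------------------------
# building blocks exposed for testing


def branch_transition_logprob(size_delta: int, expected_mutations: float) -> float:
    """log probability of a net allele-size displacement on one branch
    under strict stepwise mutation: e^(-m) I_|d|(m) (Skellam with both
    rates m/2), evaluated in the log domain."""
    if expected_mutations < 0:
        raise ValueError("expected_mutations must be >= 0")
    return float(log_skellam(int(size_delta), float(expected_mutations)))


def coalescent_intensity(traj: DemographicTrajectory, t: float) -> float:
    """Cumulative coalescent intensity integral_0^t du/N(u)."""
    return traj.intensity(t)


def _locus_loglik(g: Genealogy, state: ChainState, locus: int) -> float:
    traj = state.trajectory()
    return float(
        genealogy_loglik(
            g.parent,
            g.node_time,
            g.state,
            g.n_leaves,
            traj.N0,
            traj.N1,
            traj.T,
            _SHAPE_CODE[state.shape],
            state.mu(locus),
        )
    )


def _log_prior(state: ChainState, priors: PriorSpec) -> float:
    lp = 0.0
    for name in PARAM_NAMES:
        b = priors.block(name)
        a, s = state.alpha[name], state.sigma[name]
        if s <= 0:
            return -np.inf
        if b.alpha_sd > 0:
            lp += -0.5 * ((a - b.alpha_mean) / b.alpha_sd) ** 2 - math.log(b.alpha_sd)
        if b.sigma_sd > 0:
            lp += -0.5 * ((s - b.sigma_mean) / b.sigma_sd) ** 2 - math.log(b.sigma_sd)
        x = state.log_params[name]
        vals = np.atleast_1d(x)
        lp += float(
            (-0.5 * ((vals - a) / s) ** 2 - math.log(s)).sum()
        )
    return lp


def log_posterior(state: ChainState, priors: PriorSpec, data: Sequence[np.ndarray]) -> float:
    """Joint log density: coalescent + mutation terms for every locus
    plus the hierarchical log-prior.  Leaf-state mismatches with the
    observed data return -inf."""
    lp = _log_prior(state, priors)
    if not np.isfinite(lp):
        return lp
    for j, sizes in enumerate(data):
        g = state.genealogies[j]
        if not np.array_equal(g.state[: g.n_leaves], sizes):
            return -np.inf
        lp += _locus_loglik(g, state, j)
    return lp


# ----------------------------------------------------------------------
# initialization


def _init_genealogy(sizes: np.ndarray, N_init: float, rng: np.random.Generator) -> Genealogy:
    """UPGMA-like starting tree: merge closest allele-size pair first,
    with coalescent-scale exponential node times and midpoint ancestral
    states."""
    n = sizes.shape[0]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)
    state = np.zeros(n_nodes, dtype=np.int64)
    state[:n] = sizes
    active = list(range(n))
    vals = {i: float(sizes[i]) for i in range(n)}
    t = 0.0
    nxt = n
    k = n
    while k > 1:
        t += rng.exponential(2.0 * 2.0 * N_init / (k * (k - 1)))
        # closest pair by current working values, ties broken at random
        best, bi, bj = np.inf, 0, 1
        order = rng.permutation(len(active))
        for ii in order:
            for jj in order:
                if ii >= jj:
                    continue
                d = abs(vals[active[ii]] - vals[active[jj]])
                if d < best:
                    best, bi, bj = d, ii, jj
        a, b = active[bi], active[bj]
        for idx in sorted((bi, bj), reverse=True):
            active.pop(idx)
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = t
        vals[nxt] = 0.5 * (vals[a] + vals[b])
        state[nxt] = int(round(vals[nxt]))
        active.append(nxt)
        nxt += 1
        k -= 1
    return Genealogy(parent, node_time, state, n)


def _init_state(
    data: Sequence[np.ndarray],
    priors: PriorSpec,
    shape: str,
    rng: np.random.Generator,
) -> ChainState:
    alpha = {}
    sigma = {}
    log_params = {}
    for name in PARAM_NAMES:
        b = priors.block(name)
        alpha[name] = b.alpha_mean + b.alpha_sd * rng.standard_normal()
        sigma[name] = abs(b.sigma_mean + b.sigma_sd * rng.standard_normal())
        if sigma[name] <= 0:
            sigma[name] = max(b.sigma_mean, 0.1)
    for name in ("N0", "N1", "T"):
        log_params[name] = alpha[name] + 0.5 * sigma[name] * rng.standard_normal()
    n_theta = max(len(data), 1)
    log_params["theta"] = alpha["theta"] + 0.5 * sigma["theta"] * rng.standard_normal(
        n_theta
    )
    N_init = 10.0 ** log_params["N0"]
    gens = [_init_genealogy(sizes, N_init, rng) for sizes in data]
    return ChainState(
        log_params=log_params, alpha=alpha, sigma=sigma, genealogies=gens, shape=shape
    )


# ----------------------------------------------------------------------
# proposals (return (changed-state-part, log Hastings ratio))


def propose_node_time(g: Genealogy, node: int, rng: np.random.Generator, scale: float = 0.5):
    """New time for an internal node: uniform between its children's
    latest time and its parent's time; the root is rescaled
    multiplicatively (log Hastings = log factor)."""
    lo = max(g.node_time[c] for c in g.children_of(node))
    p = g.parent[node]
    if p < 0:
        u = scale * (rng.random() * 2.0 - 1.0)
        t_new = lo + (g.node_time[node] - lo) * math.exp(u)
        return t_new, u
    hi = g.node_time[p]
    t_new = lo + rng.random() * (hi - lo)
    return t_new, 0.0


def propose_exchange(g: Genealogy, rng: np.random.Generator):
    """Narrow exchange: swap a random child of an internal node with its
    sibling subtree when times allow; symmetric (log Hastings 0).
    Returns (node_a, node_b, new_parent_a, new_parent_b) or None."""
    internal = [
        i
        for i in range(g.n_leaves, g.parent.shape[0])
        if g.parent[i] >= 0
    ]
    if not internal:
        return None
    p = internal[rng.integers(len(internal))]
    gp = g.parent[p]
    sibs = [c for c in g.children_of(gp) if c != p]
    if not sibs:
        return None
    s = sibs[0]
    kids = g.children_of(p)
    c = kids[rng.integers(len(kids))]
    if g.node_time[s] >= g.node_time[p]:
        return None
    return (c, s, gp, p)


def propose_state(g: Genealogy, node: int, rng: np.random.Generator):
    """Symmetric integer random-walk on one internal node's allele state."""
    delta = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
    return g.state[node] + delta


# ----------------------------------------------------------------------
# the sampler


def run_chain(
    data: Sequence[np.ndarray] | GenotypeDataset,
    priors: Optional[PriorSpec] = None,
    shape: str = "exponential",
    iterations: int = 200_000,
    thinning: int = 100,
    seed: int = 0,
    burn_in_frac: float = 0.1,
) -> PosteriorChains:
    """Metropolis-Hastings over genealogies and demographic parameters.

    ``data`` is a GenotypeDataset slice or a list of per-locus integer
    allele-size arrays (gene copies).  With zero loci the sampler
    explores the prior (the standard correctness check).  Proposal
    scales adapt during the burn-in fraction only and are frozen
    afterwards, preserving detailed balance of the recorded stretch.
    """
    if priors is None:
        priors = PriorSpec.default()
    if iterations < thinning:
        raise ValueError("iterations must be >= thinning")
    if isinstance(data, GenotypeDataset):
        data = [data.sizes_at_locus(j) for j in range(data.n_loci)]
        data = [d for d in data if d.size >= 2]
    data = [np.asarray(d, dtype=np.int64) for d in data]
    rng = np.random.default_rng(seed)
    state = _init_state(data, priors, shape, rng)
    L = len(data)
    n_theta = max(L, 1)

    # pack state into padded arrays for the compiled sweep
    max_nl = max((d.size for d in data), default=2)
    maxn = 2 * max_nl - 1
    parent = np.full((max(L, 1), maxn), -1, dtype=np.int64)
    node_time = np.zeros((max(L, 1), maxn), dtype=np.float64)
    astate = np.zeros((max(L, 1), maxn), dtype=np.int64)
    child1 = np.full((max(L, 1), maxn), -1, dtype=np.int64)
    child2 = np.full((max(L, 1), maxn), -1, dtype=np.int64)
    n_leaves = np.array([d.size for d in data] or [2], dtype=np.int64)
    for j in range(L):
        g = state.genealogies[j]
        nn = g.parent.shape[0]
        parent[j, :nn] = g.parent
        node_time[j, :nn] = g.node_time
        astate[j, :nn] = g.state
        for i, pa in enumerate(g.parent):
            if pa < 0:
                continue
            if child1[j, pa] < 0:
                child1[j, pa] = i
            else:
                child2[j, pa] = i

    lp = np.array(
        [state.log_params["N0"], state.log_params["N1"], state.log_params["T"]],
        dtype=np.float64,
    )
    ltheta = np.asarray(state.log_params["theta"], dtype=np.float64).copy()
    alpha = np.array([state.alpha[n] for n in PARAM_NAMES], dtype=np.float64)
    sigma = np.array([state.sigma[n] for n in PARAM_NAMES], dtype=np.float64)
    am = np.array([priors.block(n).alpha_mean for n in PARAM_NAMES])
    asd = np.array([priors.block(n).alpha_sd for n in PARAM_NAMES])
    sm = np.array([priors.block(n).sigma_mean for n in PARAM_NAMES])
    ssd = np.array([priors.block(n).sigma_sd for n in PARAM_NAMES])
    scales = np.array([0.15, 0.15, 0.2, 0.12, 0.15, 0.1])
    code = _SHAPE_CODE[shape]

    def sweep(n_iter: int, thin: int, sd: int) -> tuple[np.ndarray, np.ndarray]:
        rec = np.empty((n_iter // thin, 4), dtype=np.float64)
        acc = np.zeros((5, 2), dtype=np.int64)
        nrec = mcmc_kernel(
            parent, node_time, astate, child1, child2, n_leaves, L,
            lp, ltheta, alpha, sigma, am, asd, sm, ssd,
            code, n_iter, thin, sd, scales, rec, acc,
        )
        return rec[:nrec], acc

    # burn-in pilot: adapt the demographic-parameter step once, then freeze
    burn = int(burn_in_frac * iterations)
    if burn > 0:
        _, acc = sweep(burn, max(burn, 1), int(rng.integers(2**31)))
        rate = acc[0, 0] / max(acc[0, 1], 1)
        if rate < 0.15:
            scales[:4] *= 0.6
        elif rate > 0.6:
            scales[:4] *= 1.4

    rec, acc = sweep(iterations, thinning, int(rng.integers(2**31)))
    records = pd.DataFrame(
        rec, columns=["log10_N0", "log10_N1", "log10_T", "log10_theta"]
    )
    keys = ("param", "hyper", "time", "topo", "state")
    acc_rates = {
        k: (acc[i, 0] / acc[i, 1] if acc[i, 1] else float("nan"))
        for i, k in enumerate(keys)
    }
    logger.info("run_chain acceptance rates: %s", acc_rates)
    return PosteriorChains(
        records=records,
        meta={
            "iterations": iterations,
            "thinning": thinning,
            "seed": seed,
            "shape": shape,
            "n_loci": L,
            "acceptance": acc_rates,
        },
    )


def run_replicated(
    data,
    priors: Optional[PriorSpec] = None,
    shape: str = "exponential",
    n_chains: int = 5,
    iterations: int = 200_000,
    thinning: int = 100,
    seed: int = 0,
) -> list[PosteriorChains]:
    """Independent replicate chains (distinct derived seeds)."""
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_chains)]
    return [
        run_chain(
            data,
            priors=priors,
            shape=shape,
            iterations=iterations,
            thinning=thinning,
            seed=s,
        )
        for s in seeds
    ]
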