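"""Coalescent simulation of microsatellite genotypes.

The engine is the time-rescaled Kingman coalescent: waiting times are
drawn on the cumulative-intensity scale (closed-form inverse from
:class:`~msatdemog.trajectory.DemographicTrajectory`), so arbitrary
single-change size histories are simulated exactly.  Mutations fall as
a Poisson process on branches and displace allele size on the integer
repeat-unit lattice under a strict-stepwise or two-phase model, with
the root allele at 0 (all downstream statistics are
translation-invariant).  Serial (temporal) sampling, island-model
subdivision, and a forward Wright–Fisher bottleneck (for mode-shift
power semantics, where "breeding individuals" matters) are layered on
top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import GenotypeDataset, LocusDef, MISSING
from .mutation import MutationModel
from .trajectory import DemographicTrajectory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubdivisionSpec:
    """Island-model subdivision: constant-size demes with symmetric
    migration at rate ``migration`` per lineage per generation, optionally
    merging into the ancestral (trajectory-governed) population at
    ``split_time`` generations ago."""

    deme_sizes: tuple[float, ...]
    migration: float
    split_time: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.deme_sizes) < 1 or any(s <= 0 for s in self.deme_sizes):
            raise ValueError("deme sizes must be positive and non-empty")
        if not 0.0 <= self.migration < 1.0:
            raise ValueError("migration rate must lie in [0, 1)")
        if (
            len(self.deme_sizes) > 1
            and self.migration == 0.0
            and self.split_time is None
        ):
            raise ValueError(
                "multiple demes with zero migration and no split time never coalesce"
            )


def _resolve_mu(traj: DemographicTrajectory, model: MutationModel) -> float:
    """Per-generation mutation rate: explicit mu wins; otherwise theta is
    read as 4*Ne*mu with Ne = N0 (equilibrium convention)."""
    if model.mu is not None:
        return model.mu
    if model.theta is not None:
        return model.theta / (4.0 * traj.N0)
    raise ValueError("MutationModel needs mu or theta to simulate")


# ----------------------------------------------------------------------
# tree building


def _sim_tree_times(
    sample_times: Sequence[tuple[float, int]],
    traj: DemographicTrajectory,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Coalescent tree under the trajectory with serial sampling.

    ``sample_times`` is a list of (time, n_lineages) entry points, time
    in generations before present.  Returns (parent, node_time) arrays;
    leaves occupy the first n indices in entry order, the root is last.
    Pairwise coalescence rate is 1/(2N(t)) (diploid convention).
    """
    n = sum(c for _, c in sample_times)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)
    # leaves keep caller order for labelling; entries are processed by time
    leaf_blocks: list[tuple[float, list[int]]] = []
    base = 0
    for t_s, c in sample_times:
        leaf_blocks.append((t_s, list(range(base, base + c))))
        base += c
    for t_s, idxs in leaf_blocks:
        for i in idxs:
            node_time[i] = t_s
    pending = sorted(leaf_blocks, key=lambda b: b[0])

    active: list[int] = []
    t = 0.0
    nxt = n
    pi = 0
    while pi < len(pending) and pending[pi][0] <= t:
        active.extend(pending[pi][1])
        pi += 1
    while len(active) > 1 or pi < len(pending):
        k = len(active)
        if k < 2:
            t = pending[pi][0]
            active.extend(pending[pi][1])
            pi += 1
            continue
        # next candidate coalescence on the intensity scale
        e = rng.exponential(1.0)
        target = traj.intensity(t) + 2.0 * e * 2.0 / (k * (k - 1))
        t_cand = traj.inverse_intensity(target)
        if pi < len(pending) and t_cand >= pending[pi][0]:
            t = pending[pi][0]
            active.extend(pending[pi][1])
            pi += 1
            continue
        t = t_cand
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = t
        active.append(nxt)
        nxt += 1
    return parent, node_time


def _drop_mutations(
    parent: np.ndarray,
    node_time: np.ndarray,
    mu: float,
    model: MutationModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson mutations on branches; returns allele size per node."""
    n_nodes = parent.shape[0]
    state = np.zeros(n_nodes, dtype=np.int64)
    # parents always carry larger indices than their children here
    for node in range(n_nodes - 2, -1, -1):
        branch = node_time[parent[node]] - node_time[node]
        nm = rng.poisson(mu * branch)
        if nm:
            state[node] = state[parent[node]] + model.sample_steps(nm, rng).sum()
        else:
            state[node] = state[parent[node]]
    return state


def simulate_locus(
    n_genes: int,
    traj: DemographicTrajectory,
    model: MutationModel,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Allele sizes for ``n_genes`` gene copies sampled at t = 0.

    Sizes are integer offsets from the root allele (state 0); with
    ``theta = 0`` the sample is monomorphic.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 gene copies")
    rng = np.random.default_rng(seed)
    mu = _resolve_mu(traj, model)
    parent, node_time = _sim_tree_times([(0.0, n_genes)], traj, rng)
    state = _drop_mutations(parent, node_time, mu, model, rng)
    return state[:n_genes]


# ----------------------------------------------------------------------
# dataset-level simulators


def _pair_into_dataset(
    per_locus_sizes: list[np.ndarray],
    prefix: str,
    population: str,
    rng: np.random.Generator,
    deme: Optional[Sequence[str]] = None,
    sample_year: Optional[Sequence[int]] = None,
) -> GenotypeDataset:
    """Pair consecutive gene copies into diploids."""
    n_ind = per_locus_sizes[0].shape[0] // 2
    L = len(per_locus_sizes)
    calls = np.empty((n_ind, L, 2), dtype=float)
    for j, sizes in enumerate(per_locus_sizes):
        calls[:, j, 0] = sizes[0::2][:n_ind]
        calls[:, j, 1] = sizes[1::2][:n_ind]
    loci = [LocusDef(f"L{j + 1:02d}") for j in range(L)]
    return GenotypeDataset(
        individuals=[f"{prefix}{i + 1:03d}" for i in range(n_ind)],
        loci=loci,
        calls=calls,
        population=np.array([population] * n_ind, dtype=object),
        deme=None if deme is None else np.asarray(deme, dtype=object),
        sample_year=None if sample_year is None else np.asarray(sample_year),
    )


def simulate_dataset(
    n_ind: int,
    n_loci: int,
    traj: DemographicTrajectory,
    model: MutationModel,
    seed: int,
    population: str = "pop1",
    prefix: str = "ind",
) -> GenotypeDataset:
    """Independent loci; gene copies paired into ``n_ind`` diploids.

    Per-locus streams are seeded by counter from the master seed so any
    locus is reproducible in isolation.
    """
    root = np.random.SeedSequence(seed)
    locus_seeds = root.spawn(n_loci + 1)
    per_locus = [
        simulate_locus(2 * n_ind, traj, model, np.random.default_rng(locus_seeds[j]))
        for j in range(n_loci)
    ]
    rng = np.random.default_rng(locus_seeds[-1])
    return _pair_into_dataset(per_locus, prefix, population, rng)


def simulate_temporal_pair(
    traj: DemographicTrajectory,
    model: MutationModel,
    gap_generations: float,
    n_hist: int,
    n_contemp: int,
    seed: int,
    n_loci: int = 10,
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Serial samples from one lineage: a historical sample taken
    ``gap_generations`` before the contemporary one."""
    if gap_generations < 0:
        raise ValueError("gap must be >= 0")
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(n_loci)
    mu = _resolve_mu(traj, model)
    contemp_sizes, hist_sizes = [], []
    for j in range(n_loci):
        rng = np.random.default_rng(seeds[j])
        parent, node_time = _sim_tree_times(
            [(0.0, 2 * n_contemp), (float(gap_generations), 2 * n_hist)], traj, rng
        )
        state = _drop_mutations(parent, node_time, mu, model, rng)
        contemp_sizes.append(state[: 2 * n_contemp])
        hist_sizes.append(state[2 * n_contemp : 2 * (n_contemp + n_hist)])
    rng = np.random.default_rng(root.spawn(1)[0])
    contemp = _pair_into_dataset(contemp_sizes, "c", "contemporary", rng)
    hist = _pair_into_dataset(hist_sizes, "h", "historical", rng)
    return hist, contemp


def simulate_subdivided(
    spec: SubdivisionSpec,
    traj: DemographicTrajectory,
    model: MutationModel,
    n_per_deme: Sequence[int],
    seed: int,
    n_loci: int = 10,
    population: str = "pop1",
) -> GenotypeDataset:
    """Structured coalescent under a symmetric island model.

    Demes hold constant sizes until ``split_time`` (if given), when all
    lineages merge into a single population following ``traj``.  With a
    single deme this reduces to :func:`simulate_dataset`.
    """
    D = len(spec.deme_sizes)
    if len(n_per_deme) != D:
        raise ValueError("n_per_deme must match deme count")
    if D == 1:
        ds = simulate_dataset(n_per_deme[0], n_loci, traj, model, seed, population)
        ds.deme = np.array(["deme1"] * ds.n_individuals, dtype=object)
        return ds
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(n_loci)
    mu = _resolve_mu(traj, model)
    n_genes_total = 2 * int(sum(n_per_deme))
    per_locus = []
    for j in range(n_loci):
        rng = np.random.default_rng(seeds[j])
        parent, node_time = _sim_structured_tree(spec, traj, n_per_deme, rng)
        state = _drop_mutations(parent, node_time, mu, model, rng)
        per_locus.append(state[:n_genes_total])
    deme_labels = []
    for d, c in enumerate(n_per_deme):
        deme_labels.extend([f"deme{d + 1}"] * c)
    rng = np.random.default_rng(root.spawn(1)[0])
    return _pair_into_dataset(
        per_locus, "s", population, rng, deme=deme_labels
    )


def _sim_structured_tree(
    spec: SubdivisionSpec,
    traj: DemographicTrajectory,
    n_per_deme: Sequence[int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Gillespie structured coalescent; merges demes at split_time."""
    n = 2 * int(sum(n_per_deme))
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)
    deme_of: dict[int, int] = {}
    base = 0
    for d, c in enumerate(n_per_deme):
        for i in range(base, base + 2 * c):
            deme_of[i] = d
        base += 2 * c
    active = list(range(n))
    t = 0.0
    nxt = n
    split = spec.split_time if spec.split_time is not None else np.inf
    while len(active) > 1:
        if t >= split:
            break
        by_deme: dict[int, list[int]] = {}
        for a in active:
            by_deme.setdefault(deme_of[a], []).append(a)
        coal_rates = {
            d: len(v) * (len(v) - 1) / 2.0 / (2.0 * spec.deme_sizes[d])
            for d, v in by_deme.items()
        }
        mig_rate = spec.migration * len(active)
        total = sum(coal_rates.values()) + mig_rate
        if total == 0:
            t = split
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt >= split:
            t = split
            continue
        t += dt
        u = rng.random() * total
        if u < mig_rate:
            a = active[rng.integers(len(active))]
            others = [d for d in range(len(spec.deme_sizes)) if d != deme_of[a]]
            deme_of[a] = others[rng.integers(len(others))]
            continue
        u -= mig_rate
        for d, r in coal_rates.items():
            if u < r:
                v = by_deme[d]
                i, j = rng.choice(len(v), size=2, replace=False)
                a, b = v[i], v[j]
                active.remove(a)
                active.remove(b)
                parent[a] = nxt
                parent[b] = nxt
                node_time[nxt] = t
                deme_of[nxt] = d
                active.append(nxt)
                nxt += 1
                break
            u -= r
    # ancestral panmictic phase under traj (time axis shifted to split)
    while len(active) > 1:
        k = len(active)
        e = rng.exponential(1.0)
        rel = max(t - split, 0.0)
        target = traj.intensity(rel) + 4.0 * e / (k * (k - 1))
        t = split + traj.inverse_intensity(target)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = t
        active.append(nxt)
        nxt += 1
    return parent, node_time


# ----------------------------------------------------------------------
# forward Wright–Fisher bottleneck (mode-shift power semantics)


def simulate_wf_bottleneck_locus(
    theta: float,
    model: MutationModel,
    n_breeders: int,
    generations: int,
    n_sample_genes: int,
    rng: np.random.Generator,
    mu: float = 5e-4,
) -> np.ndarray:
    """One locus through a forward Wright–Fisher collapse.

    An equilibrium sample of ``2 * n_breeders`` gene copies (coalescent,
    scaled rate ``theta``) founds the bottlenecked population; each of
    ``generations`` generations resamples the ``2 * n_breeders`` copies
    with replacement and mutates each at rate ``mu``.  The returned
    sample of ``n_sample_genes`` copies is drawn multinomially from the
    final gene pool (sampled individuals need not be the breeders).
    """
    traj = DemographicTrajectory.constant(theta / (4.0 * mu))
    pool = simulate_locus(2 * n_breeders, traj, model.with_mu(mu), rng)
    for _ in range(generations):
        pool = rng.choice(pool, size=2 * n_breeders, replace=True)
        mut = rng.random(2 * n_breeders) < mu
        if mut.any():
            pool = pool.copy()
            pool[mut] += model.sample_steps(int(mut.sum()), rng)
    return rng.choice(pool, size=n_sample_genes, replace=True)


# ----------------------------------------------------------------------
# study-shaped fixture bundle


def study_scenario(seed: int, n_loci: int = 10) -> dict[str, GenotypeDataset]:
    """Synthetic analog of the four-sample study design.

    Two long-isolated populations sampled twice ~19 generations apart
    (NW: n = 5 historical / 148 contemporary; SSN: 16 / 127), each with
    a decline from ancestral Ne ~ 1800 to current Ne ~ 150 at ~300
    generations; the contemporary SSN is split into three demes with
    moderate subdivision.  Deterministic under the seed.
    """
    root = np.random.SeedSequence(seed)
    s_nw, s_ssn, s_demes = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(3)]
    model = MutationModel.tpm_variance(0.95, 12.0, mu=5e-4)
    traj = DemographicTrajectory(N0=150, N1=1800, T=300, shape="exponential")
    gap = 19  # 95 years at 5-year generations

    nw_h, nw_c = simulate_temporal_pair(traj, model, gap, 5, 148, s_nw, n_loci)
    ssn_h, _ = simulate_temporal_pair(traj, model, gap, 16, 127, s_ssn, n_loci)
    # contemporary SSN carries three-deme structure (Fst target 0.05-0.13)
    ssn_c = simulate_subdivided(
        SubdivisionSpec(deme_sizes=(50.0, 50.0, 50.0), migration=0.05, split_time=300.0),
        DemographicTrajectory.constant(1800.0),
        model,
        n_per_deme=[44, 32, 51],
        seed=s_demes,
        n_loci=n_loci,
    )
    for name, ds, year in (
        ("NW_H", nw_h, 1915),
        ("NW_C", nw_c, 2008),
        ("SSN_H", ssn_h, 1915),
        ("SSN_C", ssn_c, 2008),
    ):
        ds.population = np.array([name] * ds.n_individuals, dtype=object)
        ds.sample_year = np.full(ds.n_individuals, year)
        ds.individuals = [f"{name}_{i + 1:03d}" for i in range(ds.n_individuals)]
    ssn_c.deme = np.array(
        ["North"] * 44 + ["Central"] * 32 + ["South"] * 51, dtype=object
    )
    return {"NW_H": nw_h, "NW_C": nw_c, "SSN_H": ssn_h, "SSN_C": ssn_c}
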