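"""Coalescent simulator: closed-form equilibria, drift expectations,
subdivision, and the study-shaped scenario bundle."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from msatdemog._kernels import equilibrium_batch
from msatdemog.coalsim import (
    SubdivisionSpec,
    study_scenario,
    simulate_dataset,
    simulate_locus,
    simulate_subdivided,
    simulate_temporal_pair,
)
from msatdemog.mutation import MutationModel
from msatdemog.stats import fst_wc, unbiased_he
from msatdemog.trajectory import DemographicTrajectory


def test_trajectory_intensity_closed_forms():
    const = DemographicTrajectory.constant(500.0)
    assert const.intensity(1000.0) == pytest.approx(2.0)
    assert const.inverse_intensity(2.0) == pytest.approx(1000.0)
    # exponential with N1 == N0 degenerates to constant
    exp_flat = DemographicTrajectory(N0=500, N1=500, T=100, shape="exponential")
    assert exp_flat.intensity(1000.0) == pytest.approx(2.0)
    # linear vs numerical quadrature
    lin = DemographicTrajectory(N0=100, N1=1000, T=500, shape="linear")
    from scipy.integrate import quad

    for t in (250.0, 500.0, 800.0):
        num, _ = quad(lambda u: 1.0 / lin.size_at(u), 0, t, limit=200)
        assert lin.intensity(t) == pytest.approx(num, abs=1e-8)
        assert lin.inverse_intensity(lin.intensity(t)) == pytest.approx(t, rel=1e-9)
    expo = DemographicTrajectory(N0=150, N1=2000, T=300, shape="exponential")
    for t in (100.0, 300.0, 1000.0):
        num, _ = quad(lambda u: 1.0 / expo.size_at(u), 0, t, limit=200)
        assert expo.intensity(t) == pytest.approx(num, abs=1e-8)
        assert expo.inverse_intensity(expo.intensity(t)) == pytest.approx(t, rel=1e-9)


def test_theta_zero_is_monomorphic():
    traj = DemographicTrajectory.constant(1000.0)
    sizes = simulate_locus(30, traj, MutationModel.smm(theta=0.0), seed=1)
    assert np.all(sizes == sizes[0])


def test_smm_equilibrium_matches_ohta_kimura():
    """Strict SMM, constant N: E[He] = 1 - 1/sqrt(1+2 theta) and
    E[(x_i - x_j)^2] = theta."""
    theta = 2.0
    arr = equilibrium_batch(50, 2000, theta, 1.0, 1.0, 0, 99)
    hes, msq = [], []
    for row in arr:
        n = row.size
        _, counts = np.unique(row, return_counts=True)
        p = counts / n
        hes.append(n / (n - 1) * (1 - (p**2).sum()))
        d = row[:, None] - row[None, :]
        iu = np.triu_indices(n, 1)
        msq.append(float((d[iu] ** 2).mean()))
    hes, msq = np.array(hes), np.array(msq)
    he_expect = 1 - 1 / math.sqrt(1 + 2 * theta)
    assert abs(hes.mean() - he_expect) < 3 * hes.std() / math.sqrt(len(hes))
    assert abs(msq.mean() - theta) < 3 * msq.std() / math.sqrt(len(msq))


def test_general_simulator_agrees_with_kernel_at_constant_n():
    """The time-rescaled general path and the fast equilibrium kernel
    sample the same distribution at constant N (He comparison)."""
    theta = 1.5
    traj = DemographicTrajectory.constant(theta / (4 * 5e-4))
    model = MutationModel.smm(mu=5e-4)
    hes_gen = []
    for s in range(400):
        sizes = simulate_locus(40, traj, model, seed=s)
        _, c = np.unique(sizes, return_counts=True)
        p = c / 40
        hes_gen.append(40 / 39 * (1 - (p**2).sum()))
    arr = equilibrium_batch(40, 400, theta, 1.0, 1.0, 0, 5)
    hes_k = []
    for row in arr:
        _, c = np.unique(row, return_counts=True)
        p = c / 40
        hes_k.append(40 / 39 * (1 - (p**2).sum()))
    assert sps.mannwhitneyu(hes_gen, hes_k).pvalue > 0.001


def test_distinct_alleles_increase_with_theta():
    ks = []
    for theta in (0.5, 2.0, 8.0):
        arr = equilibrium_batch(40, 300, theta, 1.0, 1.0, 0, 17)
        ks.append(np.mean([len(np.unique(r)) for r in arr]))
    assert ks[0] < ks[1] < ks[2]


def test_msprime_oracle_equilibrium_he():
    """Independent coalescent engine: msprime ancestry + our SMM mutations
    dropped on its trees reproduces the same equilibrium He."""
    msprime = pytest.importorskip("msprime")
    theta = 2.0
    mu = 5e-4
    N = theta / (4 * mu)
    rng = np.random.default_rng(11)
    model = MutationModel.smm(mu=mu)
    hes = []
    reps = msprime.sim_ancestry(
        samples=25, population_size=N, ploidy=2, num_replicates=600, random_seed=7
    )
    for ts in reps:
        tree = ts.first()
        state = {tree.root: 0}
        for node in tree.nodes(order="preorder"):
            if node == tree.root:
                continue
            br = tree.branch_length(node)
            nm = rng.poisson(mu * br)
            state[node] = state[tree.parent(node)] + (
                int(model.sample_steps(nm, rng).sum()) if nm else 0
            )
        sizes = np.array([state[u] for u in ts.samples()])
        _, c = np.unique(sizes, return_counts=True)
        p = c / sizes.size
        hes.append(sizes.size / (sizes.size - 1) * (1 - (p**2).sum()))
    he_expect = 1 - 1 / math.sqrt(1 + 2 * theta)
    hes = np.array(hes)
    assert abs(hes.mean() - he_expect) < 3 * hes.std() / math.sqrt(len(hes))


def test_dataset_shape_and_determinism():
    traj = DemographicTrajectory.constant(500.0)
    model = MutationModel.smm(theta=1.0)
    a = simulate_dataset(5, 10, traj, model, seed=42)
    b = simulate_dataset(5, 10, traj, model, seed=42)
    assert a.n_individuals == 5 and a.n_loci == 10
    np.testing.assert_array_equal(a.calls, b.calls)
    c = simulate_dataset(5, 10, traj, model, seed=43)
    assert not np.array_equal(a.calls, c.calls)


def test_equilibrium_he_in_study_range():
    traj = DemographicTrajectory.constant(500.0)
    model = MutationModel.smm(theta=1.0)
    hes = []
    for s in range(60):
        ds = simulate_dataset(30, 10, traj, model, seed=s)
        from msatdemog.io import allele_counts

        hes.append(np.mean([unbiased_he(c) for c in allele_counts(ds) if c]))
    # theta=1 mean He around 0.42; replicate means mostly in 0.3-0.6
    assert 0.3 < np.mean(hes) < 0.6


def test_temporal_pair_gap_zero_fst_near_zero():
    traj = DemographicTrajectory.constant(300.0)
    model = MutationModel.smm(theta=2.0)
    fsts = []
    for s in range(30):
        h, c = simulate_temporal_pair(traj, model, 0.0, 40, 40, seed=s, n_loci=6)
        fsts.append(fst_wc([h, c]))
    assert abs(np.mean(fsts)) < 0.01


def test_temporal_fst_tracks_drift_expectation():
    """Temporal Fst grows with the sampling gap and sits near the
    identity-probability prediction gap/(gap + 4Ne) (the genealogical
    path between a historical and a contemporary gene is gap + 2 x
    Exp(2Ne) generations)."""
    Ne = 150.0
    traj = DemographicTrajectory.constant(Ne)
    model = MutationModel.smm(theta=1.0)
    means = {}
    for gap in (0.0, 20.0, 100.0):
        vals = [
            fst_wc(simulate_temporal_pair(traj, model, gap, 30, 30, seed=s, n_loci=8))
            for s in range(25)
        ]
        means[gap] = np.mean(vals)
    assert means[0.0] < means[20.0] < means[100.0]
    gap = 19.0
    vals = np.array(
        [
            fst_wc(simulate_temporal_pair(traj, model, gap, 30, 30, seed=s, n_loci=8))
            for s in range(40)
        ]
    )
    expect = gap / (gap + 4 * Ne)
    assert 0.5 * expect < vals.mean() < 1.5 * expect


def test_temporal_fst_matches_msprime_serial_sampling():
    """Dual-route check: an independent coalescent engine with ancient
    samples yields the same Weir-Cockerham Fst distribution."""
    msprime = pytest.importorskip("msprime")
    from msatdemog.coalsim import _pair_into_dataset

    Ne, gap, mu = 150.0, 19.0, 1.0 / (4 * 150.0)
    model = MutationModel.smm(mu=mu)
    rng = np.random.default_rng(23)
    ours = np.array(
        [
            fst_wc(
                simulate_temporal_pair(
                    DemographicTrajectory.constant(Ne), model, gap, 30, 30, seed=s, n_loci=8
                )
            )
            for s in range(30)
        ]
    )
    theirs = []
    for s in range(30):
        per_locus_c, per_locus_h = [], []
        reps = msprime.sim_ancestry(
            samples=[
                msprime.SampleSet(30, time=0),
                msprime.SampleSet(30, time=gap),
            ],
            population_size=Ne,
            ploidy=2,
            num_replicates=8,
            random_seed=1000 + s,
        )
        for ts in reps:
            tree = ts.first()
            state = {tree.root: 0}
            for node in tree.nodes(order="preorder"):
                if node == tree.root:
                    continue
                nm = rng.poisson(mu * tree.branch_length(node))
                state[node] = state[tree.parent(node)] + (
                    int(model.sample_steps(nm, rng).sum()) if nm else 0
                )
            sizes = np.array([state[u] for u in ts.samples()])
            per_locus_c.append(sizes[:60])
            per_locus_h.append(sizes[60:])
        contemp = _pair_into_dataset(per_locus_c, "c", "contemp", rng)
        hist = _pair_into_dataset(per_locus_h, "h", "hist", rng)
        theirs.append(fst_wc([hist, contemp]))
    theirs = np.array(theirs)
    se = math.sqrt(ours.var() / ours.size + theirs.var() / theirs.size)
    assert abs(ours.mean() - theirs.mean()) < 3 * se + 0.005


def test_subdivision_limits():
    model = MutationModel.smm(theta=1.0)
    traj = DemographicTrajectory.constant(300.0)
    # very high migration: demes behave as one population
    spec = SubdivisionSpec(deme_sizes=(150.0, 150.0), migration=0.5)
    ds = simulate_subdivided(spec, traj, model, [25, 25], seed=1, n_loci=6)
    a, b = ds.select(deme="deme1"), ds.select(deme="deme2")
    assert fst_wc([a, b]) < 0.05
    # single deme collapses to the plain simulator interface
    one = simulate_subdivided(
        SubdivisionSpec(deme_sizes=(300.0,), migration=0.0, split_time=None),
        traj,
        model,
        [20],
        seed=2,
        n_loci=4,
    )
    assert one.n_individuals == 20 and set(one.deme) == {"deme1"}
    # zero migration with no split time cannot coalesce
    with pytest.raises(ValueError):
        SubdivisionSpec(deme_sizes=(100.0, 100.0), migration=0.0)


def test_subdivision_moderate_fst_calibration():
    """Three demes with the scenario's migration land in the moderate
    differentiation band (pairwise Fst ~ 0.05-0.13)."""
    model = MutationModel.tpm_variance(0.95, 12.0, mu=5e-4)
    spec = SubdivisionSpec(deme_sizes=(50.0, 50.0, 50.0), migration=0.05, split_time=300.0)
    traj = DemographicTrajectory.constant(1800.0)
    vals = []
    for s in range(6):
        ds = simulate_subdivided(spec, traj, model, [30, 30, 30], seed=s, n_loci=10)
        demes = [ds.select(deme=d) for d in ("deme1", "deme2", "deme3")]
        for i in range(3):
            for j in range(i + 1, 3):
                vals.append(fst_wc([demes[i], demes[j]]))
    mean_fst = float(np.mean(vals))
    assert 0.05 <= mean_fst <= 0.13


def test_study_scenario_shapes():
    bundle = study_scenario(7, n_loci=10)
    assert {k: v.n_individuals for k, v in bundle.items()} == {
        "NW_H": 5,
        "NW_C": 148,
        "SSN_H": 16,
        "SSN_C": 127,
    }
    ssn = bundle["SSN_C"]
    assert sorted(set(ssn.deme)) == ["Central", "North", "South"]
    again = study_scenario(7, n_loci=10)
    np.testing.assert_array_equal(ssn.calls, again["SSN_C"].calls)
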