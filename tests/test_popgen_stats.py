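"""Diversity estimators, F-statistics, exact tests, and corrections."""

import math
from collections import Counter
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from msatdemog.dataset import GenotypeDataset, LocusDef
from msatdemog.exact import contingency_exact, hwe_exact
from msatdemog.mutation import MutationModel
from msatdemog.stats import (
    allelic_richness,
    fis_wc,
    fst_wc,
    genic_diff_exact,
    hwe_exact_locus,
    ld_exact,
    paired_diversity_test,
    rst,
    sequential_bonferroni,
    unbiased_he,
)
from msatdemog.trajectory import DemographicTrajectory
from msatdemog.coalsim import simulate_dataset


def _one_locus_dataset(pairs, pop="p"):
    calls = np.array([[list(g)] for g in pairs], dtype=float)
    return GenotypeDataset(
        individuals=[f"i{k}" for k in range(len(pairs))],
        loci=[LocusDef("L")],
        calls=calls,
        population=np.array([pop] * len(pairs), dtype=object),
    )


# ----------------------------------------------------------------------
# He and allelic richness


@pytest.mark.parametrize(
    "counts,expected",
    [
        ({100: 20}, 0.0),  # monomorphic
        ({1: 1, 2: 1, 3: 1, 4: 1}, 1.0),  # all gene copies distinct
        ({0: 10, 1: 10}, (20 / 19) * 0.5),  # hand evaluation
    ],
)
def test_unbiased_he_values(counts, expected):
    assert unbiased_he(counts) == pytest.approx(expected)


@given(
    st.dictionaries(
        st.integers(0, 20), st.integers(1, 30), min_size=1, max_size=6
    )
)
@settings(max_examples=50, deadline=None)
def test_unbiased_he_bounds(counts):
    assert 0.0 <= unbiased_he(counts) <= 1.0


def test_allelic_richness_brute_force():
    counts = {0: 6, 1: 2}
    pool = [0] * 6 + [1] * 2
    brute = np.mean(
        [len({pool[i] for i in c}) for c in combinations(range(8), 4)]
    )
    assert allelic_richness(counts, 4) == pytest.approx(brute)
    # N == g returns observed k; monomorphic gives 1
    assert allelic_richness({5: 4, 9: 4}, 8) == pytest.approx(2.0)
    assert allelic_richness({5: 12}, 6) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        allelic_richness({5: 4}, 8)


# ----------------------------------------------------------------------
# Fis / Fst / Rst


def test_fis_all_heterozygous_is_minus_one():
    ds = _one_locus_dataset([(0, 1)] * 20)
    assert fis_wc(ds) == pytest.approx(-1.0, abs=0.08)


def test_fis_near_zero_under_random_mating():
    traj = DemographicTrajectory.constant(1000.0)
    ds = simulate_dataset(200, 10, traj, MutationModel.smm(theta=2.0), seed=7)
    assert abs(fis_wc(ds)) < 0.05


def test_fis_positive_for_pooled_demes():
    # Wahlund effect: two demes fixed-ish for different alleles
    a = [(0, 0)] * 30 + [(0, 1)] * 5
    b = [(4, 4)] * 30 + [(4, 5)] * 5
    ds = _one_locus_dataset(a + b)
    assert fis_wc(ds) > 0.5


def test_fis_monomorphic_signalled():
    ds = _one_locus_dataset([(0, 0)] * 5)
    with pytest.raises(ValueError):
        fis_wc(ds)


def test_fst_fixed_difference_and_iid():
    a = _one_locus_dataset([(0, 0)] * 25, "a")
    b = _one_locus_dataset([(9, 9)] * 25, "b")
    assert fst_wc([a, b]) == pytest.approx(1.0)
    traj = DemographicTrajectory.constant(1000.0)
    big = simulate_dataset(300, 8, traj, MutationModel.smm(theta=2.0), seed=3)
    one, two = big.subset(range(150)), big.subset(range(150, 300))
    assert abs(fst_wc([one, two])) < 0.02


def test_fst_matches_hand_computed_components():
    # two pops, one locus, two alleles; worked variance components
    a = _one_locus_dataset([(0, 0), (0, 0), (0, 1), (1, 1)], "a")
    b = _one_locus_dataset([(1, 1), (1, 1), (0, 1)], "b")

    def wc_theta(pops):
        r = len(pops)
        ns = np.array([len(p) for p in pops], dtype=float)
        nbar = ns.mean()
        nc = (ns.sum() - (ns**2).sum() / ns.sum()) / (r - 1)
        num = den = 0.0
        for allele in (0, 1):
            p_i = np.array(
                [sum(g.count(allele) for g in p) / (2 * len(p)) for p in pops]
            )
            h_i = np.array(
                [sum(1 for g in p if sorted(g) != [g[0]] * 2 and allele in g) / len(p) for p in pops]
            )
            pbar = (ns * p_i).sum() / ns.sum()
            hbar = (ns * h_i).sum() / ns.sum()
            s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            a_ = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
            )
            b_ = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c_ = hbar / 2
            num += a_
            den += a_ + b_ + c_
        return num / den

    expected = wc_theta([[(0, 0), (0, 0), (0, 1), (1, 1)], [(1, 1), (1, 1), (0, 1)]])
    assert fst_wc([a, b]) == pytest.approx(expected, abs=1e-12)


def test_rst_fixed_sizes_and_identical():
    a = _one_locus_dataset([(10, 10)] * 20, "a")
    b = _one_locus_dataset([(20, 20)] * 20, "b")
    assert rst([a, b]) == pytest.approx(1.0)
    c = _one_locus_dataset([(10, 12), (12, 14), (10, 14)] * 7, "c")
    d = _one_locus_dataset([(10, 12), (12, 14), (10, 14)] * 7, "d")
    assert abs(rst([c, d])) < 0.05


def test_rst_exceeds_fst_under_large_step_divergence():
    # demes separated by many repeat units: size variance captures more
    a = _one_locus_dataset([(0, 1), (0, 0), (1, 1)] * 10, "a")
    b = _one_locus_dataset([(8, 9), (8, 8), (9, 9)] * 10, "b")
    assert rst([a, b]) > fst_wc([a, b])


# ----------------------------------------------------------------------
# exact tests


def test_hwe_single_individual_untestable():
    res = hwe_exact({(1, 2): 1})
    assert res.p_value == 1.0 and not res.testable


def test_hwe_enumeration_is_exhaustive():
    # AA=5, BB=5: all-homozygote table; p from complete enumeration
    res = hwe_exact({(1, 1): 5, (2, 2): 5}, method="enumeration")
    # independent oracle: enumerate pairings directly over heterozygote count
    n, na = 10, 10  # 10 individuals? no: 10 genes each allele
    # 2n = 20 gene copies, 10 of each allele; heterozygote count h even loop
    probs = {}
    for h in range(0, 11):
        if (10 - h) % 2:
            continue
        naa = (10 - h) // 2
        nbb = (10 - h) // 2
        lp = (
            math.lgamma(11)
            + h * math.log(2)
            + 2 * math.lgamma(11)
            - math.lgamma(21)
            - math.lgamma(naa + 1)
            - math.lgamma(h + 1)
            - math.lgamma(nbb + 1)
        )
        probs[h] = math.exp(lp)
    tot = sum(probs.values())
    p_obs = probs[0] / tot
    expected = sum(p for p in (v / tot for v in probs.values()) if p <= p_obs * (1 + 1e-9))
    assert res.p_value == pytest.approx(expected, rel=1e-9)


def test_hwe_monte_carlo_matches_enumeration():
    table = {(1, 1): 4, (1, 2): 1, (2, 2): 4}
    exact = hwe_exact(table, method="enumeration").p_value
    mc = hwe_exact(table, method="monte_carlo", reps=40000, seed=9).p_value
    se = math.sqrt(exact * (1 - exact) / 40000)
    assert abs(mc - exact) < 3 * se + 1e-4


def test_ld_perfect_association_and_oracle(rng):
    # second locus copies the first -> strong association
    pairs = [(0, 0)] * 12 + [(1, 1)] * 12
    calls = np.array([[list(g), list(g)] for g in pairs], dtype=float)
    ds = GenotypeDataset(
        individuals=[f"i{k}" for k in range(24)],
        loci=[LocusDef("A"), LocusDef("B")],
        calls=calls,
        population=np.array(["p"] * 24, dtype=object),
    )
    assert ld_exact(ds, 0, 1, method="monte_carlo", reps=5000, seed=2).p_value < 0.01

    # 2x2 toy table equals Fisher's exact probability test
    t = np.array([[4, 1], [1, 4]])
    ours = contingency_exact(t, method="enumeration").p_value
    _, fisher_p = sps.fisher_exact(t)
    assert ours == pytest.approx(fisher_p, rel=1e-9)


def test_ld_null_uniform():
    traj = DemographicTrajectory.constant(500.0)
    pvals = []
    for seed in range(40):
        ds = simulate_dataset(30, 2, traj, MutationModel.smm(theta=1.5), seed=seed)
        res = ld_exact(ds, 0, 1, method="monte_carlo", reps=2000, seed=seed)
        if res.testable:
            pvals.append(res.p_value)
    assert len(pvals) > 20
    # independently simulated loci: p-values roughly uniform
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_genic_diff_fixed_difference_and_oracle():
    a = _one_locus_dataset([(0, 0)] * 10, "a")
    b = _one_locus_dataset([(5, 5)] * 10, "b")
    per_locus, combined = genic_diff_exact(a, b, method="monte_carlo", reps=3000, seed=4)
    assert combined < 1e-3
    # enumeration oracle on a small 2-allele table
    t = np.array([[3, 2], [1, 4]])
    enum = contingency_exact(t, method="enumeration")
    mc = contingency_exact(t, method="monte_carlo", reps=40000, seed=11)
    se = math.sqrt(enum.p_value * (1 - enum.p_value) / 40000)
    assert abs(mc.p_value - enum.p_value) < 3 * se + 1e-4


def test_exact_tests_agree_with_enumeration_on_small_tables():
    # all 2-allele genotype tables with <= 10 gene copies
    for n_ind in range(2, 6):
        for naa in range(n_ind + 1):
            for nab in range(n_ind - naa + 1):
                nbb = n_ind - naa - nab
                table = {}
                if naa:
                    table[(1, 1)] = naa
                if nab:
                    table[(1, 2)] = nab
                if nbb:
                    table[(2, 2)] = nbb
                enum = hwe_exact(table, method="enumeration")
                if not enum.testable:
                    continue
                mc = hwe_exact(table, method="monte_carlo", reps=20000, seed=5)
                se = math.sqrt(enum.p_value * (1 - enum.p_value) / 20000)
                assert abs(mc.p_value - enum.p_value) < 4 * se + 2e-3


# ----------------------------------------------------------------------
# paired tests and corrections


def test_paired_diversity_identical_and_shift():
    he = [0.2, 0.4, 0.6, 0.5, 0.3]
    t, p = paired_diversity_test(he, he)
    assert t == 0.0 and p == 1.0
    shifted = [min(h + 0.1, 1.0) for h in he]
    t2, p2 = paired_diversity_test(he, shifted)
    x = np.arcsin(np.sqrt(np.array(he)))
    y = np.arcsin(np.sqrt(np.array(shifted)))
    ref = sps.ttest_rel(x, y)
    assert t2 == pytest.approx(ref.statistic)
    assert p2 == pytest.approx(ref.pvalue)


def test_paired_diversity_domain_edges():
    t, p = paired_diversity_test([0.0, 1.0, 0.5], [0.0, 1.0, 0.5])
    assert p == 1.0


@pytest.mark.parametrize(
    "pvals,alpha,expected",
    [
        ((0.001, 0.02, 0.03, 0.5), 0.05, [True, False, False, False]),
        ((0.04,), 0.05, [True]),
        ((1.0, 1.0, 1.0), 0.05, [False, False, False]),
        ((0.01, 0.012, 0.9), 0.05, [True, True, False]),
    ],
)
def test_sequential_bonferroni(pvals, alpha, expected):
    assert list(sequential_bonferroni(pvals, alpha)) == expected


def test_hwe_locus_wrapper(tiny_dataset):
    res = hwe_exact_locus(tiny_dataset.select(population="A"), 0)
    assert 0.0 <= res.p_value <= 1.0
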