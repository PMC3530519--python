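"""Diversity and differentiation statistics for microsatellite data.

Estimators follow the variance-components (ANOVA) framework of Weir &
Cockerham for both the inbreeding coefficient (small f, here ``fis``)
and the fixation index (theta, here ``fst``); the allele-size analog
``rst`` reuses the same weighting on size variance components.
Multi-locus estimates combine as ratios of summed components.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import GenotypeDataset
from .exact import ExactResult, contingency_exact, fisher_combine, hwe_exact
from .io import allele_counts

__all__ = [
    "unbiased_he",
    "allelic_richness",
    "fis_wc",
    "fst_wc",
    "rst",
    "hwe_exact_locus",
    "ld_exact",
    "genic_diff_exact",
    "paired_diversity_test",
    "sequential_bonferroni",
    "diversity_table",
    "differentiation_matrix",
]


# ----------------------------------------------------------------------
# per-locus diversity


def unbiased_he(counts: dict | Counter) -> float:
    """Nei's unbiased expected heterozygosity from allele counts.

    He = (2n / (2n - 1)) * (1 - sum p_i^2), 2n = gene copies.
    """
    n_genes = sum(counts.values())
    if n_genes < 1:
        raise ValueError("no typed gene copies")
    if n_genes == 1:
        return 0.0
    sumsq = sum((c / n_genes) ** 2 for c in counts.values())
    return (n_genes / (n_genes - 1.0)) * (1.0 - sumsq)


def allelic_richness(counts: dict | Counter, g: int) -> float:
    """Rarefied expected allele count in a subsample of ``g`` gene copies.

    sum_i [1 - C(N - N_i, g) / C(N, g)] (El Mousadik & Petit rarefaction).
    """
    N = sum(counts.values())
    if g > N:
        raise ValueError(f"rarefaction size {g} exceeds available copies {N}")
    if g < 1:
        raise ValueError("g must be >= 1")
    denom = math.comb(N, g)
    total = 0.0
    for Ni in counts.values():
        absent = math.comb(N - Ni, g) if N - Ni >= g else 0
        total += 1.0 - absent / denom
    return total


# ----------------------------------------------------------------------
# Weir-Cockerham components


def _wc_locus_components(groups_calls: list[np.ndarray]):
    """Per-allele (a, b, c) variance components at one locus.

    ``groups_calls``: per group an (n_i, 2) array of allele sizes with
    NaN rows for missing calls.  Yields one (a, b, c) triple per allele.
    """
    cleaned = []
    for calls in groups_calls:
        ok = ~np.isnan(calls[:, 0])
        if ok.any():
            cleaned.append(calls[ok].astype(int))
    r = len(cleaned)
    if r < 1:
        return
    ns = np.array([c.shape[0] for c in cleaned], dtype=float)
    nbar = ns.mean()
    n_total = ns.sum()
    if r > 1:
        nc = (n_total - (ns**2).sum() / n_total) / (r - 1)
    else:
        nc = nbar
    alleles = sorted({int(v) for c in cleaned for v in c.ravel()})
    if len(alleles) < 2:
        return
    for al in alleles:
        p_i = np.array([(c == al).mean() for c in cleaned])  # per-group freq
        h_i = np.array([((c[:, 0] == al) ^ (c[:, 1] == al)).mean() for c in cleaned])
        pbar = (ns * p_i).sum() / n_total
        hbar = (ns * h_i).sum() / n_total
        if r > 1:
            s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
        else:
            a = 0.0
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
        c = hbar / 2.0
        yield a, b, c


def fis_wc(group: GenotypeDataset) -> float:
    """Weir-Cockerham small-f (homozygote-excess) multi-locus estimator.

    Positive values mark a heterozygote deficit (e.g. the Wahlund effect
    from pooling differentiated demes).
    """
    if group.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    num = den = 0.0
    informative = False
    for j in range(group.n_loci):
        for a, b, c in _wc_locus_components([group.calls[:, j, :]]):
            informative = True
            num += c
            den += b + c
    if not informative or den == 0:
        raise ValueError("all loci monomorphic: Fis undefined")
    return 1.0 - num / den


def fst_wc(groups: Sequence[GenotypeDataset]) -> float:
    """Weir-Cockerham theta across >= 2 groups, ratio-of-sums over
    loci and alleles.  Slightly negative estimates are reported as is."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    L = groups[0].n_loci
    num = den = 0.0
    informative = False
    for j in range(L):
        comps = list(_wc_locus_components([g.calls[:, j, :] for g in groups]))
        for a, b, c in comps:
            informative = True
            num += a
            den += a + b + c
    if not informative or den == 0:
        raise ValueError("no shared polymorphic locus between groups")
    return num / den


def rst(groups: Sequence[GenotypeDataset]) -> float:
    """Allele-size-variance analog of Fst (Slatkin's Rst, computed with
    Weir-Cockerham-style weights on one-way size-variance components)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    num = den = 0.0
    informative = False
    for j in range(groups[0].n_loci):
        sizes = []
        for g in groups:
            v = g.sizes_at_locus(j)
            if v.size:
                sizes.append(v.astype(float))
        r = len(sizes)
        if r < 2:
            continue
        ns = np.array([s.size for s in sizes], dtype=float)
        N = ns.sum()
        allv = np.concatenate(sizes)
        if np.all(allv == allv[0]):
            continue
        grand = allv.mean()
        ssb = sum(n_i * (s.mean() - grand) ** 2 for n_i, s in zip(ns, sizes))
        ssw = sum(((s - s.mean()) ** 2).sum() for s in sizes)
        msb = ssb / (r - 1)
        msw = ssw / (N - r) if N > r else 0.0
        nc = (N - (ns**2).sum() / N) / (r - 1)
        a = (msb - msw) / nc
        informative = True
        num += a
        den += a + msw
    if not informative or den == 0:
        raise ValueError("no shared polymorphic locus between groups")
    return num / den


# ----------------------------------------------------------------------
# exact tests on datasets


def _genotype_counts(group: GenotypeDataset, locus: int) -> dict:
    table: Counter = Counter()
    for a, b in group.calls[:, locus, :]:
        if not np.isnan(a):
            table[tuple(sorted((int(a), int(b))))] += 1
    return dict(table)


def hwe_exact_locus(
    group: GenotypeDataset,
    locus: int,
    method: str = "auto",
    reps: int = 100_000,
    seed: int = 0,
) -> ExactResult:
    """Exact test of Hardy-Weinberg proportions at one locus in one group."""
    return hwe_exact(_genotype_counts(group, locus), method=method, reps=reps, seed=seed)


def ld_exact(
    group: GenotypeDataset,
    locus_a: int,
    locus_b: int,
    method: str = "auto",
    reps: int = 100_000,
    seed: int = 0,
) -> ExactResult:
    """Genotypic-association exact test between two loci in one group.

    Rows are genotypes at locus A, columns genotypes at locus B; only
    individuals typed at both loci enter.
    """
    ok = ~np.isnan(group.calls[:, locus_a, 0]) & ~np.isnan(group.calls[:, locus_b, 0])
    if ok.sum() < 2:
        return ExactResult(1.0, testable=False, method="degenerate")
    ga = [tuple(sorted(map(int, row))) for row in group.calls[ok, locus_a, :]]
    gb = [tuple(sorted(map(int, row))) for row in group.calls[ok, locus_b, :]]
    ra = {g: i for i, g in enumerate(sorted(set(ga)))}
    rb = {g: i for i, g in enumerate(sorted(set(gb)))}
    table = np.zeros((len(ra), len(rb)), dtype=np.int64)
    for x, y in zip(ga, gb):
        table[ra[x], rb[y]] += 1
    return contingency_exact(table, method=method, reps=reps, seed=seed)


def genic_diff_exact(
    group1: GenotypeDataset,
    group2: GenotypeDataset,
    method: str = "auto",
    reps: int = 100_000,
    seed: int = 0,
) -> tuple[list[ExactResult], float]:
    """Per-locus genic differentiation (allele-count contingency exact
    test) plus Fisher's-method combination across testable loci."""
    results = []
    for j in range(group1.n_loci):
        c1 = Counter(group1.sizes_at_locus(j).tolist())
        c2 = Counter(group2.sizes_at_locus(j).tolist())
        alleles = sorted(set(c1) | set(c2))
        table = np.array(
            [[c1.get(a, 0) for a in alleles], [c2.get(a, 0) for a in alleles]],
            dtype=np.int64,
        )
        results.append(contingency_exact(table, method=method, reps=reps, seed=seed + j))
    combined = fisher_combine([r.p_value for r in results if r.testable])
    return results, combined


# ----------------------------------------------------------------------
# comparisons and corrections


def paired_diversity_test(
    he_group1: Sequence[float], he_group2: Sequence[float]
) -> tuple[float, float]:
    """Paired t-test of arcsine-square-root transformed per-locus He."""
    x = np.asarray(he_group1, dtype=float)
    y = np.asarray(he_group2, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 shared loci with He in both groups")
    if ((x < 0) | (x > 1) | (y < 0) | (y > 1)).any():
        raise ValueError("He values must lie in [0, 1]")
    tx, ty = np.arcsin(np.sqrt(x)), np.arcsin(np.sqrt(y))
    if np.allclose(tx, ty):
        return 0.0, 1.0
    res = sps.ttest_rel(tx, ty)
    return float(res.statistic), float(res.pvalue)


def sequential_bonferroni(pvals: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm/Rice sequential Bonferroni: sort ascending and reject while
    p_(i) < alpha / (m - i + 1); stop at the first failure."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] < alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


# ----------------------------------------------------------------------
# table-shaped reports


def diversity_table(
    dataset: GenotypeDataset,
    rarefaction_genes: int = 8,
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-population n, He, Fis, mean alleles/locus (A), and allelic
    richness (Ar) at a fixed rarefaction size in gene copies."""
    rows = []
    for pop in groups or dataset.populations():
        sub = dataset.select(population=pop)
        counts = allele_counts(sub)
        hes, ks, ars = [], [], []
        for c in counts:
            if not c:
                continue
            hes.append(unbiased_he(c))
            ks.append(len(c))
            if sum(c.values()) >= rarefaction_genes:
                ars.append(allelic_richness(c, rarefaction_genes))
        try:
            fis = fis_wc(sub)
        except ValueError:
            fis = float("nan")
        rows.append(
            {
                "group": pop,
                "n": sub.n_individuals,
                "He": float(np.mean(hes)) if hes else float("nan"),
                "Fis": fis,
                "A": float(np.mean(ks)) if ks else float("nan"),
                "Ar": float(np.mean(ars)) if ars else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def differentiation_matrix(
    dataset: GenotypeDataset,
    reps: int = 20_000,
    seed: int = 0,
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pairwise Fst (lower triangle) and Rst (upper triangle) with a
    per-pair combined genic-differentiation p-value."""
    pops = list(groups or dataset.populations())
    mat = pd.DataFrame(np.nan, index=pops, columns=pops)
    pvals = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for j, b in enumerate(pops):
            if j <= i:
                continue
            ga, gb = dataset.select(population=a), dataset.select(population=b)
            mat.loc[b, a] = fst_wc([ga, gb])
            mat.loc[a, b] = rst([ga, gb])
            _, comb = genic_diff_exact(ga, gb, reps=reps, seed=seed + 97 * i + j)
            pvals.loc[a, b] = pvals.loc[b, a] = comb
    mat.attrs["genic_p"] = pvals
    return mat
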