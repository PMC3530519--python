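"""Conditional exact tests on genotype and contingency tables.

Three tests share the machinery here: Hardy–Weinberg exact tests on
one-locus genotype counts (Levene's conditional distribution), genotypic
two-locus association ("gametic disequilibrium") tests, and genic
differentiation tests on allele x group count tables.  Small tables are
handled by complete enumeration of the conditional sample space; larger
ones by Monte Carlo sampling from the same conditional law (random
pairing of gene copies for HWE, margin permutation for contingency
tables), which is iid sampling and needs no Markov-chain burn-in.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Optional

import numpy as np
from scipy import stats as sps

_REL_TOL = 1.0 + 1e-9  # "as extreme" comparisons tolerate float roundoff


@dataclass(frozen=True)
class ExactResult:
    p_value: float
    testable: bool
    method: str
    n_tables: Optional[int] = None


# ----------------------------------------------------------------------
# Hardy-Weinberg


def _allele_counts_from_genotypes(genotype_counts: dict) -> Counter:
    m: Counter = Counter()
    for (a, b), c in genotype_counts.items():
        m[a] += c
        m[b] += c
    return m


def _levene_log_prob(genotype_counts: dict, allele_counts: Counter, n_ind: int) -> float:
    """log P(genotype table | allele counts) under Hardy-Weinberg."""
    n_het = sum(c for (a, b), c in genotype_counts.items() if a != b)
    lp = (
        math.lgamma(n_ind + 1)
        + n_het * math.log(2.0)
        + sum(math.lgamma(c + 1) for c in allele_counts.values())
        - math.lgamma(2 * n_ind + 1)
        - sum(math.lgamma(c + 1) for c in genotype_counts.values())
    )
    return lp


def _enumerate_genotype_tables(remaining: dict, cells: list, idx: int, current: dict):
    """Yield all genotype tables consistent with the allele counts.

    Plain bounded depth-first search over cells; fine at the table
    sizes we enumerate (<= a few tens of gene copies).
    """
    if idx == len(cells):
        if all(v == 0 for v in remaining.values()):
            yield dict(current)
        return
    a, b = cells[idx]
    hi = remaining[a] // 2 if a == b else min(remaining[a], remaining[b])
    for c in range(hi + 1):
        if a == b:
            remaining[a] -= 2 * c
        else:
            remaining[a] -= c
            remaining[b] -= c
        if c:
            current[(a, b)] = c
        yield from _enumerate_genotype_tables(remaining, cells, idx + 1, current)
        current.pop((a, b), None)
        if a == b:
            remaining[a] += 2 * c
        else:
            remaining[a] += c
            remaining[b] += c


def hwe_exact(
    genotype_counts: dict,
    method: str = "auto",
    reps: int = 100_000,
    seed: int = 0,
) -> ExactResult:
    """Exact conditional test of Hardy-Weinberg proportions at one locus.

    ``genotype_counts`` maps sorted allele pairs (a, b) to counts.  The
    p-value is the total conditional probability (Levene) of tables at
    most as probable as the observed one, given the allele counts.
    """
    genotype_counts = {tuple(sorted(k)): v for k, v in genotype_counts.items() if v > 0}
    n_ind = sum(genotype_counts.values())
    allele_counts = _allele_counts_from_genotypes(genotype_counts)
    alleles = sorted(allele_counts)
    if len(alleles) < 2 or n_ind < 2:
        return ExactResult(1.0, testable=False, method="degenerate")
    n_genes = 2 * n_ind
    obs_lp = _levene_log_prob(genotype_counts, allele_counts, n_ind)

    if method == "auto":
        method = "enumeration" if n_genes <= 20 or len(alleles) <= 3 and n_genes <= 60 else "monte_carlo"

    if method == "enumeration":
        cells = list(combinations_with_replacement(alleles, 2))
        total = 0.0
        extreme = 0.0
        n_tables = 0
        for table in _enumerate_genotype_tables(dict(allele_counts), cells, 0, {}):
            lp = _levene_log_prob(table, allele_counts, n_ind)
            p = math.exp(lp)
            total += p
            n_tables += 1
            if math.exp(lp) <= math.exp(obs_lp) * _REL_TOL:
                extreme += p
        # total should be 1 up to roundoff; normalize defensively
        return ExactResult(
            min(extreme / total, 1.0), testable=True, method="enumeration", n_tables=n_tables
        )

    # Monte Carlo: random pairing of the gene copies samples Levene's law
    rng = np.random.default_rng(seed)
    pool = np.repeat(
        np.arange(len(alleles)), [allele_counts[a] for a in alleles]
    )
    obs_p = math.exp(obs_lp)
    hits = 0
    for _ in range(reps):
        rng.shuffle(pool)
        pairs = pool.reshape(-1, 2)
        table: Counter = Counter()
        for a, b in pairs:
            key = (alleles[min(a, b)], alleles[max(a, b)])
            table[key] += 1
        lp = _levene_log_prob(table, allele_counts, n_ind)
        if math.exp(lp) <= obs_p * _REL_TOL:
            hits += 1
    return ExactResult((hits + 1) / (reps + 1), testable=True, method="monte_carlo")


# ----------------------------------------------------------------------
# contingency tables (genic differentiation, genotypic LD)


def _contingency_log_prob(table: np.ndarray) -> float:
    """log conditional probability of a table given both margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lp = (
        sum(math.lgamma(r + 1) for r in rows)
        + sum(math.lgamma(c + 1) for c in cols)
        - math.lgamma(n + 1)
        - sum(math.lgamma(v + 1) for v in table.ravel())
    )
    return lp


def _enumerate_contingency(rows: np.ndarray, cols: np.ndarray):
    """Yield all non-negative integer tables with the given margins."""
    R, C = len(rows), len(cols)
    table = np.zeros((R, C), dtype=np.int64)

    def rec(i: int, col_left: np.ndarray):
        if i == R - 1:
            table[i] = col_left
            yield table
            return
        # fill row i cell by cell
        def fill(j: int, row_left: int, col_left: np.ndarray):
            if j == C - 1:
                if row_left <= col_left[j]:
                    table[i, j] = row_left
                    new_left = col_left.copy()
                    new_left[j] -= row_left
                    yield from rec(i + 1, new_left)
                return
            for v in range(min(row_left, col_left[j]) + 1):
                table[i, j] = v
                new_left = col_left.copy()
                new_left[j] -= v
                yield from fill(j + 1, row_left - v, new_left)

        yield from fill(0, rows[i], col_left)

    yield from rec(0, cols.copy())


def contingency_exact(
    table: np.ndarray,
    method: str = "auto",
    reps: int = 100_000,
    seed: int = 0,
) -> ExactResult:
    """Fisher-type exact probability test on an R x C count table.

    The p-value is the conditional probability, given both margins, of
    tables whose conditional probability does not exceed the observed
    one (the multi-allele generalization of Fisher's exact test).
    """
    table = np.asarray(table, dtype=np.int64)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return ExactResult(1.0, testable=False, method="degenerate")
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    n = int(table.sum())
    obs_lp = _contingency_log_prob(table)

    if method == "auto":
        method = "enumeration" if n <= 12 else "monte_carlo"

    if method == "enumeration":
        total = 0.0
        extreme = 0.0
        n_tables = 0
        for t in _enumerate_contingency(rows, cols):
            lp = _contingency_log_prob(t)
            p = math.exp(lp)
            total += p
            n_tables += 1
            if math.exp(lp) <= math.exp(obs_lp) * _REL_TOL:
                extreme += p
        return ExactResult(
            min(extreme / total, 1.0), testable=True, method="enumeration", n_tables=n_tables
        )

    # Monte Carlo: permute column labels of the expanded observations
    rng = np.random.default_rng(seed)
    row_of = np.repeat(np.arange(len(rows)), rows)
    col_of = np.repeat(np.arange(len(cols)), cols)
    obs_p = math.exp(obs_lp)
    hits = 0
    R, C = len(rows), len(cols)
    for _ in range(reps):
        rng.shuffle(col_of)
        t = np.zeros((R, C), dtype=np.int64)
        np.add.at(t, (row_of, col_of), 1)
        if math.exp(_contingency_log_prob(t)) <= obs_p * _REL_TOL:
            hits += 1
    return ExactResult((hits + 1) / (reps + 1), testable=True, method="monte_carlo")


def fisher_combine(pvals: list[float]) -> float:
    """Fisher's method across independent tests (untestable ones excluded)."""
    ps = [min(max(p, 1e-300), 1.0) for p in pvals]
    if not ps:
        return float("nan")
    x = -2.0 * sum(math.log(p) for p in ps)
    return float(sps.chi2.sf(x, 2 * len(ps)))
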