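"""Numba hot loops for equilibrium coalescent simulation.

These kernels serve the simulated null distributions (M-critical
cutoffs, heterozygosity-excess equilibrium references), where millions
of constant-size Kingman trees with stepwise/two-phase mutations are
needed.  Time is measured in units of 2N generations, so the per-branch
mutation intensity is theta/2 per unit time (theta = 4*N*mu).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from math import lgamma as math_lgamma


@njit(cache=True)
def _seed(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _equilibrium_locus(n, theta, p_single, p_geom, shift, sizes_out):
    """One constant-N Kingman tree with TPM mutations; fills sizes_out.

    Builds coalescence times, then walks root-ward accumulating signed
    mutation displacements per lineage (root state 0).
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes, dtype=np.float64)
    active = np.empty(n, dtype=np.int64)
    for i in range(n):
        active[i] = i
    k = n
    t = 0.0
    nxt = n
    while k > 1:
        rate = k * (k - 1) / 2.0
        t += np.random.exponential(1.0 / rate)
        i = np.random.randint(k)
        a = active[i]
        active[i] = active[k - 1]
        k -= 1
        j = np.random.randint(k)
        b = active[j]
        parent[a] = nxt
        parent[b] = nxt
        time[nxt] = t
        active[j] = nxt
        nxt += 1
    # mutations: parents carry higher indices, so walk indices downward
    state = np.zeros(n_nodes, dtype=np.int64)
    for node in range(n_nodes - 2, -1, -1):
        branch = time[parent[node]] - time[node]
        lam = 0.5 * theta * branch
        nm = np.random.poisson(lam)
        disp = 0
        for _ in range(nm):
            if np.random.random() < p_single:
                step = 1
            else:
                step = shift + np.random.geometric(p_geom)
            if np.random.random() < 0.5:
                step = -step
            disp += step
        state[node] = state[parent[node]] + disp
    for i in range(n):
        sizes_out[i] = state[i]


@njit(cache=True)
def _k_and_range_and_sumsq(sizes):
    """Return (k distinct alleles, size range max-min, sum of squared
    allele frequencies)."""
    srt = np.sort(sizes)
    n = srt.shape[0]
    k = 1
    run = 1
    sumsq = 0.0
    for i in range(1, n):
        if srt[i] == srt[i - 1]:
            run += 1
        else:
            sumsq += (run / n) ** 2
            k += 1
            run = 1
    sumsq += (run / n) ** 2
    rng = srt[n - 1] - srt[0]
    return k, rng, sumsq


@njit(cache=True)
def m_critical_null(n_genes, n_loci, reps, theta, p_single, p_geom, shift, seed):
    """Replicate equilibrium multi-locus mean M-ratios.

    Per replicate, n_loci independent loci are simulated at the given
    theta; M = k / (range + 1) averaged over polymorphic loci.  A
    replicate with no polymorphic locus reports M = 1 (no evidence of
    allele loss).
    """
    np.random.seed(seed)
    out = np.empty(reps, dtype=np.float64)
    sizes = np.empty(n_genes, dtype=np.int64)
    for r in range(reps):
        msum = 0.0
        npoly = 0
        for _ in range(n_loci):
            _equilibrium_locus(n_genes, theta, p_single, p_geom, shift, sizes)
            k, rng, _ = _k_and_range_and_sumsq(sizes)
            if k > 1:
                msum += k / (rng + 1.0)
                npoly += 1
        out[r] = msum / npoly if npoly > 0 else 1.0
    return out


@njit(cache=True)
def he_conditional_on_k(n_genes, k_obs, theta_start, p_single, p_geom, shift, reps, seed):
    """Equilibrium unbiased-He replicates conditional on allele count.

    Two-phase rejection sampler.  First a stochastic-approximation
    phase (no collection) walks the working theta toward values whose
    equilibrium allele count matches ``k_obs``; theta is then frozen
    and only exact-k replicates are kept.  Freezing matters: collecting
    while theta still adapts mixes conditioning levels and biases the
    null mean slightly low (inflating the one-tailed excess test).
    Returns (he_samples, n_attempts).
    """
    np.random.seed(seed)
    he = np.empty(reps, dtype=np.float64)
    sizes = np.empty(n_genes, dtype=np.int64)
    log_theta = np.log(theta_start)
    for _ in range(300):
        _equilibrium_locus(n_genes, np.exp(log_theta), p_single, p_geom, shift, sizes)
        k, _, _ = _k_and_range_and_sumsq(sizes)
        log_theta += 0.1 * (k_obs - k) / max(k_obs, 1)
        if log_theta > 6.0:
            log_theta = 6.0
        elif log_theta < -6.0:
            log_theta = -6.0
    theta = np.exp(log_theta)
    got = 0
    attempts = 0
    max_attempts = reps * 300
    while got < reps and attempts < max_attempts:
        attempts += 1
        _equilibrium_locus(n_genes, theta, p_single, p_geom, shift, sizes)
        k, _, sumsq = _k_and_range_and_sumsq(sizes)
        if k == k_obs:
            he[got] = (n_genes / (n_genes - 1.0)) * (1.0 - sumsq)
            got += 1
    return he[:got], attempts


@njit(cache=True)
def equilibrium_batch(n_genes, n_loci, theta, p_single, p_geom, shift, seed):
    """Simulate one dataset's worth of equilibrium gene copies.

    Returns an (n_loci, n_genes) array of allele sizes.
    """
    np.random.seed(seed)
    out = np.empty((n_loci, n_genes), dtype=np.int64)
    sizes = np.empty(n_genes, dtype=np.int64)
    for j in range(n_loci):
        _equilibrium_locus(n_genes, theta, p_single, p_geom, shift, sizes)
        out[j] = sizes
    return out


# ----------------------------------------------------------------------
# size-change model likelihood (latent-genealogy MCMC)


@njit(cache=True)
def _intensity(t, N0, N1, T, shape_code):
    """integral_0^t du/N(u); shape_code 0=constant, 1=exponential, 2=linear."""
    if shape_code == 0 or N0 == N1 or T == 0.0:
        return t / N0
    head = t if t < T else T
    if shape_code == 1:
        beta = np.log(N1 / N0) / T
        lam = (1.0 - np.exp(-beta * head)) / (N0 * beta)
    else:
        c = (N1 - N0) / T
        lam = np.log1p(c * head / N0) / c
    if t > T:
        lam += (t - T) / N1
    return lam


@njit(cache=True)
def _size_at(t, N0, N1, T, shape_code):
    if shape_code == 0 or N0 == N1 or T == 0.0:
        return N0
    if t >= T:
        return N1
    frac = t / T
    if shape_code == 1:
        return N0 * (N1 / N0) ** frac
    return N0 + (N1 - N0) * frac


@njit(cache=True)
def log_bessel_i(v, m):
    """log I_v(m) for integer order v >= 0, m >= 0.

    Series evaluated with the multiplicative term recurrence
    t_j / t_{j-1} = (m/2)^2 / (j (j+v)), accumulated relative to the
    first term with periodic rescaling, so no per-term lgamma calls.
    """
    if m == 0.0:
        return 0.0 if v == 0 else -np.inf
    half = 0.5 * m
    hh = half * half
    t0_log = v * np.log(half) - math_lgamma(v + 1.0)
    rel = 1.0
    acc = 1.0
    extra = 0.0
    j = 0
    while True:
        j += 1
        rel *= hh / (j * (j + v))
        acc += rel
        if rel < 1e-16 * acc and j > half:
            break
        if acc > 1e270:
            acc *= 1e-270
            rel *= 1e-270
            extra += 621.6979751083924  # log(1e270)
        if j > 1_000_000:
            break
    return t0_log + np.log(acc) + extra


@njit(cache=True)
def log_skellam(d, m):
    """log P(net displacement d | Poisson(m) symmetric unit steps)."""
    if m < 0.0:
        return -np.inf
    dd = d if d >= 0 else -d
    if m == 0.0:
        return 0.0 if dd == 0 else -np.inf
    return -m + log_bessel_i(dd, m)


@njit(cache=True)
def genealogy_loglik(parent, node_time, state, n_leaves, N0, N1, T, shape_code, mu):
    """Coalescent density of node times under the size trajectory plus
    stepwise-mutation transition terms over all branches.

    Pairwise coalescence rate is 1/(2N(t)); branch mutation counts are
    Poisson(mu * branch length in generations).
    """
    n_nodes = parent.shape[0]
    # --- coalescent part
    internal = np.sort(node_time[n_leaves:])
    ll = 0.0
    k = n_leaves
    prev = 0.0
    for i in range(internal.shape[0]):
        t = internal[i]
        if t < prev:
            return -np.inf
        ll -= (
            0.5
            * k
            * (k - 1)
            / 2.0
            * (_intensity(t, N0, N1, T, shape_code) - _intensity(prev, N0, N1, T, shape_code))
        )
        ll -= np.log(2.0 * _size_at(t, N0, N1, T, shape_code))
        k -= 1
        prev = t
    # --- mutation part
    for node in range(n_nodes - 1):
        p = parent[node]
        if p < 0:
            continue
        branch = node_time[p] - node_time[node]
        if branch < 0.0:
            return -np.inf
        ll += log_skellam(state[node] - state[p], mu * branch)
    return ll



@njit(cache=True)
def _log_prior_arrays(lp, ltheta, alpha, sigma, am, asd, sm, ssd):
    """Hierarchical log-prior; blocks 0..3 = N0, N1, T, theta."""
    tot = 0.0
    for b in range(4):
        s = sigma[b]
        if s <= 0.0:
            return -np.inf
        if asd[b] > 0.0:
            tot += -0.5 * ((alpha[b] - am[b]) / asd[b]) ** 2 - np.log(asd[b])
        if ssd[b] > 0.0:
            tot += -0.5 * ((s - sm[b]) / ssd[b]) ** 2 - np.log(ssd[b])
    for b in range(3):
        tot += -0.5 * ((lp[b] - alpha[b]) / sigma[b]) ** 2 - np.log(sigma[b])
    for i in range(ltheta.shape[0]):
        tot += -0.5 * ((ltheta[i] - alpha[3]) / sigma[3]) ** 2 - np.log(sigma[3])
    return tot


@njit(cache=True)
def _locus_ll(parent, time, astate, nl, nn, lp, ltheta_i, shape_code):
    N0 = 10.0 ** lp[0]
    N1 = 10.0 ** lp[1]
    T = 10.0 ** lp[2]
    mu = 10.0 ** ltheta_i / (2.0 * N0)
    return genealogy_loglik(
        parent[:nn], time[:nn], astate[:nn], nl, N0, N1, T, shape_code, mu
    )


@njit(cache=True)
def mcmc_kernel(
    parent,
    time,
    astate,
    child1,
    child2,
    n_leaves,
    n_loci,
    lp,
    ltheta,
    alpha,
    sigma,
    am,
    asd,
    sm,
    ssd,
    shape_code,
    iterations,
    thinning,
    seed,
    scales,
    rec,
    acc,
):
    """Metropolis-Hastings sweep over genealogies and parameters.

    Mutates all state arrays in place; fills ``rec`` (records x 4:
    log10 N0, N1, T, mean log10 theta) and ``acc`` (accept/total pairs
    for param, hyper, time, topo, state moves).  ``scales`` holds
    proposal SDs: [N0, N1, T, theta, alpha, sigma].
    Returns the number of records written.
    """
    np.random.seed(seed)
    L = n_loci
    n_theta = ltheta.shape[0]
    lp_prior = _log_prior_arrays(lp, ltheta, alpha, sigma, am, asd, sm, ssd)
    lliks = np.zeros(L)
    for j in range(L):
        nl = n_leaves[j]
        nn = 2 * nl - 1
        lliks[j] = _locus_ll(parent[j], time[j], astate[j], nl, nn, lp, ltheta[j], shape_code)
    ri = 0
    for it in range(iterations):
        for j in range(L):
            nl = n_leaves[j]
            nn = 2 * nl - 1
            # ---- node-time move
            node = nl + np.random.randint(nn - nl)
            lo = time[j, child1[j, node]]
            t2 = time[j, child2[j, node]]
            if t2 > lo:
                lo = t2
            t_old = time[j, node]
            log_h = 0.0
            if parent[j, node] < 0:
                u = 0.5 * (np.random.random() * 2.0 - 1.0)
                t_new = lo + (t_old - lo) * np.exp(u)
                log_h = u
            else:
                hi = time[j, parent[j, node]]
                if hi <= lo:
                    t_new = t_old
                else:
                    t_new = lo + np.random.random() * (hi - lo)
            time[j, node] = t_new
            ll_new = _locus_ll(parent[j], time[j], astate[j], nl, nn, lp, ltheta[j], shape_code)
            acc[2, 1] += 1
            if np.log(np.random.random() + 1e-300) < ll_new - lliks[j] + log_h:
                lliks[j] = ll_new
                acc[2, 0] += 1
            else:
                time[j, node] = t_old
            # ---- narrow exchange
            p = nl + np.random.randint(nn - nl)
            gp = parent[j, p]
            if gp >= 0:
                s = child1[j, gp]
                if s == p:
                    s = child2[j, gp]
                if time[j, s] < time[j, p]:
                    if np.random.random() < 0.5:
                        c = child1[j, p]
                    else:
                        c = child2[j, p]
                    # swap c <-> s
                    parent[j, c] = gp
                    parent[j, s] = p
                    if child1[j, gp] == s:
                        child1[j, gp] = c
                    else:
                        child2[j, gp] = c
                    if child1[j, p] == c:
                        child1[j, p] = s
                    else:
                        child2[j, p] = s
                    ll_new = _locus_ll(parent[j], time[j], astate[j], nl, nn, lp, ltheta[j], shape_code)
                    acc[3, 1] += 1
                    if np.log(np.random.random() + 1e-300) < ll_new - lliks[j]:
                        lliks[j] = ll_new
                        acc[3, 0] += 1
                    else:
                        parent[j, c] = p
                        parent[j, s] = gp
                        if child1[j, gp] == c:
                            child1[j, gp] = s
                        else:
                            child2[j, gp] = s
                        if child1[j, p] == s:
                            child1[j, p] = c
                        else:
                            child2[j, p] = c
            # ---- internal state move
            node = nl + np.random.randint(nn - nl)
            delta = 1 + np.random.randint(2)
            if np.random.random() < 0.5:
                delta = -delta
            astate[j, node] += delta
            ll_new = _locus_ll(parent[j], time[j], astate[j], nl, nn, lp, ltheta[j], shape_code)
            acc[4, 1] += 1
            if np.log(np.random.random() + 1e-300) < ll_new - lliks[j]:
                lliks[j] = ll_new
                acc[4, 0] += 1
            else:
                astate[j, node] -= delta

        # ---- demographic parameter moves (N0, N1, T)
        for b in range(3):
            old = lp[b]
            lp[b] = old + scales[b] * np.random.standard_normal()
            new_lp = _log_prior_arrays(lp, ltheta, alpha, sigma, am, asd, sm, ssd)
            delta_ll = new_lp - lp_prior
            ll_all = np.zeros(L)
            for j in range(L):
                nl = n_leaves[j]
                nn = 2 * nl - 1
                ll_all[j] = _locus_ll(parent[j], time[j], astate[j], nl, nn, lp, ltheta[j], shape_code)
                delta_ll += ll_all[j] - lliks[j]
            acc[0, 1] += 1
            if np.log(np.random.random() + 1e-300) < delta_ll:
                lp_prior = new_lp
                for j in range(L):
                    lliks[j] = ll_all[j]
                acc[0, 0] += 1
            else:
                lp[b] = old
        # ---- per-locus theta moves
        for i in range(n_theta):
            old = ltheta[i]
            ltheta[i] = old + scales[3] * np.random.standard_normal()
            new_lp = _log_prior_arrays(lp, ltheta, alpha, sigma, am, asd, sm, ssd)
            delta_ll = new_lp - lp_prior
            ll_new = 0.0
            if i < L:
                nl = n_leaves[i]
                nn = 2 * nl - 1
                ll_new = _locus_ll(parent[i], time[i], astate[i], nl, nn, lp, ltheta[i], shape_code)
                delta_ll += ll_new - lliks[i]
            acc[0, 1] += 1
            if np.log(np.random.random() + 1e-300) < delta_ll:
                lp_prior = new_lp
                if i < L:
                    lliks[i] = ll_new
                acc[0, 0] += 1
            else:
                ltheta[i] = old
        # ---- hyperparameter moves (prior terms only)
        for b in range(4):
            if asd[b] > 0.0:
                old = alpha[b]
                alpha[b] = old + scales[4] * np.random.standard_normal()
                new_lp = _log_prior_arrays(lp, ltheta, alpha, sigma, am, asd, sm, ssd)
                acc[1, 1] += 1
                if np.log(np.random.random() + 1e-300) < new_lp - lp_prior:
                    lp_prior = new_lp
                    acc[1, 0] += 1
                else:
                    alpha[b] = old
            if ssd[b] > 0.0:
                old = sigma[b]
                prop = old + scales[5] * np.random.standard_normal()
                if prop < 0.0:
                    prop = -prop
                sigma[b] = prop
                new_lp = _log_prior_arrays(lp, ltheta, alpha, sigma, am, asd, sm, ssd)
                acc[1, 1] += 1
                if np.log(np.random.random() + 1e-300) < new_lp - lp_prior:
                    lp_prior = new_lp
                    acc[1, 0] += 1
                else:
                    sigma[b] = old

        if (it + 1) % thinning == 0:
            rec[ri, 0] = lp[0]
            rec[ri, 1] = lp[1]
            rec[ri, 2] = lp[2]
            tsum = 0.0
            for i in range(n_theta):
                tsum += ltheta[i]
            rec[ri, 3] = tsum / n_theta
            ri += 1
    return ri
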