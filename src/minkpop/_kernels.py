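"""Low-level simulation kernels.

Hot loops of the backward-time coalescent (tree building, mutation dropping,
fixed-S null replicates) and of the ABC summary-statistic computation.  All
kernels are compiled with numba when available and fall back to plain Python
otherwise; each entry point takes an explicit integer seed so that results are
reproducible call-by-call.

Demographic events are encoded as parallel arrays sorted by time:
``ev_type`` 0 = split (move every lineage of pop ``a`` into pop ``b``),
1 = admixture (each lineage of ``a`` independently joins ``b`` with
probability ``x``, else ``c``), 2 = size change (pop ``a`` gets coalescent
size ``x``).  Population sizes are passed already scaled to "coalescent
units": 2N allele copies for autosomal diploid loci, N/2 for mtDNA.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _simulate_tree(lin_pop, sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_x,
                   parent, ntime):
    """Coalesce ``n`` lineages under the event schedule; fill parent/ntime.

    Node ids: tips ``0..n-1`` (time 0), internal nodes in coalescence order,
    root ``2n-2``.  A parent id is always larger than its children's.
    """
    n = lin_pop.shape[0]
    npops = sizes.shape[0]
    members = np.empty((npops, n), np.int64)
    k = np.zeros(npops, np.int64)
    for i in range(n):
        p = lin_pop[i]
        members[p, k[p]] = i
        k[p] += 1
    sz = sizes.copy()
    t = 0.0
    ei = 0
    nev = ev_time.shape[0]
    nxt = n
    nact = n
    while nact > 1:
        rate = 0.0
        for p in range(npops):
            if k[p] > 1:
                rate += k[p] * (k[p] - 1) * 0.5 / sz[p]
        if rate > 0.0:
            dt = np.random.exponential(1.0 / rate)
        else:
            dt = 1e300
        if ei < nev and t + dt >= ev_time[ei]:
            t = ev_time[ei]
            typ = ev_type[ei]
            a = ev_a[ei]
            if typ == 0:  # split: a -> b
                b = ev_b[ei]
                for j in range(k[a]):
                    members[b, k[b]] = members[a, j]
                    k[b] += 1
                k[a] = 0
            elif typ == 1:  # admixture: a -> b w.p. x else c
                b = ev_b[ei]
                c = ev_c[ei]
                x = ev_x[ei]
                for j in range(k[a]):
                    node = members[a, j]
                    if np.random.random() < x:
                        members[b, k[b]] = node
                        k[b] += 1
                    else:
                        members[c, k[c]] = node
                        k[c] += 1
                k[a] = 0
            else:  # size change
                sz[a] = ev_x[ei]
            ei += 1
            continue
        if rate == 0.0:
            # no event left and no coalescence possible: malformed schedule;
            # guaranteed not to happen for validated scenarios
            break
        t += dt
        u = np.random.random() * rate
        acc = 0.0
        chosen = -1
        for p in range(npops):
            if k[p] > 1:
                acc += k[p] * (k[p] - 1) * 0.5 / sz[p]
                if u <= acc:
                    chosen = p
                    break
        if chosen == -1:
            for p in range(npops - 1, -1, -1):
                if k[p] > 1:
                    chosen = p
                    break
        i1 = np.random.randint(0, k[chosen])
        i2 = np.random.randint(0, k[chosen] - 1)
        if i2 >= i1:
            i2 += 1
        c1 = members[chosen, i1]
        c2 = members[chosen, i2]
        parent[c1] = nxt
        parent[c2] = nxt
        ntime[nxt] = t
        members[chosen, i1] = nxt
        members[chosen, i2] = members[chosen, k[chosen] - 1]
        k[chosen] -= 1
        nxt += 1
        nact -= 1
    return nxt


@njit(cache=True)
def _drop_msat(parent, ntime, n, mu, p_gsm, ancestral, amin, amax):
    """Generalized-stepwise mutation walk down the tree -> tip repeat counts."""
    nn = 2 * n - 1
    allele = np.empty(nn, np.int64)
    allele[nn - 1] = ancestral
    for i in range(nn - 2, -1, -1):
        pa = parent[i]
        a = allele[pa]
        bl = ntime[pa] - ntime[i]
        m = np.random.poisson(mu * bl)
        for _ in range(m):
            step = np.random.geometric(1.0 - p_gsm) if p_gsm > 0.0 else 1
            if np.random.random() < 0.5:
                step = -step
            a += step
            if a < amin:  # reflecting boundaries keep the range biological
                a = 2 * amin - a
            if a > amax:
                a = 2 * amax - a
            if a < amin:
                a = amin
            if a > amax:
                a = amax
        allele[i] = a
    return allele[:n]


@njit(cache=True)
def sim_msat_dataset(seed, lin_pop, sizes, ev_time, ev_type, ev_a, ev_b, ev_c,
                     ev_x, n_loci, mu, p_gsm, ancestral, amin, amax):
    """Simulate ``n_loci`` unlinked microsatellite loci for one parameter draw.

    ``lin_pop`` holds the population of each allele copy (2 per individual);
    returns an (n_copies, n_loci) array of repeat counts.
    """
    np.random.seed(seed)
    n = lin_pop.shape[0]
    out = np.empty((n, n_loci), np.int64)
    for l in range(n_loci):
        parent = np.full(2 * n - 1, -1, np.int64)
        ntime = np.zeros(2 * n - 1, np.float64)
        _simulate_tree(lin_pop, sizes, ev_time, ev_type, ev_a, ev_b, ev_c,
                       ev_x, parent, ntime)
        out[:, l] = _drop_msat(parent, ntime, n, mu, p_gsm, ancestral, amin, amax)
    return out


@njit(cache=True)
def sim_mtdna(seed, lin_pop, sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_x,
              mu_site, L):
    """Simulate one mtDNA genealogy with infinite-sites mutations.

    Returns ``(states, sites)``: ``states`` is an (n, M) 0/1 derived-state
    matrix and ``sites`` the distinct site index of each mutation.  M is
    capped at L (the infinite-sites assumption bounds S by the sequence
    length; overflow is effectively impossible at realistic rates).
    """
    np.random.seed(seed)
    n = lin_pop.shape[0]
    nn = 2 * n - 1
    parent = np.full(nn, -1, np.int64)
    ntime = np.zeros(nn, np.float64)
    _simulate_tree(lin_pop, sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_x,
                   parent, ntime)
    mcount = np.zeros(nn - 1, np.int64)
    total = 0
    for i in range(nn - 1):
        m = np.random.poisson(mu_site * L * (ntime[parent[i]] - ntime[i]))
        if total + m > L:
            m = L - total
        mcount[i] = m
        total += m
    offset = np.zeros(nn - 1, np.int64)
    acc = 0
    for i in range(nn - 1):
        offset[i] = acc
        acc += mcount[i]
    # choose `total` distinct sites by partial Fisher-Yates
    perm = np.arange(L)
    for j in range(total):
        kk = j + np.random.randint(0, L - j)
        tmp = perm[j]
        perm[j] = perm[kk]
        perm[kk] = tmp
    states = np.zeros((nn, total), np.int8)
    for i in range(nn - 2, -1, -1):
        pa = parent[i]
        for col in range(total):
            states[i, col] = states[pa, col]
        for col in range(offset[i], offset[i] + mcount[i]):
            states[i, col] = 1 - states[i, col]
    return states[:n], perm[:total]


@njit(cache=True)
def sim_fixed_s(seed, n, S):
    """Constant-size coalescent of ``n`` tips with exactly ``S`` mutations.

    Mutations are placed uniformly on branch length; returns the (n, S)
    derived-state matrix.  This is the null machinery behind the simulated
    significance of the neutrality tests.
    """
    np.random.seed(seed)
    nn = 2 * n - 1
    parent = np.full(nn, -1, np.int64)
    ntime = np.zeros(nn, np.float64)
    lin_pop = np.zeros(n, np.int64)
    sizes = np.ones(1, np.float64)
    ev = np.zeros(0, np.float64)
    evi = np.zeros(0, np.int64)
    _simulate_tree(lin_pop, sizes, ev, evi, evi, evi, evi, ev, parent, ntime)
    blen = np.empty(nn - 1, np.float64)
    tot = 0.0
    for i in range(nn - 1):
        blen[i] = ntime[parent[i]] - ntime[i]
        tot += blen[i]
    mcount = np.zeros(nn - 1, np.int64)
    for _ in range(S):
        u = np.random.random() * tot
        acc = 0.0
        b = nn - 2
        for i in range(nn - 1):
            acc += blen[i]
            if u <= acc:
                b = i
                break
        mcount[b] += 1
    offset = np.zeros(nn - 1, np.int64)
    acc2 = 0
    for i in range(nn - 1):
        offset[i] = acc2
        acc2 += mcount[i]
    states = np.zeros((nn, S), np.int8)
    for i in range(nn - 2, -1, -1):
        pa = parent[i]
        for col in range(S):
            states[i, col] = states[pa, col]
        for col in range(offset[i], offset[i] + mcount[i]):
            states[i, col] = 1 - states[i, col]
    return states[:n]


# -- ABC summary statistics --------------------------------------------------

@njit(cache=True)
def summarize_msat_kernel(alleles, ind_pop, npops, amin, amax):
    """DIYABC-style summary-statistic vector from raw repeat counts.

    ``alleles``: (n_ind, n_loci, 2) with -1 for missing; ``ind_pop``: pop code
    per individual.  Layout (K = npops, P = K*(K-1)/2 ordered pairs):
      [ mean alleles/locus per pop | mean He per pop | mean size variance per
        pop | pairwise Weir-Cockerham theta | pairwise (delta mu)^2 |
        pairwise allele-sharing distance ]
    """
    n_ind, n_loci, _ = alleles.shape
    nall = amax - amin + 1
    counts = np.zeros((npops, n_loci, nall), np.float64)
    hets = np.zeros((npops, n_loci, nall), np.float64)  # het indiv carrying allele
    nind_pl = np.zeros((npops, n_loci), np.float64)
    for i in range(n_ind):
        p = ind_pop[i]
        for l in range(n_loci):
            a = alleles[i, l, 0]
            b = alleles[i, l, 1]
            if a < 0:
                continue
            counts[p, l, a - amin] += 1.0
            counts[p, l, b - amin] += 1.0
            nind_pl[p, l] += 1.0
            if a != b:
                hets[p, l, a - amin] += 1.0
                hets[p, l, b - amin] += 1.0

    K = npops
    P = K * (K - 1) // 2
    out = np.zeros(3 * K + 3 * P, np.float64)

    # per-population statistics
    for p in range(K):
        mean_na = 0.0
        mean_he = 0.0
        mean_var = 0.0
        for l in range(n_loci):
            ncop = 2.0 * nind_pl[p, l]
            if ncop < 2.0:
                continue
            na = 0
            sump2 = 0.0
            msize = 0.0
            for u in range(nall):
                c = counts[p, l, u]
                if c > 0.0:
                    na += 1
                    f = c / ncop
                    sump2 += f * f
                    msize += f * (u + amin)
            vsize = 0.0
            for u in range(nall):
                c = counts[p, l, u]
                if c > 0.0:
                    d = (u + amin) - msize
                    vsize += (c / ncop) * d * d
            mean_na += na
            mean_he += (ncop / (ncop - 1.0)) * (1.0 - sump2)
            mean_var += vsize
        out[p] = mean_na / n_loci
        out[K + p] = mean_he / n_loci
        out[2 * K + p] = mean_var / n_loci

    # pairwise statistics
    pair = 0
    for p1 in range(K):
        for p2 in range(p1 + 1, K):
            suma = 0.0
            sumabc = 0.0
            dmu2 = 0.0
            das = 0.0
            nloc_eff = 0
            for l in range(n_loci):
                n1 = nind_pl[p1, l]
                n2 = nind_pl[p2, l]
                if n1 < 1.0 or n2 < 1.0:
                    continue
                nloc_eff += 1
                nbar = 0.5 * (n1 + n2)
                nc = (2.0 * nbar - (n1 * n1 + n2 * n2) / (2.0 * nbar))
                m1 = 0.0
                m2 = 0.0
                shared = 0.0
                for u in range(nall):
                    c1 = counts[p1, l, u]
                    c2 = counts[p2, l, u]
                    f1 = c1 / (2.0 * n1)
                    f2 = c2 / (2.0 * n2)
                    m1 += f1 * (u + amin)
                    m2 += f2 * (u + amin)
                    if f1 < f2:
                        shared += f1
                    else:
                        shared += f2
                    if c1 + c2 <= 0.0:
                        continue
                    h1 = hets[p1, l, u] / n1
                    h2 = hets[p2, l, u] / n2
                    pbar = (n1 * f1 + n2 * f2) / (2.0 * nbar)
                    s2 = (n1 * (f1 - pbar) ** 2 + n2 * (f2 - pbar) ** 2) / nbar
                    hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
                    if nbar > 1.0 and nc > 0.0:
                        a = (nbar / nc) * (
                            s2
                            - (pbar * (1.0 - pbar) - 0.5 * s2 - 0.25 * hbar)
                            / (nbar - 1.0)
                        )
                        b = (nbar / (nbar - 1.0)) * (
                            pbar * (1.0 - pbar)
                            - 0.5 * s2
                            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
                        )
                        c = 0.5 * hbar
                        suma += a
                        sumabc += a + b + c
                dmu2 += (m1 - m2) ** 2
                das += 1.0 - shared
            out[3 * K + pair] = suma / sumabc if sumabc != 0.0 else 0.0
            out[3 * K + P + pair] = dmu2 / max(nloc_eff, 1)
            out[3 * K + 2 * P + pair] = das / max(nloc_eff, 1)
            pair += 1
    return out
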