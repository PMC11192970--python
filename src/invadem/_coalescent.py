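"""Low-level structured-coalescent machinery (numba kernels).

Simulates per-locus genealogies of gene copies distributed over demes with
piecewise-constant diploid sizes and a backward-time event schedule
(splits, admixture pulses, instantaneous size changes), then drops
infinite-sites mutations on the resulting trees.

Time is measured in generations before sampling; a deme of diploid size N
coalesces k lineages at rate k(k-1)/(4N) per generation.  Events with equal
times are applied in list order.  All randomness flows through numba's
thread-local NumPy RNG, seeded once per dataset via :func:`seed_kernel_rng`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KIND_SPLIT = 0
KIND_ADMIX = 1
KIND_SIZE = 2

__all__ = [
    "KIND_SPLIT",
    "KIND_ADMIX",
    "KIND_SIZE",
    "seed_kernel_rng",
    "sim_tree_lengths",
    "sim_snp_dosages",
    "sim_poisson_mutations",
]


@njit(cache=True)
def seed_kernel_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _sim_tree(sample_deme, sizes0, ev_time, ev_kind, ev_a, ev_b, ev_c, ev_r,
              parent, node_time):
    """Simulate one genealogy; fill parent/node_time (length 2n-1, root last).

    Returns 0 on success, -1 if lineages can never find a common ancestor
    (stranded in separate demes with no remaining events).
    """
    n = sample_deme.shape[0]
    n_demes = sizes0.shape[0]
    sizes = sizes0.copy()
    active = np.empty(n, np.int64)
    ademe = np.empty(n, np.int64)
    counts = np.zeros(n_demes, np.int64)
    for i in range(n):
        active[i] = i
        ademe[i] = sample_deme[i]
        counts[sample_deme[i]] += 1
        parent[i] = -1
        node_time[i] = 0.0
    for v in range(n, 2 * n - 1):
        parent[v] = -1
        node_time[v] = 0.0
    k = n
    nxt = n
    t = 0.0
    m = ev_time.shape[0]
    ev = 0
    while k > 1:
        total = 0.0
        for d in range(n_demes):
            c = counts[d]
            if c > 1:
                total += c * (c - 1.0) / (4.0 * sizes[d])
        if total > 0.0:
            dt = np.random.exponential(1.0 / total)
        else:
            dt = np.inf
        if ev < m and (t + dt >= ev_time[ev] or not np.isfinite(dt)):
            t = ev_time[ev]
            kind = ev_kind[ev]
            a = ev_a[ev]
            if kind == KIND_SPLIT:
                b = ev_b[ev]
                for i in range(k):
                    if ademe[i] == a:
                        ademe[i] = b
                        counts[a] -= 1
                        counts[b] += 1
            elif kind == KIND_ADMIX:
                b = ev_b[ev]
                c2 = ev_c[ev]
                r = ev_r[ev]
                for i in range(k):
                    if ademe[i] == a:
                        counts[a] -= 1
                        if np.random.random() < r:
                            ademe[i] = b
                            counts[b] += 1
                        else:
                            ademe[i] = c2
                            counts[c2] += 1
            else:  # KIND_SIZE
                sizes[a] = ev_r[ev]
            ev += 1
            continue
        if not np.isfinite(dt):
            return -1
        t += dt
        u = np.random.random() * total
        acc = 0.0
        dsel = -1
        for d in range(n_demes):
            c = counts[d]
            if c > 1:
                acc += c * (c - 1.0) / (4.0 * sizes[d])
                dsel = d
                if u < acc:
                    break
        c = counts[dsel]
        j1 = int(np.random.random() * c)
        if j1 >= c:
            j1 = c - 1
        j2 = int(np.random.random() * (c - 1))
        if j2 >= c - 1:
            j2 = c - 2
        if j2 >= j1:
            j2 += 1
        s1 = -1
        s2 = -1
        seen = 0
        for i in range(k):
            if ademe[i] == dsel:
                if seen == j1:
                    s1 = i
                if seen == j2:
                    s2 = i
                seen += 1
        parent[active[s1]] = nxt
        parent[active[s2]] = nxt
        node_time[nxt] = t
        active[s1] = nxt
        # remove slot s2 (swap with tail)
        active[s2] = active[k - 1]
        ademe[s2] = ademe[k - 1]
        counts[dsel] -= 1
        k -= 1
        nxt += 1
    return 0


@njit(cache=True)
def _total_length(parent, node_time, nn):
    total = 0.0
    for v in range(nn - 1):
        total += node_time[parent[v]] - node_time[v]
    return total


@njit(cache=True)
def _mark_descendants(parent, n, node, derived):
    """Set derived[leaf] = 1 for every sampled copy below `node`."""
    nn = 2 * n - 1
    left = np.full(nn, -1, np.int64)
    right = np.full(nn, -1, np.int64)
    for v in range(nn - 1):
        p = parent[v]
        if left[p] < 0:
            left[p] = v
        else:
            right[p] = v
    stack = np.empty(nn, np.int64)
    top = 0
    stack[top] = node
    top += 1
    while top > 0:
        top -= 1
        v = stack[top]
        if v < n:
            derived[v] = 1
        else:
            stack[top] = left[v]
            top += 1
            stack[top] = right[v]
            top += 1


@njit(cache=True)
def _pick_branch(parent, node_time, nn, total):
    u = np.random.random() * total
    acc = 0.0
    sel = nn - 2
    for v in range(nn - 1):
        acc += node_time[parent[v]] - node_time[v]
        if u < acc:
            sel = v
            break
    return sel


@njit(cache=True)
def sim_tree_lengths(sample_deme, sizes, ev_time, ev_kind, ev_a, ev_b, ev_c,
                     ev_r, n_trees):
    """Total branch lengths of `n_trees` independent genealogies (pilot runs)."""
    n = sample_deme.shape[0]
    nn = 2 * n - 1
    parent = np.empty(nn, np.int64)
    node_time = np.empty(nn, np.float64)
    out = np.empty(n_trees, np.float64)
    for i in range(n_trees):
        ok = _sim_tree(sample_deme, sizes, ev_time, ev_kind, ev_a, ev_b, ev_c,
                       ev_r, parent, node_time)
        if ok < 0:
            out[i] = -1.0
            return out
        out[i] = _total_length(parent, node_time, nn)
    return out


@njit(cache=True)
def sim_snp_dosages(sample_deme, sizes, ev_time, ev_kind, ev_a, ev_b, ev_c,
                    ev_r, n_loci, lam, maf_min, max_tries):
    """Simulate `n_loci` biallelic SNPs, one per retained genealogy.

    A genealogy is retained with probability 1 - exp(-lam * total_length)
    (length-biased acceptance, i.e. conditioning on the locus segregating
    under a Poisson mutation process with per-generation intensity `lam`);
    a single mutation is then placed uniformly on its branches.  Loci whose
    pooled minor-allele frequency is <= maf_min are rejected as well when
    maf_min > 0.  Returns (dosages int8[n_loci, n_ind], status).

    status: 0 ok, -1 stranded lineages, -2 retention quota not met within
    max_tries tree simulations.
    """
    n = sample_deme.shape[0]
    n_ind = n // 2
    nn = 2 * n - 1
    parent = np.empty(nn, np.int64)
    node_time = np.empty(nn, np.float64)
    derived = np.zeros(n, np.int8)
    out = np.zeros((n_loci, n_ind), np.int8)
    got = 0
    tries = 0
    while got < n_loci:
        if tries >= max_tries:
            return out, -2
        tries += 1
        ok = _sim_tree(sample_deme, sizes, ev_time, ev_kind, ev_a, ev_b, ev_c,
                       ev_r, parent, node_time)
        if ok < 0:
            return out, -1
        total = _total_length(parent, node_time, nn)
        if np.random.random() >= 1.0 - np.exp(-lam * total):
            continue
        for i in range(n):
            derived[i] = 0
        v = _pick_branch(parent, node_time, nn, total)
        _mark_descendants(parent, n, v, derived)
        nder = 0
        for i in range(n):
            nder += derived[i]
        if maf_min > 0.0:
            maf = nder / n
            if maf > 0.5:
                maf = 1.0 - maf
            if maf <= maf_min:
                continue
        for i in range(n_ind):
            out[got, i] = derived[2 * i] + derived[2 * i + 1]
        got += 1
    return out, 0


@njit(cache=True)
def sim_poisson_mutations(sample_deme, sizes, ev_time, ev_kind, ev_a, ev_b,
                          ev_c, ev_r, n_loci, lam, buf_cap):
    """Infinite-sites mutations at rate `lam` per branch-generation per locus.

    Every mutation becomes one biallelic site.  Returns
    (dosages int8[buf_cap, n_ind], per_locus_counts int64[n_loci], status);
    status -3 signals buffer overflow (caller re-allocates), -1 stranded.
    """
    n = sample_deme.shape[0]
    n_ind = n // 2
    nn = 2 * n - 1
    parent = np.empty(nn, np.int64)
    node_time = np.empty(nn, np.float64)
    derived = np.zeros(n, np.int8)
    out = np.zeros((buf_cap, n_ind), np.int8)
    counts = np.zeros(n_loci, np.int64)
    filled = 0
    for loc in range(n_loci):
        ok = _sim_tree(sample_deme, sizes, ev_time, ev_kind, ev_a, ev_b, ev_c,
                       ev_r, parent, node_time)
        if ok < 0:
            return out, counts, -1
        total = _total_length(parent, node_time, nn)
        nm = np.random.poisson(lam * total)
        counts[loc] = nm
        for _ in range(nm):
            if filled >= buf_cap:
                return out, counts, -3
            for i in range(n):
                derived[i] = 0
            v = _pick_branch(parent, node_time, nn, total)
            _mark_descendants(parent, n, v, derived)
            for i in range(n_ind):
                out[filled, i] = derived[2 * i] + derived[2 * i + 1]
            filled += 1
    return out, counts, 0
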