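"""Diversity/differentiation statistics against enumeration oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from invadem import (FilterThresholds, diversity, filter_genotypes,
                     hwe_exact_test, mantel_ibd, nei_distance_pcoa,
                     pairwise_fst, rarefied_na)
from invadem.matrix import MISSING
from invadem.stats import FstMatrix, nei_distance

from conftest import as_matrix


# ----------------------------------------------------------------------
# HWE exact test: brute-force oracle over heterozygote counts
# ----------------------------------------------------------------------
def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional het-count law."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    probs = {}
    for het in range(n_minor % 2, n_minor + 1, 2):
        hom_min = (n_minor - het) // 2
        hom_maj = n - het - hom_min
        num = (math.factorial(n) * 2 ** het * math.factorial(n_minor)
               * math.factorial(2 * n - n_minor))
        den = (math.factorial(hom_maj) * math.factorial(het)
               * math.factorial(hom_min) * math.factorial(2 * n))
        probs[het] = Fraction(num, den)
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


@pytest.mark.parametrize("table", [(10, 0, 0), (1, 1, 1), (64, 32, 4),
                                   (0, 5, 0), (3, 0, 3), (2, 7, 1)])
def test_hwe_matches_oracle_examples(table):
    assert hwe_exact_test(*table) == pytest.approx(hwe_oracle(*table), abs=1e-12)


def test_hwe_errors_on_empty_table():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_balanced_sample_near_equilibrium_is_unremarkable():
    assert hwe_exact_test(64, 32, 4) > 0.5


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------
def _toy_filter_matrix():
    """13 individuals x 5 loci: locus 2 rare (1/26 < 0.05 MAF), individual
    0 misses 2/5 = 40% of calls; everything else clean."""
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 2, size=(13, 5)).astype(np.int8) \
        + rng.integers(0, 2, size=(13, 5)).astype(np.int8)
    calls[:, 2] = 0
    calls[0, 2] = 1                      # single alt copy: MAF = 1/26
    calls[0, 0] = MISSING
    calls[0, 1] = MISSING
    return as_matrix(calls, ["A"] * 7 + ["B"] * 6)


def test_filter_removes_exactly_rare_locus_and_missing_individual():
    gm = _toy_filter_matrix()
    th = FilterThresholds(maf_min=0.05, ind_missing_max=0.30,
                          hwe_p_min=1e-6, locus_presence_min=0.8,
                          min_pops_shared=2)
    out, audit = filter_genotypes(gm, th)
    assert audit.removed_individuals == 1
    assert "i0" not in out.individual_ids
    assert "L2" not in out.locus_ids
    assert audit.removed_maf == 1
    audit.check()


def test_filter_idempotent_on_clean_matrix():
    gm = _toy_filter_matrix()
    th = FilterThresholds(min_pops_shared=2)
    once, _ = filter_genotypes(gm, th)
    twice, audit = filter_genotypes(once, th)
    assert np.array_equal(once.calls, twice.calls)
    assert audit.loci_in == audit.loci_retained
    assert audit.removed_individuals == 0


def test_filter_audit_identity(micro_gm):
    _, audit = filter_genotypes(micro_gm, FilterThresholds(min_pops_shared=3))
    audit.check()
    assert audit.loci_in == micro_gm.n_loci


# ----------------------------------------------------------------------
# diversity / rarefaction
# ----------------------------------------------------------------------
def test_diversity_hand_values():
    gm = as_matrix([[0], [1]], ["p", "p"])
    t = diversity(gm).table
    assert t.loc["p", "He"] == pytest.approx(0.375)
    assert t.loc["p", "Ho"] == pytest.approx(0.5)
    mono = as_matrix([[0], [0], [0]], ["p"] * 3)
    t2 = diversity(mono).table
    assert t2.loc["p", "He"] == 0.0 and t2.loc["p", "Ho"] == 0.0


def test_diversity_unbiased_flag():
    gm = as_matrix([[0], [1]], ["p", "p"])
    t = diversity(gm, unbiased=True).table
    assert t.loc["p", "He"] == pytest.approx(0.375 * 4 / 3)


def rarefaction_oracle(alt_copies, n_copies, g):
    """Mean distinct-allele count over all C(N, g) subsamples."""
    pool = [1] * alt_copies + [0] * (n_copies - alt_copies)
    vals = [len(set(sub)) for sub in itertools.combinations(pool, g)]
    return float(np.mean(vals))


def test_rarefied_na_examples_and_exhaustive_oracle():
    gm = as_matrix([[1], [0]], ["p", "p"])       # counts (1,3) over 4 copies
    assert rarefied_na(gm, 2)["p"] == pytest.approx(1.5)
    mono = as_matrix([[0], [0]], ["p", "p"])
    assert rarefied_na(mono, 2)["p"] == pytest.approx(1.0)
    rng = np.random.default_rng(1)
    for _ in range(10):
        n_ind = int(rng.integers(2, 5))          # N = 4, 6, 8 copies
        dose = rng.integers(0, 3, n_ind)
        gm = as_matrix(dose[:, None], ["p"] * n_ind)
        g = int(rng.integers(1, 2 * n_ind))
        expect = rarefaction_oracle(int(dose.sum()), 2 * n_ind, g)
        assert rarefied_na(gm, g)["p"] == pytest.approx(expect, abs=1e-12)


def test_rarefied_na_rejects_oversized_g():
    gm = as_matrix([[1], [0]], ["p", "p"])
    with pytest.raises(ValueError):
        rarefied_na(gm, 5)


# ----------------------------------------------------------------------
# Weir-Cockerham FST
# ----------------------------------------------------------------------
def wc_theta_oracle(calls1, calls2):
    """Literal per-locus transcription of the variance components."""
    num = den = 0.0
    r = 2
    for j in range(calls1.shape[1]):
        stats = []
        for calls in (calls1, calls2):
            col = calls[:, j]
            col = col[col != MISSING]
            n = len(col)
            if n == 0:
                stats = None
                break
            p = col.sum() / (2 * n)
            h = np.mean(col == 1)
            stats.append((n, p, h))
        if stats is None:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        nbar = (n1 + n2) / 2
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (s2 - 1 / (nbar - 1)
                         * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def test_wc_theta_matches_independent_oracle():
    rng = np.random.default_rng(2)
    calls = rng.integers(0, 3, size=(14, 40)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = MISSING
    gm = as_matrix(calls, ["A"] * 7 + ["B"] * 7)
    theta = pairwise_fst(gm).values.loc["A", "B"]
    oracle = wc_theta_oracle(calls[:7], calls[7:])
    assert theta == pytest.approx(oracle, abs=1e-12)


def test_fst_symmetric_and_permutation_reproducible(micro_gm):
    f1 = pairwise_fst(micro_gm, n_perm=30, seed=9)
    f2 = pairwise_fst(micro_gm, n_perm=30, seed=9)
    assert np.allclose(f1.values, f1.values.T)
    assert f1.pvalues.equals(f2.pvalues)
    assert ((f1.pvalues.fillna(1) > 0) & (f1.pvalues.fillna(1) <= 1)).all().all()


# ----------------------------------------------------------------------
# Mantel isolation by distance
# ----------------------------------------------------------------------
def _fst_from(values, pops):
    df = pd.DataFrame(values, index=pops, columns=pops)
    return FstMatrix(values=df, pvalues=None, n_permutations=0)


def test_mantel_perfect_line_r_one():
    # y = F/(1-F) built to be exactly linear in log-distance
    pops = list("ABCD")
    coords = {p: (0.0, 1.0 * 2 ** i) for i, p in enumerate(pops)}
    k = len(pops)
    lin = np.zeros((k, k))
    from invadem.stats import haversine_km
    for i in range(k):
        for j in range(i + 1, k):
            x = math.log(haversine_km(*coords[pops[i]], *coords[pops[j]]))
            y = 0.01 * x + 0.005
            lin[i, j] = lin[j, i] = y / (1 + y)   # so that F/(1-F) = y
    res = mantel_ibd(_fst_from(lin, pops), coords, n_perm=49, seed=0)
    assert res.r == pytest.approx(1.0, abs=1e-9)


def test_mantel_permutation_matches_exhaustive_enumeration():
    rng = np.random.default_rng(4)
    pops = list("ABCD")
    coords = {p: (float(rng.uniform(30, 38)), float(rng.uniform(125, 131)))
              for p in pops}
    f = np.zeros((4, 4))
    iu = np.triu_indices(4, 1)
    vals = rng.uniform(0.02, 0.2, 6)
    f[iu] = vals
    f += f.T
    fst = _fst_from(f, pops)
    res = mantel_ibd(fst, coords, n_perm=4999, seed=1)
    # oracle: exact permutation distribution over all 4! relabelings
    from invadem.stats import haversine_km
    x = np.array([math.log(haversine_km(*coords[pops[i]], *coords[pops[j]]))
                  for i, j in zip(*iu)])
    lin = np.clip(f, 1e-6, None) / (1 - np.clip(f, 1e-6, None))
    np.fill_diagonal(lin, 0)
    r_obs = np.corrcoef(x, lin[iu])[0, 1]
    count = total = 0
    for perm in itertools.permutations(range(4)):
        rp = np.corrcoef(x, lin[np.ix_(perm, perm)][iu])[0, 1]
        total += 1
        if abs(rp) >= abs(r_obs) - 1e-15:
            count += 1
    exact_p = count / total
    assert res.p == pytest.approx(exact_p, abs=0.03)


def test_linearization_arithmetic():
    assert 0.5 / (1 - 0.5) == pytest.approx(1.0)


def test_mantel_rejects_coincident_populations():
    pops = ["A", "B"]
    coords = {"A": (33.0, 126.0), "B": (33.0, 126.0)}
    with pytest.raises(ValueError, match="coincident"):
        mantel_ibd(_fst_from(np.array([[0, .1], [.1, 0]]), pops), coords,
                   n_perm=9)


# ----------------------------------------------------------------------
# Nei distance / PCoA
# ----------------------------------------------------------------------
def test_nei_identical_populations_distance_zero():
    calls = np.tile(np.array([[0, 1, 2, 1]], dtype=np.int8), (6, 1))
    gm = as_matrix(calls, ["A"] * 3 + ["B"] * 3)
    D, _ = nei_distance(gm)
    assert D[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_pcoa_embedding_reproduces_distances(micro_gm):
    res = nei_distance_pcoa(micro_gm, level="individual", n_axes=10)
    D, items = nei_distance(micro_gm, level="individual")
    # Euclidean distances in the full positive-eigenvalue embedding
    # approximate the input distances (exact when D is Euclidean)
    C = res.coordinates.to_numpy()
    d01 = np.linalg.norm(C[0] - C[1])
    assert d01 == pytest.approx(D[0, 1], rel=0.2)
    assert np.all(np.diff(res.percent_variance) <= 1e-9)
    assert res.percent_variance[0] >= res.percent_variance[-1]


def test_pcoa_exact_for_euclidean_three_points():
    # distances of a 3-4-5 right triangle are exactly embeddable
    import skbio
    from skbio.stats.ordination import pcoa
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    res = pcoa(skbio.DistanceMatrix(D, ids=list("abc")))
    C = res.samples.to_numpy()
    for i in range(3):
        for j in range(3):
            assert np.linalg.norm(C[i] - C[j]) == pytest.approx(D[i, j],
                                                                abs=1e-9)
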