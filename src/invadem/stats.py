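"""SNP filtering and diversity / differentiation statistics.

Implements the standard RAD-panel workflow for diploid biallelic SNPs:
an exact Hardy-Weinberg test, ordered genotype filtering with an audit
trail, expected/observed heterozygosity, rarefied allelic richness,
multi-locus Weir-Cockerham FST with permutation tests, Nei's (1972)
standard genetic distance with principal-coordinates analysis, and a
Mantel isolation-by-distance test on linearized FST.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .matrix import GenotypeMatrix, MISSING

__all__ = [
    "FilterThresholds",
    "FilterAudit",
    "DiversityTable",
    "FstMatrix",
    "MantelResult",
    "PcoaResult",
    "hwe_exact_test",
    "filter_genotypes",
    "diversity",
    "rarefied_na",
    "pairwise_fst",
    "mantel_ibd",
    "nei_distance",
    "nei_distance_pcoa",
    "haversine_km",
]


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------
def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (the standard SNP exact test of Wigginton et al.).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_Aa  # copies of one allele
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0

    def logprob(het: int) -> float:
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        return (math.lgamma(n + 1)
                - math.lgamma(hom_major + 1) - math.lgamma(het + 1)
                - math.lgamma(hom_minor + 1)
                + het * math.log(2.0)
                + math.lgamma(n_minor + 1) + math.lgamma(2 * n - n_minor + 1)
                - math.lgamma(2 * n + 1))

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logs = np.array([logprob(int(h)) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = np.flatnonzero(hets == n_Aa)
    if obs.size == 0:  # inconsistent table
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the fixed four-step filter (see :func:`filter_genotypes`).

    Defaults reproduce a Stacks -> Plink -> Tassel style pipeline: loci
    called in >= 80% of samples within each of >= 12 populations, exact
    HWE exclusion at p < 1e-6 on the pooled sample, individuals with
    > 30% missing calls dropped, then pooled minor allele frequency
    <= 0.05 dropped.
    """

    maf_min: float = 0.05
    ind_missing_max: float = 0.30
    hwe_p_min: float = 1e-6
    locus_presence_min: float = 0.80
    min_pops_shared: int = 12

    def __post_init__(self) -> None:
        for name in ("maf_min", "ind_missing_max", "locus_presence_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.hwe_p_min < 1.0:
            raise ValueError("hwe_p_min must be in (0, 1)")
        if self.min_pops_shared < 1:
            raise ValueError("min_pops_shared must be >= 1")


@dataclass
class FilterAudit:
    loci_in: int
    removed_presence: int
    removed_hwe: int
    removed_maf: int
    loci_retained: int
    individuals_in: int
    removed_individuals: int
    individuals_retained: int

    def check(self) -> None:
        assert self.loci_in == (self.removed_presence + self.removed_hwe
                                + self.removed_maf + self.loci_retained)
        assert self.individuals_in == (self.removed_individuals
                                       + self.individuals_retained)


def filter_genotypes(gm: GenotypeMatrix, th: FilterThresholds = FilterThresholds()
                     ) -> tuple[GenotypeMatrix, FilterAudit]:
    """Apply the four filters in fixed order; return new matrix + audit.

    Order: per-population locus presence, pooled HWE, per-individual
    missingness, pooled MAF.  When fewer populations than
    ``min_pops_shared`` exist, the sharing requirement degrades to "all
    populations".
    """
    pops = gm.populations
    need_pops = min(th.min_pops_shared, len(pops))
    called = gm.calls != MISSING

    # 1. locus presence per population
    pres_ok = np.zeros(gm.n_loci, dtype=np.int64)
    for pop in pops:
        idx = gm.pop_indices(pop)
        frac = called[idx].mean(axis=0)
        pres_ok += frac >= th.locus_presence_min
    keep1 = pres_ok >= need_pops
    removed_presence = int((~keep1).sum())

    # 2. pooled exact HWE
    keep2 = keep1.copy()
    sub = gm.calls
    for j in np.flatnonzero(keep1):
        col = sub[:, j]
        col = col[col != MISSING]
        n_aa = int((col == 2).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 0).sum())
        if n_AA + n_Aa + n_aa == 0:
            keep2[j] = False
            continue
        if hwe_exact_test(n_AA, n_Aa, n_aa) < th.hwe_p_min:
            keep2[j] = False
    removed_hwe = int(keep1.sum() - keep2.sum())

    # 3. individual missingness on surviving loci
    loci_idx = np.flatnonzero(keep2)
    miss = (gm.calls[:, loci_idx] == MISSING).mean(axis=1) if loci_idx.size \
        else np.zeros(gm.n_individuals)
    ind_keep = miss <= th.ind_missing_max
    removed_ind = int((~ind_keep).sum())

    # 4. pooled MAF on surviving individuals
    calls3 = gm.calls[np.ix_(np.flatnonzero(ind_keep), loci_idx)]
    called3 = calls3 != MISSING
    alt = np.where(called3, calls3, 0).sum(axis=0)
    tot = 2 * called3.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    keep4 = maf > th.maf_min
    removed_maf = int((~keep4).sum())

    out = gm.restrict(individuals=np.flatnonzero(ind_keep),
                      loci=loci_idx[keep4])
    audit = FilterAudit(
        loci_in=gm.n_loci, removed_presence=removed_presence,
        removed_hwe=removed_hwe, removed_maf=removed_maf,
        loci_retained=out.n_loci, individuals_in=gm.n_individuals,
        removed_individuals=removed_ind, individuals_retained=out.n_individuals)
    audit.check()
    return out, audit


# ----------------------------------------------------------------------
# diversity
# ----------------------------------------------------------------------
@dataclass
class DiversityTable:
    table: pd.DataFrame  # index pop; columns He, Ho, [Na], n, He_se, Ho_se


def diversity(gm: GenotypeMatrix, unbiased: bool = False) -> DiversityTable:
    """Per-population mean expected / observed heterozygosity over loci.

    He per locus is ``1 - p^2 - q^2`` from the within-population allele
    frequency (GENALEX convention); ``unbiased=True`` applies the
    ``2n/(2n-1)`` small-sample correction.  Ho is the fraction of
    heterozygous calls.  Standard errors are across loci.
    """
    rows = {}
    for pop in gm.populations:
        idx = gm.pop_indices(pop)
        calls = gm.calls[idx]
        called = calls != MISSING
        tot = 2 * called.sum(axis=0)
        if tot.sum() == 0:
            raise ValueError(f"population {pop!r} has no non-missing calls")
        ok = tot > 0
        alt = np.where(called, calls, 0).sum(axis=0)[ok]
        n_copies = tot[ok]
        p = alt / n_copies
        he = 2 * p * (1 - p)
        if unbiased:
            he = he * n_copies / (n_copies - 1)
        ho = (calls[:, ok] == 1).sum(axis=0) / called[:, ok].sum(axis=0)
        rows[pop] = {
            "He": he.mean(), "Ho": ho.mean(), "n": len(idx),
            "He_se": he.std(ddof=1) / np.sqrt(he.size) if he.size > 1 else 0.0,
            "Ho_se": ho.std(ddof=1) / np.sqrt(ho.size) if ho.size > 1 else 0.0,
        }
    return DiversityTable(pd.DataFrame(rows).T)


def rarefied_na(gm: GenotypeMatrix, g: int) -> pd.Series:
    """Rarefied allele count per population at ``g`` gene copies.

    Per locus, ``Na(g) = sum_alleles 1 - C(N - N_i, g) / C(N, g)`` with N
    the non-missing copies and N_i the copies of allele i; averaged over
    loci with N >= g (loci with fewer copies are skipped and counted).
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    out = {}
    for pop in gm.populations:
        idx = gm.pop_indices(pop)
        if g > 2 * len(idx):
            raise ValueError(f"g={g} exceeds copies available in {pop!r}")
        calls = gm.calls[idx]
        called = calls != MISSING
        N = 2 * called.sum(axis=0)
        alt = np.where(called, calls, 0).sum(axis=0)
        vals = []
        skipped = 0
        for j in range(gm.n_loci):
            if N[j] < g:
                skipped += 1
                continue
            # math.comb(N - copies, g) is 0 when fewer than g copies remain,
            # i.e. the allele is guaranteed to appear in the subsample
            denom = math.comb(int(N[j]), g)
            na = sum(1.0 - math.comb(int(N[j] - copies), g) / denom
                     for copies in (alt[j], N[j] - alt[j]))
            vals.append(na)
        if not vals:
            raise ValueError(f"no locus with >= {g} copies in {pop!r}")
        out[pop] = (float(np.mean(vals)), skipped)
    return pd.Series({k: v[0] for k, v in out.items()}, name=f"Na({g})")


# ----------------------------------------------------------------------
# Weir-Cockerham FST
# ----------------------------------------------------------------------
def _wc_components_pair(calls1: np.ndarray, calls2: np.ndarray
                        ) -> tuple[float, float]:
    """Summed (a, a+b+c) Weir-Cockerham variance components over loci for
    two populations of diploid calls (missing = -1)."""
    r = 2.0
    comp_a = np.zeros(calls1.shape[1])
    comp_abc = np.zeros(calls1.shape[1])
    n_i = np.empty((2, calls1.shape[1]))
    p_i = np.empty((2, calls1.shape[1]))
    h_i = np.empty((2, calls1.shape[1]))
    for s, calls in enumerate((calls1, calls2)):
        called = calls != MISSING
        n = called.sum(axis=0).astype(float)
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[s] = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
            h_i[s] = np.where(n > 0,
                              (calls == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
        n_i[s] = n
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    valid = (n_i > 0).all(axis=0) & (nbar > 1) & (nc > 0)
    comp_a[valid] = a[valid]
    comp_abc[valid] = (a + b + c)[valid]
    if not valid.any():
        return np.nan, np.nan
    return float(comp_a.sum()), float(comp_abc.sum())


def _theta_from_components(num: float, den: float) -> float:
    if not np.isfinite(num) or den == 0:
        return np.nan
    return num / den


@dataclass
class FstMatrix:
    values: pd.DataFrame
    pvalues: pd.DataFrame | None
    n_permutations: int


def pairwise_fst(gm: GenotypeMatrix, n_perm: int = 0, seed: int | None = None
                 ) -> FstMatrix:
    """Multi-locus Weir-Cockerham theta for every population pair.

    Theta is the ratio of summed variance components over loci.  With
    ``n_perm > 0``, a one-sided permutation test relabels individuals
    within each pair; p = (b + 1) / (m + 1) where b counts permuted theta
    >= observed.
    """
    pops = gm.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    rng = np.random.default_rng(seed)
    vals = pd.DataFrame(0.0, index=pops, columns=pops)
    pvals = pd.DataFrame(np.nan, index=pops, columns=pops) if n_perm else None
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            c1 = gm.calls[gm.pop_indices(p1)]
            c2 = gm.calls[gm.pop_indices(p2)]
            if c1.shape[0] < 2 or c2.shape[0] < 2:
                raise ValueError("each population needs >= 2 individuals")
            num, den = _wc_components_pair(c1, c2)
            theta = _theta_from_components(num, den)
            vals.loc[p1, p2] = vals.loc[p2, p1] = theta
            if n_perm:
                pooled = np.vstack([c1, c2])
                n1 = c1.shape[0]
                b = 0
                for _ in range(n_perm):
                    perm = rng.permutation(pooled.shape[0])
                    tnum, tden = _wc_components_pair(pooled[perm[:n1]],
                                                     pooled[perm[n1:]])
                    if _theta_from_components(tnum, tden) >= theta:
                        b += 1
                p = (b + 1) / (n_perm + 1)
                pvals.loc[p1, p2] = pvals.loc[p2, p1] = p
    return FstMatrix(values=vals, pvalues=pvals, n_permutations=n_perm)


# ----------------------------------------------------------------------
# Mantel isolation by distance
# ----------------------------------------------------------------------
@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres."""
    rad = math.pi / 180.0
    dlat = (lat2 - lat1) * rad
    dlon = (lon2 - lon1) * rad
    a = (math.sin(dlat / 2) ** 2
         + math.cos(lat1 * rad) * math.cos(lat2 * rad) * math.sin(dlon / 2) ** 2)
    return 2 * 6371.0088 * math.asin(math.sqrt(a))


def mantel_ibd(fst: FstMatrix, coords: dict[str, tuple[float, float]],
               n_perm: int = 999, seed: int | None = None,
               planar: bool = False) -> MantelResult:
    """Mantel test of linearized FST against log geographic distance.

    y = theta / (1 - theta) (theta clamped below at 1e-6 for log/ratio
    safety), x = ln(distance); distances are great-circle kilometres by
    default, or planar Euclidean degrees with ``planar=True``.  The
    permutation p-value jointly permutes rows/columns of one matrix.
    """
    pops = list(fst.values.index)
    missing = [p for p in pops if p not in coords]
    if missing:
        raise ValueError(f"no coordinates for populations {missing}")
    k = len(pops)
    geo = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            (la1, lo1), (la2, lo2) = coords[pops[i]], coords[pops[j]]
            d = (math.hypot(la1 - la2, lo1 - lo2) if planar
                 else haversine_km(la1, lo1, la2, lo2))
            if d <= 0:
                raise ValueError(f"coincident populations {pops[i]}/{pops[j]}")
            geo[i, j] = geo[j, i] = math.log(d)
    theta = np.clip(fst.values.to_numpy(float), 1e-6, None)
    lin = theta / (1 - theta)
    np.fill_diagonal(lin, 0.0)
    iu = np.triu_indices(k, 1)
    x = geo[iu]

    def corr(mat: np.ndarray) -> float:
        return float(np.corrcoef(x, mat[iu])[0, 1])

    r_obs = corr(lin)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        if abs(corr(lin[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-15:
            b += 1
    return MantelResult(r=r_obs, p=(b + 1) / (n_perm + 1), n_permutations=n_perm)


# ----------------------------------------------------------------------
# Nei distance + PCoA
# ----------------------------------------------------------------------
def _nei_from_freqs(freqs: np.ndarray) -> np.ndarray:
    """Nei (1972) standard distance between rows of per-locus alt
    frequencies (NaN = untyped locus for that item)."""
    k = freqs.shape[0]
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~np.isnan(freqs[i]) & ~np.isnan(freqs[j])
            if not ok.any():
                raise ValueError(f"items {i} and {j} share no typed loci")
            p1, p2 = freqs[i, ok], freqs[j, ok]
            jxy = np.mean(p1 * p2 + (1 - p1) * (1 - p2))
            jx = np.mean(p1 ** 2 + (1 - p1) ** 2)
            jy = np.mean(p2 ** 2 + (1 - p2) ** 2)
            ident = jxy / math.sqrt(jx * jy)
            D[i, j] = D[j, i] = -math.log(min(ident, 1.0)) if ident > 0 else np.inf
    return D


def nei_distance(gm: GenotypeMatrix, level: str = "population"
                 ) -> tuple[np.ndarray, list[str]]:
    if level == "population":
        items = gm.populations
        freqs = np.vstack([gm.allele_freqs(p) for p in items])
    elif level == "individual":
        items = list(gm.individual_ids)
        with np.errstate(invalid="ignore"):
            freqs = np.where(gm.calls == MISSING, np.nan, gm.calls / 2.0)
    else:
        raise ValueError("level must be 'population' or 'individual'")
    return _nei_from_freqs(freqs), items


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame
    percent_variance: np.ndarray


def nei_distance_pcoa(gm: GenotypeMatrix, level: str = "population",
                      n_axes: int = 3) -> PcoaResult:
    """Principal coordinates of Nei's genetic distance (Gower centering)."""
    D, items = nei_distance(gm, level)
    if len(items) < 3:
        raise ValueError("need >= 3 items for PCoA")
    res = _skbio_pcoa(DistanceMatrix(D, ids=items), number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    pos = eig[eig > 0]
    pct = 100.0 * pos / pos.sum()
    k = min(n_axes, pos.size)
    coords = res.samples.iloc[:, :k]
    coords.columns = [f"axis{i+1}" for i in range(k)]
    return PcoaResult(coordinates=coords, percent_variance=pct[:k])
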