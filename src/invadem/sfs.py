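"""Folded-SFS construction and single-population demographic fitting.

A population's folded site-frequency spectrum (counts of SNP loci whose
minor allele occurs 1..n/2 times among n sampled gene copies) is fitted
against the expected spectrum of the three size-history models
(constant, bottleneck, bottleneck + rebound) by maximizing the
multinomial composite log-likelihood

    lnL = sum_i  c_i * ln(pi_i),

where pi is the expected folded class distribution renormalized over
segregating classes (monomorphic mass excluded: the data are ascertained
SNPs without invariant-site counts).  Models are compared by
AIC = 2k - 2 lnL; confidence intervals come from refitting multinomial
bootstrap resamples of the observed spectrum.

Because the monomorphic class is excluded, the constant model's spectrum
does not depend on its size parameter: only size *changes* (relative to
the contemporary size, on the coalescent timescale) leave a signature in
the renormalized folded spectrum.  The contemporary size can therefore
be fixed to an external estimate (e.g. the LD-based Ne) via ``n_con``,
which also anchors the absolute time scale of the fitted history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import hypergeom

from .matrix import GenotypeMatrix, MISSING
from .simulate import DemographicModel, SimulationConfig, expected_folded_sfs

__all__ = [
    "FoldedSFS",
    "FitResult",
    "BootstrapCI",
    "folded_sfs",
    "composite_loglik",
    "fit_model",
    "select_model",
    "bootstrap_cis",
    "read_obs",
    "write_obs",
]


@dataclass
class FoldedSFS:
    """Counts over minor-allele classes 1..n/2 (monomorphic excluded)."""

    counts: np.ndarray
    n_copies: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n_copies < 4 or self.n_copies % 2:
            raise ValueError("n_copies must be an even number >= 4")
        if self.counts.shape != (self.n_copies // 2,):
            raise ValueError("counts must cover classes 1..n_copies/2")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def n_loci(self) -> float:
        return float(self.counts.sum())

    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def folded_sfs(gm_pop: GenotypeMatrix, policy: str = "complete_only",
               project_to: int | None = None) -> FoldedSFS:
    """Folded spectrum of one population's SNPs.

    ``complete_only`` keeps loci with no missing call in the population
    (n = 2 x individuals); ``project_to`` projects loci with missing
    calls down to ``project_to`` copies by hypergeometric expectation.
    Monomorphic loci are excluded either way.
    """
    if gm_pop.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    calls = gm_pop.calls
    called = calls != MISSING
    alt = np.where(called, calls, 0).sum(axis=0)
    m = 2 * called.sum(axis=0)
    if policy == "complete_only":
        n = 2 * gm_pop.n_individuals
        full = m == n
        seg = full & (alt > 0) & (alt < n)
        if not seg.any():
            raise ValueError("no segregating fully-typed locus in this population")
        minor = np.minimum(alt[seg], n - alt[seg])
        counts = np.bincount(minor, minlength=n // 2 + 1)[1:n // 2 + 1].astype(float)
        return FoldedSFS(counts, n)
    if policy == "project_to":
        if project_to is None or project_to < 4 or project_to % 2:
            raise ValueError("project_to must be an even number >= 4")
        n = project_to
        expected = np.zeros(n + 1)
        usable = (m >= n) & (alt > 0) & (alt < m)
        if not usable.any():
            raise ValueError("no projectable segregating locus")
        for k, mm in zip(alt[usable], m[usable]):
            j = np.arange(n + 1)
            expected += hypergeom.pmf(j, mm, k, n)
        unfolded = expected[1:n]  # drop projected monomorphic mass
        half = n // 2
        counts = np.empty(half)
        for j in range(1, half + 1):
            counts[j - 1] = unfolded[j - 1] if 2 * j == n \
                else unfolded[j - 1] + unfolded[n - j - 1]
        return FoldedSFS(counts, n)
    raise ValueError("policy must be 'complete_only' or 'project_to'")


# ----------------------------------------------------------------------
# likelihood and fitting
# ----------------------------------------------------------------------
def composite_loglik(sfs: FoldedSFS, model: DemographicModel,
                     mode: str = "analytic", n_loci_mc: int = 100_000,
                     seed: int | None = None) -> float:
    """Multinomial composite log-likelihood of the spectrum under a model."""
    pi = expected_folded_sfs(model, sfs.n_copies, mode=mode,
                             n_loci=n_loci_mc, seed=seed)
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    if np.any((pi == 0) & (sfs.counts > 0)):
        return -math.inf
    return float(np.sum(np.where(sfs.counts > 0, sfs.counts * logpi, 0.0)))


# free parameters per model, in log10 space; bounds sizes [1, 1e7],
# times [1, 1e4]; the rebound model optimizes (T_BOT, dT) so that
# T_ENDBOT = T_BOT + dT > T_BOT by construction.
_FREE = {
    "constant": [],
    "bottleneck": [("N_ANC", 0.0, 7.0), ("T_ENDBOT", 0.0, 4.0)],
    "bottleneck_rebound": [("N_ANC", 0.0, 7.0), ("N_BOT", 0.0, 7.0),
                           ("T_BOT", 0.0, 4.0), ("dT", -1.0, 4.0)],
}


def _build_model(model_id: str, n_con: float, log_params: dict[str, float]
                 ) -> DemographicModel:
    vals = {k: 10.0 ** v for k, v in log_params.items()}
    if model_id == "constant":
        return DemographicModel("constant", N_CON=n_con)
    if model_id == "bottleneck":
        return DemographicModel("bottleneck", N_CON=n_con,
                                N_ANC=vals["N_ANC"], T_ENDBOT=vals["T_ENDBOT"])
    return DemographicModel("bottleneck_rebound", N_CON=n_con,
                            N_ANC=vals["N_ANC"], N_BOT=vals["N_BOT"],
                            T_BOT=vals["T_BOT"],
                            T_ENDBOT=vals["T_BOT"] + vals["dT"])


@dataclass
class FitResult:
    model: DemographicModel
    lnL_max: float
    k: int
    aic: float
    n_restarts: int
    converged: bool
    free_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert abs(self.aic - (2 * self.k - 2 * self.lnL_max)) < 1e-9


def fit_model(sfs: FoldedSFS, model_id: str, n_restarts: int = 8,
              max_cycles: int = 80, tol: float = 1e-3, mode: str = "analytic",
              seed: int | None = None, n_con: float | None = None,
              free_ncon: bool | None = None, starts: list[dict] | None = None
              ) -> FitResult:
    """Maximize the composite likelihood by cyclic coordinate ascent.

    One Brent line search per free parameter per cycle, on log10 scale,
    multi-started from random points; a restart stops when the cycle
    improvement in lnL drops below ``tol``.  ``n_con`` fixes the
    contemporary size (recommended: an external Ne estimate); with
    ``free_ncon=True`` it is optimized instead.  The free-parameter
    count ``k`` is what AIC penalizes.
    """
    if model_id not in _FREE:
        raise ValueError(f"unknown model {model_id!r}")
    if sfs.counts.sum() <= 0:
        raise ValueError("degenerate spectrum: no segregating loci")
    if free_ncon is None:
        free_ncon = n_con is None
    base_ncon = 1000.0 if n_con is None else float(n_con)
    free = list(_FREE[model_id])
    if free_ncon:
        free = [("N_CON", 0.0, 7.0)] + free
    rng = np.random.default_rng(seed)

    def lnl(log_params: dict[str, float]) -> float:
        ncon = 10.0 ** log_params["N_CON"] if free_ncon else base_ncon
        mdl = _build_model(model_id, ncon,
                           {k: v for k, v in log_params.items() if k != "N_CON"})
        return composite_loglik(sfs, mdl, mode=mode)

    if not free:  # constant model with fixed size: nothing to optimize
        mdl = _build_model(model_id, base_ncon, {})
        ll = composite_loglik(sfs, mdl, mode=mode)
        return FitResult(mdl, ll, 0, -2 * ll, 0, True, ())

    best_ll = -math.inf
    best_params: dict[str, float] = {}
    best_conv = False
    start_list = list(starts or [])
    while len(start_list) < n_restarts:
        start_list.append({name: rng.uniform(lo, hi) for name, lo, hi in free})
    for start in start_list[:max(n_restarts, len(start_list))]:
        params = dict(start)
        ll = lnl(params)
        conv = False
        for _ in range(max_cycles):
            prev = ll
            for name, lo, hi in free:
                def neg(v: float, _n=name) -> float:
                    trial = dict(params)
                    trial[_n] = v
                    return -lnl(trial)
                res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                      options={"xatol": 1e-4})
                if -res.fun > ll:
                    params[name] = float(res.x)
                    ll = -res.fun
            if ll - prev < tol:
                conv = True
                break
        if ll > best_ll:
            best_ll, best_params, best_conv = ll, dict(params), conv
    ncon = 10.0 ** best_params["N_CON"] if free_ncon else base_ncon
    mdl = _build_model(model_id, ncon,
                       {k: v for k, v in best_params.items() if k != "N_CON"})
    k = len(free)
    return FitResult(mdl, best_ll, k, 2 * k - 2 * best_ll, len(start_list),
                     best_conv, tuple(n for n, _, _ in free))


def select_model(fits: list[FitResult]) -> tuple[pd.DataFrame, FitResult]:
    """Rank fits by AIC (ascending); ties go to the simpler model."""
    if not fits:
        raise ValueError("need at least one fit")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].k))
    rows = [{"model": fits[i].model.model_id, "k": fits[i].k,
             "lnL": fits[i].lnL_max, "AIC": fits[i].aic,
             "dAIC": fits[i].aic - fits[order[0]].aic} for i in order]
    return pd.DataFrame(rows), fits[order[0]]


@dataclass
class BootstrapCI:
    intervals: dict[str, tuple[float, float]]
    n_boot: int
    n_failed: int
    warning: str = ""


def bootstrap_cis(sfs: FoldedSFS, model_id: str, mle: FitResult,
                  n_boot: int = 50, seed: int | None = None,
                  n_restarts: int = 3, **fit_kwargs) -> BootstrapCI:
    """Percentile 95% CIs from multinomial resamples of the spectrum.

    Each pseudo-replicated spectrum redraws ``n_loci`` loci from the
    observed class proportions and is refitted (the MLE is included as a
    warm start).  Parameters reported are the model's fitted fields.
    """
    rng = np.random.default_rng(seed)
    n = int(round(sfs.n_loci))
    p = sfs.proportions()
    names = [f for f in ("N_CON", "N_ANC", "N_BOT", "T_BOT", "T_ENDBOT")
             if getattr(mle.model, f) is not None]
    warm = _warm_start(mle)
    samples: dict[str, list[float]] = {k: [] for k in names}
    failed = 0
    for _ in range(n_boot):
        counts = rng.multinomial(n, p).astype(float)
        if counts.sum() == 0:
            failed += 1
            continue
        boot = FoldedSFS(counts, sfs.n_copies)
        try:
            fit = fit_model(boot, model_id, n_restarts=n_restarts,
                            seed=int(rng.integers(2**31 - 1)),
                            starts=[warm] if warm else None, **fit_kwargs)
        except Exception:
            failed += 1
            continue
        for k in names:
            samples[k].append(float(getattr(fit.model, k)))
    ivs = {}
    for k in names:
        vals = np.array(samples[k])
        if vals.size == 0:
            ivs[k] = (math.nan, math.nan)
        else:
            ivs[k] = (float(np.percentile(vals, 2.5)),
                      float(np.percentile(vals, 97.5)))
    warning = ""
    if n_boot and failed / n_boot > 0.2:
        warning = f"{failed}/{n_boot} bootstrap refits failed"
    return BootstrapCI(ivs, n_boot, failed, warning)


def _warm_start(mle: FitResult) -> dict[str, float]:
    out = {}
    m = mle.model
    for name in mle.free_names:
        if name == "dT":
            out[name] = math.log10(max(m.T_ENDBOT - m.T_BOT, 0.1))
        else:
            out[name] = math.log10(max(getattr(m, name), 1.0))
    return out


# ----------------------------------------------------------------------
# fastsimcoal-style .obs I/O (single-population folded "MAF" dialect)
# ----------------------------------------------------------------------
def write_obs(sfs: FoldedSFS, path: str) -> None:
    """Write the single-population folded spectrum in the _MAFpop0.obs
    dialect: a header line, a class-label line (d0_0 .. d0_{n/2}), and
    one line of counts with the monomorphic class written as 0."""
    half = sfs.n_copies // 2
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        fh.write("\t".join(f"d0_{j}" for j in range(half + 1)) + "\n")
        fh.write("\t".join(["0"] + [f"{c:g}" for c in sfs.counts]) + "\n")


def read_obs(path: str) -> FoldedSFS:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ValueError("not a recognizable .obs file")
    labels = lines[1].split()
    counts = np.array([float(x) for x in lines[2].split()])
    if len(labels) != len(counts):
        raise ValueError("label/count length mismatch in .obs file")
    half = len(counts) - 1
    return FoldedSFS(counts[1:], 2 * half)
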