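"""ABC random-forest scenario choice and parameter estimation.

Approximate Bayesian computation with random forests replaces
rejection-style ABC: a classifier forest is trained on summary
statistics of datasets simulated under competing scenarios, the
scenario's support is read from per-tree votes on the observed vector,
and the posterior probability of the selected scenario is estimated as
1 - local error, where the local error is an out-of-bag (OOB)
misclassification rate regressed onto summary space and evaluated at
the observed point.  Parameters of the selected scenario are estimated
with regression forests whose leaf co-occurrence weights also provide
posterior quantiles and a locally-weighted normalized mean absolute
error (NMAE).

Summary statistics follow the DIYABC families the study found most
informative: per-population variability (proportion of polymorphic
loci, mean and variance of expected heterozygosity, mean minor-allele
frequency), pairwise differentiation (Weir-Cockerham FST, Nei distance,
f2), and three-sample statistics (bias-corrected f3 and the
least-squares two-source admixture coefficient alpha for each target
population).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .matrix import GenotypeMatrix, MISSING
from .simulate import (InvasionScenario, PriorSpec, ScenarioParameters,
                       SimulationConfig, sample_priors, simulate_scenario,
                       PARAM_NAMES)
from .stats import _wc_components_pair, _theta_from_components

__all__ = [
    "ReferenceTable",
    "ScenarioChoice",
    "ParamEstimate",
    "summary_statistics",
    "build_reference_table",
    "classify_scenario",
    "lda_projection",
    "estimate_parameters",
]


# ----------------------------------------------------------------------
# summary statistics
# ----------------------------------------------------------------------
def summary_names(pops: tuple[str, str, str] = ("pop1", "pop2", "pop3")
                  ) -> list[str]:
    names = []
    for p in pops:
        names += [f"ppoly_{p}", f"he_mean_{p}", f"he_var_{p}", f"maf_mean_{p}"]
    pairs = [(0, 1), (0, 2), (1, 2)]
    for i, j in pairs:
        names += [f"fst_{pops[i]}_{pops[j]}", f"neid_{pops[i]}_{pops[j]}",
                  f"f2_{pops[i]}_{pops[j]}"]
    for t in range(3):
        names += [f"f3_{pops[t]}", f"alpha_{pops[t]}"]
    for i, j in pairs:
        names.append(f"fst_{pops[i]}_{pops[j]}_ok")
    for t in range(3):
        names.append(f"alpha_{pops[t]}_ok")
    return names


def summary_statistics(gm: GenotypeMatrix) -> pd.Series:
    """Fixed-schema summary vector for a three-population SNP matrix.

    Degenerate entries (e.g. FST with an all-monomorphic population,
    alpha with coincident donor frequencies) are imputed as 0 with their
    paired ``*_ok`` indicator set to 0 so that vector length and order
    stay constant across simulations.
    """
    pops = gm.populations
    if len(pops) != 3:
        raise ValueError(f"need exactly 3 populations, got {len(pops)}")
    pops = tuple(pops)
    vals: dict[str, float] = {}

    freqs = {}
    counts = {}
    for p in pops:
        alt, tot = gm.allele_counts(p)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        freqs[p] = f
        counts[p] = tot
        ok = ~np.isnan(f)
        fo = f[ok]
        maf = np.minimum(fo, 1 - fo)
        he = 2 * fo * (1 - fo)
        vals[f"ppoly_{p}"] = float((maf > 0).mean()) if fo.size else 0.0
        vals[f"he_mean_{p}"] = float(he.mean()) if fo.size else 0.0
        vals[f"he_var_{p}"] = float(he.var()) if fo.size else 0.0
        vals[f"maf_mean_{p}"] = float(maf.mean()) if fo.size else 0.0

    pairs = [(0, 1), (0, 2), (1, 2)]
    for i, j in pairs:
        pi, pj = pops[i], pops[j]
        num, den = _wc_components_pair(gm.calls[gm.pop_indices(pi)],
                                       gm.calls[gm.pop_indices(pj)])
        theta = _theta_from_components(num, den)
        ok = np.isfinite(theta)
        vals[f"fst_{pi}_{pj}"] = float(theta) if ok else 0.0
        vals[f"fst_{pi}_{pj}_ok"] = float(ok)
        both = ~np.isnan(freqs[pi]) & ~np.isnan(freqs[pj])
        f1, f2_ = freqs[pi][both], freqs[pj][both]
        c1 = counts[pi][both].astype(float)
        c2 = counts[pj][both].astype(float)
        jxy = np.mean(f1 * f2_ + (1 - f1) * (1 - f2_))
        jx = np.mean(f1 ** 2 + (1 - f1) ** 2)
        jy = np.mean(f2_ ** 2 + (1 - f2_) ** 2)
        ident = jxy / math.sqrt(jx * jy) if jx > 0 and jy > 0 else 1.0
        vals[f"neid_{pi}_{pj}"] = -math.log(min(ident, 1.0)) if ident > 0 else 0.0
        # bias-corrected f2 (Patterson): subtract sampling variance terms
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (f1 * (1 - f1) / np.maximum(c1 - 1, 1)
                    + f2_ * (1 - f2_) / np.maximum(c2 - 1, 1))
        vals[f"f2_{pi}_{pj}"] = float(np.mean((f1 - f2_) ** 2 - corr)) \
            if both.any() else 0.0

    for t in range(3):
        a, b = [x for x in range(3) if x != t]
        pt, pa, pb = pops[t], pops[a], pops[b]
        shared = (~np.isnan(freqs[pt]) & ~np.isnan(freqs[pa])
                  & ~np.isnan(freqs[pb]))
        ft, fa, fb = (freqs[p][shared] for p in (pt, pa, pb))
        ct = counts[pt][shared].astype(float)
        if shared.any():
            corr_t = ft * (1 - ft) / np.maximum(ct - 1, 1)
            vals[f"f3_{pt}"] = float(np.mean((ft - fa) * (ft - fb) - corr_t))
            den = float(np.sum((fa - fb) ** 2))
            if den > 0:
                alpha = float(np.sum((ft - fb) * (fa - fb)) / den)
                vals[f"alpha_{pt}"] = float(np.clip(alpha, -0.5, 1.5))
                vals[f"alpha_{pt}_ok"] = 1.0
            else:
                vals[f"alpha_{pt}"] = 0.0
                vals[f"alpha_{pt}_ok"] = 0.0
        else:
            vals[f"f3_{pt}"] = 0.0
            vals[f"alpha_{pt}"] = 0.0
            vals[f"alpha_{pt}_ok"] = 0.0

    names = summary_names(pops)
    return pd.Series([vals[n] for n in names], index=names)


# ----------------------------------------------------------------------
# reference table
# ----------------------------------------------------------------------
@dataclass
class ReferenceTable:
    summaries: pd.DataFrame          # one row per simulation
    params: pd.DataFrame             # ScenarioParameters fields
    scenario_ids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def subset(self, scenario_id: int) -> "ReferenceTable":
        mask = self.scenario_ids == scenario_id
        return ReferenceTable(self.summaries[mask].reset_index(drop=True),
                              self.params[mask].reset_index(drop=True),
                              self.scenario_ids[mask], dict(self.provenance))


def build_reference_table(scenarios: dict[int, InvasionScenario],
                          prior: PriorSpec, n_per_scenario: int,
                          samples: dict[str, int], cfg: SimulationConfig,
                          seed: int | None = None, n_loci: int = 200,
                          ) -> ReferenceTable:
    """Simulate the ABC training table: prior draw -> scenario -> summaries.

    Rows are shuffled with a recorded permutation; individual simulation
    failures are skipped and logged, but more than 1% failures aborts.
    """
    rng = np.random.default_rng(seed)
    rows, prows, sids = [], [], []
    failures = 0
    total = len(scenarios) * n_per_scenario
    for sid in sorted(scenarios):
        draws = sample_priors(prior, n_per_scenario,
                              seed=int(rng.integers(2**31 - 1)))
        for params in draws:
            try:
                gm = simulate_scenario(scenarios[sid], params, cfg, samples,
                                       n_loci,
                                       seed=int(rng.integers(2**31 - 1)))
                rows.append(summary_statistics(gm))
            except Exception:
                failures += 1
                if failures > max(1, 0.01 * total):
                    raise RuntimeError(
                        f"more than 1% of simulations failed ({failures})")
                continue
            prows.append(params.as_dict())
            sids.append(sid)
    perm = rng.permutation(len(rows))
    summaries = pd.DataFrame(rows).iloc[perm].reset_index(drop=True)
    params_df = pd.DataFrame(prows).iloc[perm].reset_index(drop=True)
    return ReferenceTable(
        summaries, params_df, np.asarray(sids)[perm],
        provenance={"seed": seed, "n_per_scenario": n_per_scenario,
                    "n_loci": n_loci, "samples": dict(samples),
                    "failures": failures, "permutation_recorded": True})


# ----------------------------------------------------------------------
# scenario choice
# ----------------------------------------------------------------------
@dataclass
class ScenarioChoice:
    votes: dict[int, int]
    selected: int
    posterior_probability: float
    global_error: float
    local_error: float
    n_trees: int


def classify_scenario(rt: ReferenceTable, observed: pd.Series,
                      n_trees: int = 500, seed: int | None = None
                      ) -> ScenarioChoice:
    """Random-forest scenario choice with OOB-based error estimates.

    ``global_error`` is the overall OOB misclassification rate;
    ``local_error`` is the prediction, at the observed vector, of a
    regression forest trained on each training row's OOB
    misclassification indicator; the selected scenario's posterior
    probability is 1 - local_error by construction.
    """
    if len(np.unique(rt.scenario_ids)) < 2:
        raise ValueError("reference table needs >= 2 scenarios")
    if list(observed.index) != list(rt.summaries.columns):
        raise ValueError("observed vector names do not match reference table")
    X = rt.summaries.to_numpy()
    y = rt.scenario_ids
    # canonical sort: forest output is then invariant to row permutations
    order = np.lexsort(tuple(X.T) + (y,))
    X, y = X[order], y[order]
    clf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                 oob_score=True, random_state=seed, n_jobs=1)
    clf.fit(X, y)
    obs = observed.to_numpy()[None, :]
    classes = clf.classes_
    # individual forest trees predict encoded class indices, not labels
    tree_votes = classes[np.array([int(t.predict(obs)[0])
                                   for t in clf.estimators_])]
    votes = {int(c): int((tree_votes == c).sum()) for c in classes}
    selected = int(max(votes, key=votes.get))

    oob = clf.oob_decision_function_
    have = ~np.isnan(oob).any(axis=1)
    oob_pred = classes[np.nanargmax(np.where(np.isnan(oob), -1, oob), axis=1)]
    mis = (oob_pred != y).astype(float)
    global_error = float(mis[have].mean())
    # the misclassification-rate regression needs far fewer, smoother
    # trees than the vote forest; capping it keeps large tables tractable
    reg = RandomForestRegressor(n_estimators=min(200, n_trees),
                                min_samples_leaf=5, random_state=seed,
                                n_jobs=1)
    reg.fit(X[have], mis[have])
    local_error = float(np.clip(reg.predict(obs)[0], 0.0, 1.0))
    return ScenarioChoice(votes=votes, selected=selected,
                          posterior_probability=1.0 - local_error,
                          global_error=global_error, local_error=local_error,
                          n_trees=n_trees)


def lda_projection(rt: ReferenceTable, observed: pd.Series
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """First two linear-discriminant axes of the reference table
    (scenario as class), with training rows and the observed vector
    projected; returns (training coordinates + scenario, observed point)."""
    if len(np.unique(rt.scenario_ids)) < 3:
        raise ValueError("need >= 3 scenarios for two discriminant axes")
    lda = LinearDiscriminantAnalysis(n_components=2)
    coords = lda.fit_transform(rt.summaries.to_numpy(), rt.scenario_ids)
    df = pd.DataFrame(coords, columns=["LD1", "LD2"])
    df["scenario"] = rt.scenario_ids
    obs = lda.transform(observed.to_numpy()[None, :])[0]
    return df, obs


# ----------------------------------------------------------------------
# parameter estimation
# ----------------------------------------------------------------------
@dataclass
class ParamEstimate:
    name: str
    mean: float
    median: float
    q05: float
    q95: float
    nmae_global: float
    nmae_local: float
    zero_variance: bool = False


def _weighted_quantile(y: np.ndarray, w: np.ndarray, qs: list[float]
                       ) -> list[float]:
    order = np.argsort(y)
    y, w = y[order], w[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return [float(np.interp(q, cw, y)) for q in qs]


def estimate_parameters(rt_selected: ReferenceTable,
                        observed: pd.Series | pd.DataFrame,
                        n_trees: int = 500, seed: int | None = None,
                        parameters: list[str] | None = None):
    """Quantile-forest parameter estimation on one scenario's rows.

    One regression forest per parameter; leaf co-occurrence weights with
    the observed vector give the posterior median / 5-95% quantiles and
    the locally-weighted NMAE; the global NMAE averages |oob - true|/true
    over the training rows.  ``observed`` may be a single summary vector
    (returns ``{name: ParamEstimate}``) or a DataFrame of vectors
    (returns a list of such dicts, one per row, reusing each forest).
    """
    if len(np.unique(rt_selected.scenario_ids)) != 1:
        raise ValueError("reference table must contain a single scenario")
    single = isinstance(observed, pd.Series)
    obs_df = observed.to_frame().T if single else observed
    X = rt_selected.summaries.to_numpy()
    P = rt_selected.params
    order = np.lexsort(tuple(X.T))
    X = X[order]
    obs = obs_df.to_numpy()
    results: list[dict[str, ParamEstimate]] = [dict() for _ in range(len(obs))]
    names = parameters or [c for c in P.columns]
    for k, name in enumerate(names):
        y = P[name].to_numpy(float)[order]
        if np.allclose(y, y[0]):
            for res in results:
                res[name] = ParamEstimate(name, float(y[0]), float(y[0]),
                                          float(y[0]), float(y[0]), 0.0, 0.0,
                                          zero_variance=True)
            continue
        rf = RandomForestRegressor(n_estimators=n_trees, oob_score=True,
                                   random_state=None if seed is None
                                   else seed + k, n_jobs=1)
        rf.fit(X, y)
        points = rf.predict(obs)
        leaves = rf.apply(X)
        obs_leaves = rf.apply(obs)
        oob_pred = rf.oob_prediction_
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(oob_pred - y) / np.abs(y)
        ok = np.isfinite(rel)
        nmae_g = float(rel[ok].mean())
        # per-tree leaf sizes, shared across observed vectors
        for m, res in enumerate(results):
            w = np.zeros(len(y))
            for t in range(leaves.shape[1]):
                match = leaves[:, t] == obs_leaves[m, t]
                n_in = match.sum()
                if n_in:
                    w[match] += 1.0 / n_in
            w /= leaves.shape[1]
            med, q05, q95 = _weighted_quantile(y, w, [0.5, 0.05, 0.95])
            wn = w[ok] / max(w[ok].sum(), 1e-300)
            nmae_l = float(np.sum(wn * rel[ok]))
            res[name] = ParamEstimate(name, float(points[m]), med, q05, q95,
                                      nmae_g, nmae_l)
    return results[0] if single else results
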