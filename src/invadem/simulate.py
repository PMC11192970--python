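"""Coalescent simulation of single-population size histories and
multi-deme invasion scenarios.

The simulator works backward in time on a set of demes with
piecewise-constant diploid effective sizes.  Three single-population
models describe a population's size history:

``constant``
    one size ``N_CON`` at all times;
``bottleneck``
    ``N_CON`` today, switching to an ancient size ``N_ANC`` further back
    than ``T_ENDBOT`` generations;
``bottleneck_rebound``
    ``N_CON`` today, a transient size ``N_BOT`` between ``T_BOT`` and
    ``T_ENDBOT`` generations ago, and ``N_ANC`` before that.

Invasion scenarios place three sampled demes (pop1-pop3), up to three
unsampled "ghost" source demes, and a native-range ancestor on a
backward-time event list of splits and admixture pulses, parameterized by
introduction/divergence times (ti > td > td1), a native divergence time
ta, and per-deme sizes N1-N6 / Na_anc.  Scenario topologies live in
``data/scenarios.yaml`` so they can be revised without code changes.

SNP loci are unlinked: each locus is an independent genealogy.  Under
``segregating`` ascertainment one biallelic SNP is emitted per locus,
simulated conditional on the locus segregating in the pooled sample
(length-biased genealogy acceptance), optionally with a pooled
minor-allele-frequency floor to emulate a filtered RAD SNP panel.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.linalg import expm
from scipy.special import gammaln

from . import _coalescent as _ck
from .matrix import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "DemographicModel",
    "ScenarioParameters",
    "InvasionScenario",
    "PriorSpec",
    "default_prior_spec",
    "load_scenarios",
    "sample_priors",
    "simulate_single_pop",
    "simulate_scenario",
    "simulate_custom",
    "expected_folded_sfs",
]

# deme indices used by the scenario encodings
DEME_INDEX = {"pop1": 0, "pop2": 1, "pop3": 2,
              "ghost4": 3, "ghost5": 4, "ghost6": 5, "anc": 6}
SAMPLED_DEMES = ("pop1", "pop2", "pop3")

# default expected mutations per retained genealogy under SNP
# ascertainment; small enough that length-biased acceptance stays accurate
# (residual bias on class proportions is O(x), well below Monte-Carlo
# noise at x = 0.1), large enough that the acceptance rate remains
# workable (~10%).  Throughput-critical callers that only need
# self-consistency (e.g. ABC reference tables) may raise it.
_ASCERTAIN_X = 0.1


# ----------------------------------------------------------------------
# configuration / parameter types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SimulationConfig:
    """Mutation model and SNP ascertainment settings.

    ``mutation_rate`` is the per-site per-generation mutation probability
    (default 7e-9, an Arabidopsis-derived plant rate) and
    ``locus_length`` the number of base pairs per RAD locus.  One
    generation is one year for this annual-flowering perennial weed;
    ``generation_time`` only matters when converting to calendar years.
    ``ascertainment`` is ``"none"`` (Poisson infinite-sites mutations,
    zero or several SNPs per locus), ``"segregating"`` (exactly one SNP
    per locus, conditioned on segregating), or a float in [0, 0.5)
    interpreted as a pooled-MAF retention threshold on top of
    ``"segregating"``.
    """

    mutation_rate: float = 7e-9
    locus_length: int = 150
    generation_time: float = 1.0
    ascertainment: str | float = "segregating"
    snp_intensity: float = _ASCERTAIN_X
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be > 0")
        if not 0 < self.snp_intensity < 2:
            raise ValueError("snp_intensity must be in (0, 2)")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")
        if isinstance(self.ascertainment, float) and not (
                0.0 <= self.ascertainment < 0.5):
            raise ValueError("MAF ascertainment threshold must be in [0, 0.5)")
        if isinstance(self.ascertainment, str) and self.ascertainment not in (
                "none", "segregating"):
            raise ValueError("ascertainment must be 'none', 'segregating' or a MAF float")


@dataclass(frozen=True)
class DemographicModel:
    """Single-population piecewise-constant size history (see module docs)."""

    model_id: str
    N_CON: float
    N_ANC: float | None = None
    N_BOT: float | None = None
    T_BOT: float | None = None
    T_ENDBOT: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in ("constant", "bottleneck", "bottleneck_rebound"):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.N_CON < 1:
            raise ValueError("sizes must be >= 1")
        if self.model_id == "bottleneck":
            if self.N_ANC is None or self.T_ENDBOT is None:
                raise ValueError("bottleneck needs N_ANC and T_ENDBOT")
            if self.N_ANC < 1 or self.T_ENDBOT <= 0:
                raise ValueError("invalid bottleneck parameters")
        if self.model_id == "bottleneck_rebound":
            if None in (self.N_ANC, self.N_BOT, self.T_BOT, self.T_ENDBOT):
                raise ValueError("bottleneck_rebound needs N_ANC, N_BOT, T_BOT, T_ENDBOT")
            if not (0 < self.T_BOT < self.T_ENDBOT):
                raise ValueError("need 0 < T_BOT < T_ENDBOT")
            if self.N_ANC < 1 or self.N_BOT < 1:
                raise ValueError("sizes must be >= 1")

    @property
    def k_params(self) -> int:
        """Nominal parameter count (contemporary size included)."""
        return {"constant": 1, "bottleneck": 3, "bottleneck_rebound": 5}[self.model_id]

    def epochs(self) -> list[tuple[float, float]]:
        """(start_time_ago, diploid_size) pieces, most recent first."""
        if self.model_id == "constant":
            return [(0.0, self.N_CON)]
        if self.model_id == "bottleneck":
            return [(0.0, self.N_CON), (float(self.T_ENDBOT), float(self.N_ANC))]
        return [(0.0, self.N_CON), (float(self.T_BOT), float(self.N_BOT)),
                (float(self.T_ENDBOT), float(self.N_ANC))]

    def size_change_events(self, deme: int = 0) -> list[tuple]:
        evs = []
        for t, size in self.epochs()[1:]:
            evs.append((t, _ck.KIND_SIZE, deme, 0, 0, size))
        return evs


@dataclass(frozen=True)
class ScenarioParameters:
    """Times (generations) and diploid sizes parameterizing a scenario."""

    ti: float
    td: float
    td1: float
    ta: float
    N1: float
    N2: float
    N3: float
    N4: float
    N5: float = 1000.0
    N6: float = 1000.0
    Na_anc: float = 10000.0
    r: float = 0.5  # admixture proportion toward the first-listed donor

    def __post_init__(self) -> None:
        if not (self.ti > self.td > self.td1 > 0):
            raise ValueError("need ti > td > td1 > 0")
        if self.ta <= 0:
            raise ValueError("ta must be > 0")
        sizes = (self.N1, self.N2, self.N3, self.N4, self.N5, self.N6, self.Na_anc)
        if any(s < 1 for s in sizes):
            raise ValueError("all sizes must be >= 1")
        if not (0.0 < self.r < 1.0):
            raise ValueError("admixture proportion r must be in (0,1)")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PARAM_NAMES}


PARAM_NAMES = ("ti", "td", "td1", "ta", "N1", "N2", "N3", "N4", "N5", "N6",
               "Na_anc", "r")


@dataclass(frozen=True)
class InvasionScenario:
    """Backward-time event list over demes pop1-3, ghost4-6 and ``anc``."""

    scenario_id: int
    events: tuple  # of (time_symbol, kind, args...) dicts, see scenarios.yaml

    def __post_init__(self) -> None:
        if not (1 <= self.scenario_id <= 9):
            raise ValueError("scenario_id must be in 1..9")
        for ev in self.events:
            if ev["kind"] not in ("split", "admixture"):
                raise ValueError(f"unknown event kind {ev['kind']!r}")
            for key in ("from", "to") if ev["kind"] == "split" else ("from",):
                if ev[key] not in DEME_INDEX:
                    raise ValueError(f"unknown deme {ev[key]!r}")
            if ev["kind"] == "admixture":
                if len(ev["donors"]) != 2 or any(d not in DEME_INDEX for d in ev["donors"]):
                    raise ValueError("admixture needs two known donor demes")
            if ev["time"] not in ("ti", "td", "td1", "ta"):
                raise ValueError(f"unknown time symbol {ev['time']!r}")

    def concrete_events(self, params: ScenarioParameters) -> list[tuple]:
        """Resolve symbols into kernel event tuples, sorted by time (stable)."""
        out = []
        for ev in self.events:
            t = float(getattr(params, ev["time"]))
            if ev["kind"] == "split":
                out.append((t, _ck.KIND_SPLIT, DEME_INDEX[ev["from"]],
                            DEME_INDEX[ev["to"]], 0, 0.0))
            else:
                a, b = (DEME_INDEX[d] for d in ev["donors"])
                out.append((t, _ck.KIND_ADMIX, DEME_INDEX[ev["from"]], a, b,
                            float(params.r)))
        out.sort(key=lambda e: e[0])
        return out

    def validate(self, params: ScenarioParameters) -> None:
        """Check every sampled deme's lineages can reach the ancestor."""
        evs = self.concrete_events(params)
        # forward-simulate deme reachability deterministically: a lineage in
        # an admixed deme may end up in either donor, so track sets.
        current: dict[int, set[int]] = {DEME_INDEX[d]: {DEME_INDEX[d]}
                                        for d in SAMPLED_DEMES}
        for t, kind, a, b, c, _r in evs:
            for start, where in current.items():
                if kind == _ck.KIND_SPLIT and a in where:
                    where.discard(a)
                    where.add(b)
                elif kind == _ck.KIND_ADMIX and a in where:
                    where.discard(a)
                    where.update((b, c))
        anc = DEME_INDEX["anc"]
        for start, where in current.items():
            if where != {anc}:
                raise ValueError(
                    f"scenario {self.scenario_id}: lineages sampled in deme "
                    f"{start} do not all reach the native ancestor ({where})")

    def deme_sizes(self, params: ScenarioParameters) -> np.ndarray:
        return np.array([params.N1, params.N2, params.N3, params.N4,
                         params.N5, params.N6, params.Na_anc], dtype=np.float64)


def load_scenarios() -> dict[int, InvasionScenario]:
    """The nine default invasion-scenario topologies."""
    text = (importlib.resources.files("invadem") / "data" / "scenarios.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for sid, spec in raw["scenarios"].items():
        out[int(sid)] = InvasionScenario(scenario_id=int(sid),
                                         events=tuple(spec["events"]))
    return out


# ----------------------------------------------------------------------
# priors
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform bounds plus strict order constraints.

    ``order`` lists (larger, smaller) name pairs; draws violating any
    constraint are rejected, which preserves the marginal bounds.
    """

    bounds: dict[str, tuple[float, float]]
    order: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bound for {name!r} must have lower < upper")
        # cycle check on the constraint digraph
        graph = {n: set() for pair in self.order for n in pair}
        for big, small in self.order:
            if big not in self.bounds or small not in self.bounds:
                raise ValueError("order constraints must reference bounded parameters")
            graph[big].add(small)
        seen: dict[str, int] = {}

        def visit(u: str) -> None:
            seen[u] = 1
            for v in graph[u]:
                if seen.get(v) == 1:
                    raise ValueError("order constraints contain a cycle")
                if v not in seen:
                    visit(v)
            seen[u] = 2

        for u in graph:
            if u not in seen:
                visit(u)


def default_prior_spec() -> PriorSpec:
    """Study priors: sizes 100-100,000; ti > td > td1 in [10, 60]; ta in [101, 10,000]."""
    bounds = {name: (100.0, 100_000.0)
              for name in ("N1", "N2", "N3", "N4", "N5", "N6", "Na_anc")}
    bounds.update(ti=(10.0, 60.0), td=(10.0, 60.0), td1=(10.0, 60.0),
                  ta=(101.0, 10_000.0), r=(0.05, 0.95))
    return PriorSpec(bounds=bounds, order=(("ti", "td"), ("td", "td1")))


def sample_priors(spec: PriorSpec, n: int, seed: int | None = None
                  ) -> list[ScenarioParameters]:
    """Draw i.i.d. parameter sets from the truncated uniform prior (rejection)."""
    rng = np.random.default_rng(seed)
    names = list(spec.bounds)
    out: list[ScenarioParameters] = []
    tries = 0
    max_tries = max(200_000, 2000 * max(n, 1))
    while len(out) < n:
        if tries >= max_tries:
            raise RuntimeError("prior constraint region appears infeasible "
                               f"({len(out)}/{n} draws in {tries} attempts)")
        tries += 1
        draw = {nm: rng.uniform(*spec.bounds[nm]) for nm in names}
        if any(draw[big] <= draw[small] for big, small in spec.order):
            continue
        defaults = {"N5": 1000.0, "N6": 1000.0, "Na_anc": 10_000.0, "r": 0.5}
        kwargs = {k: draw.get(k, defaults.get(k)) for k in PARAM_NAMES}
        out.append(ScenarioParameters(**kwargs))
    return out


# ----------------------------------------------------------------------
# simulation wrappers
# ----------------------------------------------------------------------
def _events_to_arrays(events: list[tuple]) -> tuple:
    m = len(events)
    ev_time = np.array([e[0] for e in events], dtype=np.float64)
    ev_kind = np.array([e[1] for e in events], dtype=np.int64)
    ev_a = np.array([e[2] for e in events], dtype=np.int64)
    ev_b = np.array([e[3] for e in events], dtype=np.int64)
    ev_c = np.array([e[4] for e in events], dtype=np.int64)
    ev_r = np.array([e[5] for e in events], dtype=np.float64)
    if m == 0:
        ev_time = np.zeros(0); ev_kind = np.zeros(0, np.int64)
        ev_a = np.zeros(0, np.int64); ev_b = np.zeros(0, np.int64)
        ev_c = np.zeros(0, np.int64); ev_r = np.zeros(0)
    return ev_time, ev_kind, ev_a, ev_b, ev_c, ev_r


def simulate_custom(sample_deme: np.ndarray, deme_sizes: np.ndarray,
                    events: list[tuple], n_loci: int, cfg: SimulationConfig,
                    individual_pops: list[str], seed: int | None = None,
                    coords: dict | None = None) -> GenotypeMatrix:
    """Simulate a SNP matrix for an arbitrary deme layout and event list.

    ``sample_deme`` assigns each gene copy (2 per individual, adjacent) to a
    deme index; ``individual_pops`` labels the resulting individuals.
    """
    if len(sample_deme) != 2 * len(individual_pops):
        raise ValueError("sample_deme must list 2 gene copies per individual")
    rng = np.random.default_rng(seed)
    _ck.seed_kernel_rng(int(rng.integers(2**31 - 1)))
    arrs = _events_to_arrays(sorted(events, key=lambda e: e[0]))
    sd = np.asarray(sample_deme, dtype=np.int64)
    sizes = np.asarray(deme_sizes, dtype=np.float64)
    n_ind = len(individual_pops)

    if n_loci == 0:
        calls = np.zeros((n_ind, 0), np.int8)
        return GenotypeMatrix(calls, [f"ind{i}" for i in range(n_ind)], [],
                              list(individual_pops), coords or {})

    if cfg.ascertainment == "none":
        lam = cfg.mutation_rate * cfg.locus_length
        lens = _ck.sim_tree_lengths(sd, sizes, *arrs, 64)
        if lens[0] < 0:
            raise RuntimeError("lineages cannot reach a common ancestor")
        cap = int(max(64, n_loci * max(4 * lam * lens.mean(), 0.5)))
        while True:
            dos, counts, status = _ck.sim_poisson_mutations(
                sd, sizes, *arrs, n_loci, lam, cap)
            if status == -1:
                raise RuntimeError("lineages cannot reach a common ancestor")
            if status == 0:
                break
            cap *= 4
        n_snp = int(counts.sum())
        calls = dos[:n_snp].T.copy()
        locus_ids = [f"L{i}_{j}" for i, c in enumerate(counts) for j in range(c)]
    else:
        if len(sd) < 2:
            raise ValueError("SNP ascertainment impossible with < 2 gene copies")
        lens = _ck.sim_tree_lengths(sd, sizes, *arrs, 64)
        if lens[0] < 0:
            raise RuntimeError("lineages cannot reach a common ancestor")
        lam = cfg.snp_intensity / float(np.mean(lens))
        maf = float(cfg.ascertainment) if isinstance(cfg.ascertainment, float) else 0.0
        max_tries = max(10_000, 500 * n_loci)
        dos, status = _ck.sim_snp_dosages(sd, sizes, *arrs, n_loci, lam, maf,
                                          max_tries)
        if status == -1:
            raise RuntimeError("lineages cannot reach a common ancestor")
        if status == -2:
            raise RuntimeError("SNP retention quota not met; ascertainment too strict")
        calls = dos.T.copy()
        locus_ids = [f"L{i}" for i in range(n_loci)]

    return GenotypeMatrix(calls, [f"ind{i}" for i in range(n_ind)], locus_ids,
                          list(individual_pops), coords or {})


def simulate_single_pop(model: DemographicModel, cfg: SimulationConfig,
                        n_ind: int, n_loci: int, seed: int | None = None,
                        pop_name: str = "pop1") -> GenotypeMatrix:
    """Genotypes for one population under a piecewise-constant size history."""
    if n_ind < 2:
        raise ValueError("need at least 2 individuals")
    sample_deme = np.zeros(2 * n_ind, dtype=np.int64)
    sizes = np.array([model.N_CON], dtype=np.float64)
    events = model.size_change_events(deme=0)
    return simulate_custom(sample_deme, sizes, events, n_loci, cfg,
                           [pop_name] * n_ind, seed=seed)


def simulate_scenario(scn: InvasionScenario, params: ScenarioParameters,
                      cfg: SimulationConfig, samples: dict[str, int],
                      n_loci: int, seed: int | None = None) -> GenotypeMatrix:
    """Genotypes for the sampled demes of an invasion scenario."""
    bad = set(samples) - set(SAMPLED_DEMES)
    if bad:
        raise ValueError(f"only demes {SAMPLED_DEMES} can be sampled, got {bad}")
    scn.validate(params)
    sample_deme = []
    pops = []
    for name in SAMPLED_DEMES:
        for _ in range(samples.get(name, 0)):
            sample_deme.extend([DEME_INDEX[name]] * 2)
            pops.append(name)
    return simulate_custom(np.array(sample_deme, dtype=np.int64),
                           scn.deme_sizes(params), scn.concrete_events(params),
                           n_loci, cfg, pops, seed=seed)


# ----------------------------------------------------------------------
# expected folded SFS
# ----------------------------------------------------------------------
def _expected_level_times(model: DemographicModel, n: int) -> np.ndarray:
    """E[time with k lineages] in generations, for k = 2..n (index k-2).

    Works in rescaled time tau = integral dt / (4 N(t)), where the lineage
    count is a homogeneous pure-death chain with rates k(k-1); occupancy
    integrals per epoch come from solving the linear ODE system exactly.
    """
    epochs = model.epochs()
    n_states = n - 1  # k = n..2
    A = np.zeros((n_states, n_states))
    for k in range(2, n + 1):
        i = n - k  # row index of state k
        A[i, i] = -k * (k - 1)
        if k >= 3:
            A[i + 1, i] = k * (k - 1)
    p = np.zeros(n_states)
    p[0] = 1.0  # start with n lineages
    occ_total = np.zeros(n_states)
    E_T = np.zeros(n_states)
    for e, (t_start, size) in enumerate(epochs):
        if e + 1 < len(epochs):
            dtau = (epochs[e + 1][0] - t_start) / (4.0 * size)
            p_next = expm(A * dtau) @ p
            occ = np.linalg.solve(A, p_next - p)
        else:
            p_next = np.zeros(n_states)
            occ = np.linalg.solve(A, p_next - p)
        E_T += 4.0 * size * occ
        p = p_next
    # reorder to k = 2..n
    return E_T[::-1]


def _log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def expected_folded_sfs(model: DemographicModel, n_copies: int,
                        mode: str = "analytic", n_loci: int = 100_000,
                        cfg: SimulationConfig | None = None,
                        seed: int | None = None) -> np.ndarray:
    """Expected folded class proportions over minor-allele counts 1..n/2.

    The monomorphic class is excluded and proportions sum to 1.  Analytic
    mode combines expected inter-coalescent times under the size history
    with the classical branch-subtending probabilities
    ``P(i of n | k) = C(n-i-1, k-2) / C(n-1, k-1)``; Monte-Carlo mode
    averages folded spectra of simulated SNPs.
    """
    if n_copies < 4 or n_copies % 2:
        raise ValueError("n_copies must be an even number >= 4 (diploid sampling)")
    n = n_copies
    if mode == "analytic":
        E_T = _expected_level_times(model, n)  # k = 2..n
        ks = np.arange(2, n + 1, dtype=float)
        i_arr = np.arange(1, n, dtype=float)
        # xi[i] = sum_k k * E[T_k] * C(n-i-1, k-2)/C(n-1, k-1)
        K, I = np.meshgrid(ks, i_arr)
        valid = (n - I - 1) >= (K - 2)
        with np.errstate(invalid="ignore"):
            logp = _log_comb(n - I - 1, K - 2) - _log_comb(
                np.full_like(K, n - 1.0), K - 1)
        term = np.where(valid, np.exp(logp), 0.0) * K * E_T[None, :]
        xi = term.sum(axis=1)
        half = n // 2
        folded = np.empty(half)
        for j in range(1, half + 1):
            folded[j - 1] = xi[j - 1] if 2 * j == n else xi[j - 1] + xi[n - j - 1]
        return folded / folded.sum()
    if mode == "monte_carlo":
        cfg = cfg or SimulationConfig()
        cfg = replace(cfg, ascertainment="segregating")
        gm = simulate_single_pop(model, cfg, n // 2, n_loci, seed=seed)
        alt = gm.calls.sum(axis=0)
        minor = np.minimum(alt, n - alt)
        counts = np.bincount(minor, minlength=n // 2 + 1)[1:]
        return counts / counts.sum()
    raise ValueError("mode must be 'analytic' or 'monte_carlo'")
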