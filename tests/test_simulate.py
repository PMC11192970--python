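"""Coalescent simulator: priors, spectra, scenarios, determinism."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from invadem import (DemographicModel, PriorSpec, ScenarioParameters,
                     SimulationConfig, default_prior_spec, expected_folded_sfs,
                     load_scenarios, sample_priors, simulate_scenario,
                     simulate_single_pop)
from invadem.stats import pairwise_fst


# ----------------------------------------------------------------------
# priors
# ----------------------------------------------------------------------
def test_prior_draws_satisfy_bounds_and_order():
    spec = default_prior_spec()
    draws = sample_priors(spec, 100_000, seed=1)
    ti = np.array([d.ti for d in draws])
    td = np.array([d.td for d in draws])
    td1 = np.array([d.td1 for d in draws])
    assert ((ti > td) & (td > td1)).all()
    for name, (lo, hi) in spec.bounds.items():
        v = np.array([getattr(d, name) for d in draws])
        assert v.min() >= lo and v.max() <= hi


def test_prior_empty_and_mean():
    spec = default_prior_spec()
    assert sample_priors(spec, 0, seed=1) == []
    draws = sample_priors(spec, 10_000, seed=2)
    n1 = np.array([d.N1 for d in draws])
    se = (100_000 - 100) / np.sqrt(12) / np.sqrt(n1.size)
    assert abs(n1.mean() - 50_050) < 3 * se


def test_prior_infeasible_region_errors():
    spec = PriorSpec(bounds={"ti": (1.0, 2.0), "td": (5.0, 6.0),
                             "td1": (0.1, 0.5), "ta": (101.0, 200.0),
                             "N1": (100.0, 200.0), "N2": (100.0, 200.0),
                             "N3": (100.0, 200.0), "N4": (100.0, 200.0)},
                     order=(("ti", "td"),))  # ti < 2 can never exceed td > 5
    with pytest.raises(RuntimeError):
        sample_priors(spec, 5, seed=3)


def test_prior_cycle_detection():
    with pytest.raises(ValueError, match="cycle"):
        PriorSpec(bounds={"a": (0, 1), "b": (0, 1)},
                  order=(("a", "b"), ("b", "a")))


# ----------------------------------------------------------------------
# single-population coalescent
# ----------------------------------------------------------------------
def test_watterson_and_pairwise_diversity():
    """Constant size: segregating sites match theta*a_n, pi matches theta."""
    N, n_ind, L = 1000, 10, 20_000
    cfg = SimulationConfig(mutation_rate=7e-9, locus_length=150,
                           ascertainment="none")
    model = DemographicModel("constant", N_CON=N)
    gm = simulate_single_pop(model, cfg, n_ind, L, seed=42)
    theta = 4 * N * cfg.mutation_rate * cfg.locus_length
    n = 2 * n_ind
    a_n = sum(1.0 / i for i in range(1, n))
    # segregating sites per locus
    s_tot = gm.n_loci
    exp_s = theta * a_n * L
    assert abs(s_tot - exp_s) < 3 * np.sqrt(exp_s)
    # mean pairwise diversity per locus (sum over SNPs of 2p(1-p)*n/(n-1))
    p = gm.calls.sum(axis=0) / n
    pi_tot = np.sum(2 * p * (1 - p) * n / (n - 1))
    se = theta * np.sqrt(L) / L * 3  # crude MC scale; pi variance ~ theta^2
    assert abs(pi_tot / L - theta) < max(3 * pi_tot / L / np.sqrt(s_tot), se)


def test_empty_locus_request():
    cfg = SimulationConfig()
    gm = simulate_single_pop(DemographicModel("constant", N_CON=100), cfg, 3, 0)
    assert gm.n_loci == 0 and gm.n_individuals == 3


def test_rebound_with_flat_sizes_matches_constant():
    """N_BOT = N_ANC = N_CON degenerates to the constant model's SFS."""
    cfg = SimulationConfig()
    flat = DemographicModel("bottleneck_rebound", N_CON=500, N_ANC=500,
                            N_BOT=500, T_BOT=10, T_ENDBOT=20)
    const = DemographicModel("constant", N_CON=500)
    ok = 0
    reps = 12
    for rep in range(reps):
        spectra = []
        for model, seed in ((flat, rep), (const, 1000 + rep)):
            gm = simulate_single_pop(model, cfg, 8, 1500, seed=seed)
            alt = gm.calls.sum(axis=0)
            minor = np.minimum(alt, 16 - alt)
            spectra.append(np.bincount(minor, minlength=9)[1:])
        _, p, _, _ = chi2_contingency(np.vstack(spectra))
        ok += p > 0.01
    assert ok >= reps - 2


def test_same_seed_bit_identical_different_seed_differs():
    cfg = SimulationConfig()
    m = DemographicModel("constant", N_CON=300)
    a = simulate_single_pop(m, cfg, 5, 40, seed=7)
    b = simulate_single_pop(m, cfg, 5, 40, seed=7)
    c = simulate_single_pop(m, cfg, 5, 40, seed=8)
    assert np.array_equal(a.calls, b.calls)
    assert not np.array_equal(a.calls, c.calls)


def test_maf_ascertainment_respected():
    cfg = SimulationConfig(ascertainment=0.1)
    gm = simulate_single_pop(DemographicModel("constant", N_CON=500), cfg,
                             10, 300, seed=3)
    p = gm.calls.sum(axis=0) / 20
    assert (np.minimum(p, 1 - p) > 0.1).all()


# ----------------------------------------------------------------------
# expected folded SFS
# ----------------------------------------------------------------------
def test_expected_sfs_rejects_odd_or_tiny_n():
    m = DemographicModel("constant", N_CON=100)
    with pytest.raises(ValueError):
        expected_folded_sfs(m, 5)
    with pytest.raises(ValueError):
        expected_folded_sfs(m, 2)


@pytest.mark.parametrize("model", [
    DemographicModel("constant", N_CON=1000),
    DemographicModel("bottleneck", N_CON=100, N_ANC=5000, T_ENDBOT=30),
    DemographicModel("bottleneck_rebound", N_CON=100, N_ANC=2000, N_BOT=20,
                     T_BOT=10, T_ENDBOT=20),
])
def test_expected_sfs_normalized(model):
    for n in (4, 10, 24):
        pi = expected_folded_sfs(model, n)
        assert pi.shape == (n // 2,)
        assert (pi > 0).all()
        assert abs(pi.sum() - 1) < 1e-12


def test_expected_sfs_constant_matches_harmonic_fold():
    """Constant size folds the classical 1/i spectrum for any n."""
    m = DemographicModel("constant", N_CON=777)
    for n in (8, 20, 30):
        xi = 1.0 / np.arange(1, n)
        folded = np.array([xi[j - 1] + (xi[n - j - 1] if 2 * j != n else 0.0)
                           for j in range(1, n // 2 + 1)])
        expect = folded / folded.sum()
        assert np.allclose(expected_folded_sfs(m, n), expect, atol=1e-12)


# ----------------------------------------------------------------------
# invasion scenarios
# ----------------------------------------------------------------------
def test_all_nine_scenarios_instantiable_and_valid():
    scns = load_scenarios()
    assert sorted(scns) == list(range(1, 10))
    params = sample_priors(default_prior_spec(), 1, seed=5)[0]
    for scn in scns.values():
        scn.validate(params)
        gm = simulate_scenario(scn, params,
                               SimulationConfig(snp_intensity=0.4),
                               {"pop1": 4, "pop2": 4, "pop3": 4}, 30,
                               seed=scn.scenario_id)
        assert gm.n_individuals == 12 and gm.n_loci == 30


def test_scenario_rejects_ghost_samples_and_bad_times():
    scns = load_scenarios()
    params = sample_priors(default_prior_spec(), 1, seed=5)[0]
    with pytest.raises(ValueError):
        simulate_scenario(scns[1], params, SimulationConfig(),
                          {"ghost4": 4}, 10)
    with pytest.raises(ValueError):
        ScenarioParameters(ti=10, td=20, td1=5, ta=500,
                           N1=100, N2=100, N3=100, N4=100)


def test_scenario_instant_divergence_gives_no_structure():
    """ti -> 0+ : the three demes are effectively one population."""
    scns = load_scenarios()
    params = ScenarioParameters(ti=0.03, td=0.02, td1=0.01, ta=2000.0,
                                N1=1000, N2=1000, N3=1000, N4=1000)
    thetas = []
    for rep in range(5):
        gm = simulate_scenario(scns[1], params,
                               SimulationConfig(snp_intensity=0.4),
                               {"pop1": 8, "pop2": 8, "pop3": 8}, 300,
                               seed=rep)
        v = pairwise_fst(gm).values.to_numpy()
        thetas.append(v[np.triu_indices(3, 1)].mean())
    assert abs(np.mean(thetas)) < 0.01


def test_deep_sources_inflate_differentiation():
    """Repeated introductions from divergent sources beat a single origin."""
    scns = load_scenarios()
    cfg = SimulationConfig(snp_intensity=0.4)
    kw = dict(N1=500, N2=500, N3=500, N4=10_000, N5=10_000, N6=10_000,
              Na_anc=10_000)
    p1 = ScenarioParameters(ti=50, td=30, td1=15, ta=5000, **kw)
    wins = 0
    reps = 20
    for rep in range(reps):
        fsts = {}
        for sid in (1, 6):
            gm = simulate_scenario(scns[sid], p1, cfg,
                                   {"pop1": 8, "pop2": 8, "pop3": 8}, 150,
                                   seed=1000 * sid + rep)
            v = pairwise_fst(gm).values.to_numpy()
            fsts[sid] = v[np.triu_indices(3, 1)].mean()
        wins += fsts[6] > fsts[1]
    assert wins >= 0.9 * reps
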