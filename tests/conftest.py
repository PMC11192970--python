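import numpy as np
import pytest

from invadem.matrix import GenotypeMatrix
from invadem.synthetic_study import generate_worked_micro


@pytest.fixture(scope="session")
def micro_gm() -> GenotypeMatrix:
    """Seconds-scale 3-population fixture shared across tests."""
    return generate_worked_micro(seed=11)


def wf_genotypes(ne: int, n_sample: int, n_loci: int, gens: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Forward Wright-Fisher diploid population with unlinked loci.

    Random mating without selfing, free recombination; returns dosages
    of ``n_sample`` individuals drawn from the final generation.  Serves
    as an independent (non-coalescent) route for LD-based Ne checks.
    """
    H = (rng.random((ne, 2, n_loci)) < 0.5).astype(np.int8)
    for _ in range(gens):
        mothers = rng.integers(ne, size=ne)
        fathers = (mothers + 1 + rng.integers(ne - 1, size=ne)) % ne
        Hn = np.empty_like(H)
        Hn[:, 0] = np.where(rng.random((ne, n_loci)) < 0.5,
                            H[mothers, 0], H[mothers, 1])
        Hn[:, 1] = np.where(rng.random((ne, n_loci)) < 0.5,
                            H[fathers, 0], H[fathers, 1])
        H = Hn
    idx = rng.choice(ne, n_sample, replace=False)
    return (H[idx, 0] + H[idx, 1]).astype(np.int8)


def as_matrix(calls: np.ndarray, pops: list[str]) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(
        calls,
        [f"i{k}" for k in range(calls.shape[0])],
        [f"L{j}" for j in range(calls.shape[1])],
        list(pops),
    )
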