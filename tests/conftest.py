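import numpy as np
import pytest

from karyoscan import simulate as sim

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply exactly n_subs substitutions at distinct positions."""
    arr = list(seq)
    for i in rng.choice(len(arr), size=n_subs, replace=False):
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_bundle():
    """One shared default simulation (seed 1) for cross-module checks."""
    return sim.run_default_simulation(1)
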