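import logging

import numpy as np
import pytest

from paleoselect.selstats import HaplotypeMatrix

logging.getLogger("paleoselect").setLevel(logging.ERROR)


def random_haplotype_matrix(
    rng: np.random.Generator,
    max_n: int = 12,
    max_sites: int = 30,
    polarised: bool = True,
) -> HaplotypeMatrix:
    """A random binary haplotype matrix with sorted distinct positions."""
    n = int(rng.integers(2, max_n + 1))
    n_sites = int(rng.integers(1, max_sites + 1))
    alleles = rng.integers(0, 2, size=(n, n_sites)).astype(np.int8)
    positions = np.sort(
        rng.choice(np.arange(1, 10 * max_sites + 1), size=n_sites, replace=False)
    )
    return HaplotypeMatrix(alleles, positions, polarised=polarised)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def msprime_sample(n: int, seed: int, theta: float = 10.0, length: int = 10_000):
    """Neutral coalescent haplotype sample plus its tree sequence.

    theta is the population-scaled mutation rate 4*Ne*mu*L for the sample.
    """
    import msprime

    ne = 10_000
    mu = theta / (4 * ne * length)
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=ne,
        sequence_length=length,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts, rate=mu, random_seed=seed + 1,
        model=msprime.BinaryMutationModel(),
    )
    matrix = np.clip(ts.genotype_matrix().T.astype(np.int8), 0, 1)
    positions = np.array([s.position for s in ts.sites()])
    keep = np.concatenate(([True], np.diff(positions) > 0))
    h = HaplotypeMatrix(
        matrix[:, keep], positions[keep].astype(np.int64), polarised=True
    )
    return h, ts
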