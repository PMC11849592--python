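"""Synthetic genotype and haplotype data with ancient-cohort structure.

Two generators cover the two kinds of input the analysis consumes:

* :func:`simulate_admixture_dataset` draws sparse diploid genotype tables for
  two parental populations and a two-way admixed offspring population, with
  optional Wright-Fisher drift after admixture, optional selection on an
  appended focal locus, and independent per-genotype missingness mimicking
  heterogeneous ancient coverage.

* :func:`simulate_haplotypes` runs a forward Wright-Fisher simulation of
  binary haplotypes with infinite-sites mutation, single-crossover
  recombination and genic selection on a focal derived allele, yielding the
  phased, polarised panels the selection scans expect.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from paleoselect.popfreq import MISSING, GenotypeTable
from paleoselect.selstats import HaplotypeMatrix


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the admixture genotype simulation.

    ``admixture_alpha`` is the fraction of offspring ancestry drawn from
    parental population x.  Neutral locus frequencies in the parents are
    drawn uniformly from [0.05, 0.95] — the broad SNP frequency range of a
    typical ascertained panel; the focal locus is appended last with the
    configured starting frequencies.  ``selection_coefficient`` acts on the
    focal locus only, each post-admixture generation, before drift.
    """

    n_parental_x: int = 50
    n_parental_y: int = 50
    n_offspring: int = 50
    admixture_alpha: float = 0.5
    n_loci: int = 1000
    focal_freq_x: float = 0.05
    focal_freq_y: float = 0.15
    drift_generations: int = 0
    effective_size: int = 10_000
    selection_coefficient: float = 0.0
    missingness_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_parental_x, self.n_parental_y, self.n_offspring) < 1:
            raise ValueError("population sizes must be >= 1")
        if not 0 <= self.admixture_alpha <= 1:
            raise ValueError("admixture_alpha must be in [0, 1]")
        for f in (self.focal_freq_x, self.focal_freq_y):
            if not 0 <= f <= 1:
                raise ValueError("focal frequencies must be in [0, 1]")
        if self.drift_generations < 0:
            raise ValueError("drift_generations must be non-negative")
        if self.effective_size < 1:
            raise ValueError("effective_size must be positive")
        if self.selection_coefficient < -1:
            raise ValueError("selection_coefficient must be >= -1")
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness_rate must be in [0, 1)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


@dataclass(frozen=True)
class TrueParameters:
    """Ground truth recorded alongside a simulated dataset."""

    freq_x: np.ndarray
    freq_y: np.ndarray
    offspring_founder_freq: np.ndarray
    offspring_final_freq: np.ndarray
    focal_index: int
    config: SimulationConfig


def _selection_update(f: np.ndarray, s: float) -> np.ndarray:
    """One generation of deterministic genic selection: f' = f(1+s)/(1+fs)."""
    return f * (1 + s) / (1 + f * s)


def simulate_admixture_dataset(
    config: SimulationConfig,
) -> Tuple[Dict[str, GenotypeTable], TrueParameters]:
    """Simulate genotype tables for parental_x, parental_y and offspring.

    Per neutral locus: parental frequencies are independent uniform draws;
    the offspring founder frequency is ``alpha * f_x + (1 - alpha) * f_y``;
    drift (if any) binomially resamples the offspring frequency for
    ``drift_generations`` at ``2 * effective_size`` alleles.  The focal
    locus is appended as the last variant, with selection applied
    deterministically before each drift generation.  Diploid genotypes are
    binomial draws from the final frequencies and are masked missing
    independently at ``missingness_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n_loci = config.n_loci
    alpha = config.admixture_alpha

    freq_x = np.append(rng.uniform(0.05, 0.95, n_loci), config.focal_freq_x)
    freq_y = np.append(rng.uniform(0.05, 0.95, n_loci), config.focal_freq_y)
    founder = alpha * freq_x + (1 - alpha) * freq_y

    final = founder.copy()
    n_alleles = 2 * config.effective_size
    s = config.selection_coefficient
    for _ in range(config.drift_generations):
        if s != 0.0:
            final[-1] = _selection_update(final[-1:], s)[0]
        final = rng.binomial(n_alleles, final) / n_alleles
    sizes = {
        "parental_x": config.n_parental_x,
        "parental_y": config.n_parental_y,
        "offspring": config.n_offspring,
    }
    freqs = {"parental_x": freq_x, "parental_y": freq_y, "offspring": final}
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * (n_loci + 1),
            "pos": np.arange(1, n_loci + 2) * 1000,
            "ref": ["A"] * (n_loci + 1),
            "alt": ["G"] * (n_loci + 1),
            "derived": ["G"] * (n_loci + 1),
        }
    )
    tables: Dict[str, GenotypeTable] = {}
    for pop, size in sizes.items():
        calls = rng.binomial(2, freqs[pop], size=(size, n_loci + 1)).astype(
            np.int8
        )
        if config.missingness_rate > 0:
            mask = rng.random(calls.shape) < config.missingness_rate
            calls[mask] = MISSING
        individuals = pd.DataFrame(
            {
                "sample": [f"{pop}_{i}" for i in range(size)],
                "population": pop,
            }
        )
        tables[pop] = GenotypeTable(individuals, variants.copy(), calls)
    truth = TrueParameters(
        freq_x=freq_x,
        freq_y=freq_y,
        offspring_founder_freq=founder,
        offspring_final_freq=final,
        focal_index=n_loci,
        config=config,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Forward Wright-Fisher haplotype simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForwardSimConfig:
    """Parameters of the forward haplotype simulation.

    Rates are per bp per generation.  The founder population carries neutral
    standing variation drawn from a coalescent sample at
    ``founder_effective_size`` (so the panel has realistic background
    diversity and LD before selection starts); ``focal_start_freq`` sets the
    initial derived-allele frequency at the focal site, assigned to the
    carriers of an actual founder variant so the selected allele has a
    single mutational origin.  ``selection_coefficient`` multiplies the
    fitness of every haplotype carrying the derived allele (genic
    selection, 1 + s).
    """

    pop_size: int = 500
    sequence_length: int = 200_000
    mutation_rate: float = 1e-8
    recombination_rate: float = 1e-8
    focal_position: int = 100_000
    selection_coefficient: float = 0.0
    generations: int = 100
    focal_start_freq: float = 0.05
    founder_effective_size: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not 0 <= self.focal_position < self.sequence_length:
            raise ValueError("focal_position must lie in [0, sequence_length)")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.focal_start_freq <= 1:
            raise ValueError("focal_start_freq must be in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.founder_effective_size < 2:
            raise ValueError("founder_effective_size must be >= 2")


@dataclass
class ForwardSimResult:
    """Final-generation sample from the forward simulator.

    ``focal_extinct`` distinguishes loss of the focal derived allele from a
    successful run; the haplotype matrix always contains the focal column
    (monomorphic ancestral when extinct).
    """

    haplotypes: HaplotypeMatrix
    focal_position: int
    focal_frequency: float
    focal_extinct: bool


def _founder_population(
    config: ForwardSimConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neutral standing variation for the founders, plus the focal column.

    Haplotypes come from a coalescent sample (msprime) at
    ``founder_effective_size`` with the configured mutation and
    recombination rates.  The focal derived allele is grafted onto the
    carriers of the founder variant whose frequency is closest to
    ``focal_start_freq`` (single mutational origin on a realistic
    background); that variant's own column is consumed by the graft.  With
    no standing variation (for example mu = 0) carriers are drawn at
    random instead.
    """
    import msprime

    n = config.pop_size
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=config.founder_effective_size,
        sequence_length=config.sequence_length,
        recombination_rate=config.recombination_rate,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        random_seed=int(rng.integers(1, 2**31 - 1)),
        model=msprime.BinaryMutationModel(),
    )
    matrix = ts.genotype_matrix().T.astype(np.int8)  # (n, sites)
    positions = np.array(
        [int(site.position) for site in ts.sites()], dtype=np.int64
    )
    if len(positions):
        # discrete positions can collide; keep the first site at each position
        keep = np.concatenate(([True], np.diff(positions) > 0))
        keep &= positions != config.focal_position
        matrix, positions = matrix[:, keep], positions[keep]
    matrix = np.clip(matrix, 0, 1)

    focal = np.zeros(n, dtype=bool)
    if config.focal_start_freq > 0:
        freqs = matrix.mean(axis=0) if matrix.shape[1] else np.array([])
        candidates = np.flatnonzero((freqs > 0) & (freqs < 1))
        if len(candidates):
            j = candidates[
                np.argmin(np.abs(freqs[candidates] - config.focal_start_freq))
            ]
            focal = matrix[:, j] == 1
            drop = np.ones(matrix.shape[1], dtype=bool)
            drop[j] = False
            matrix, positions = matrix[:, drop], positions[drop]
        else:
            k = int(round(n * config.focal_start_freq))
            focal[rng.choice(n, size=k, replace=False)] = True
    return matrix, positions, focal


def simulate_haplotypes(config: ForwardSimConfig) -> ForwardSimResult:
    """Forward Wright-Fisher simulation of binary haplotypes.

    Starting from founders carrying neutral coalescent standing variation,
    each generation samples ``pop_size`` offspring with replacement with
    probability proportional to fitness (1 + s for focal-derived carriers).
    With probability ``recombination_rate * sequence_length`` an offspring
    is a single-crossover recombinant of two parents; new mutations arrive
    as Poisson(pop_size * mu * L) per generation at uniformly drawn,
    previously monomorphic positions (infinite-sites approximation;
    collisions are re-drawn).
    """
    rng = np.random.default_rng(config.seed)
    n = config.pop_size
    L = config.sequence_length
    s = config.selection_coefficient

    matrix, positions, focal = _founder_population(config, rng)
    p_recomb = min(1.0, config.recombination_rate * L)
    mut_mean = n * config.mutation_rate * L

    for _ in range(config.generations):
        # inverse-CDF parent sampling on common uniforms: runs that differ
        # only in s share every random draw, so seed-paired comparisons
        # across selection coefficients are genuinely paired
        w = np.where(focal, 1.0 + s, 1.0) if s != 0.0 else np.ones(n)
        cum = np.cumsum(w / w.sum())
        u = rng.random((n, 2))
        parent_idx = np.minimum(np.searchsorted(cum, u, side="right"), n - 1)
        recomb_draws = rng.random(n) < p_recomb
        xos = rng.integers(1, L, size=n)
        new_matrix = np.empty_like(matrix)
        new_focal = np.zeros(n, dtype=bool)
        for k in range(n):
            p1, p2 = parent_idx[k]
            if recomb_draws[k] and p1 != p2:
                cut = int(np.searchsorted(positions, xos[k]))
                new_matrix[k, :cut] = matrix[p1, :cut]
                new_matrix[k, cut:] = matrix[p2, cut:]
                new_focal[k] = (
                    focal[p1] if config.focal_position < xos[k] else focal[p2]
                )
            else:
                new_matrix[k] = matrix[p1]
                new_focal[k] = focal[p1]
        matrix, focal = new_matrix, new_focal
        n_new = int(rng.poisson(mut_mean))
        if n_new:
            taken = set(positions.tolist()) | {config.focal_position}
            new_cols = []
            new_pos = []
            for _ in range(n_new):
                pos = int(rng.integers(0, L))
                while pos in taken:
                    pos = int(rng.integers(0, L))
                taken.add(pos)
                col = np.zeros(n, dtype=np.int8)
                col[int(rng.integers(0, n))] = 1
                new_cols.append(col)
                new_pos.append(pos)
            positions = np.concatenate([positions, np.array(new_pos)])
            matrix = np.concatenate([matrix, np.stack(new_cols, axis=1)], axis=1)
            order = np.argsort(positions)
            positions, matrix = positions[order], matrix[:, order]
        # prune fixed and lost background columns
        counts = matrix.sum(axis=0)
        seg = (counts > 0) & (counts < n)
        if not seg.all():
            matrix, positions = matrix[:, seg], positions[seg]

    focal_freq = float(focal.mean())
    insert = int(np.searchsorted(positions, config.focal_position))
    full = np.insert(matrix, insert, focal.astype(np.int8), axis=1)
    full_pos = np.insert(positions, insert, config.focal_position)
    out = HaplotypeMatrix(full, full_pos, polarised=True)
    return ForwardSimResult(
        haplotypes=out,
        focal_position=config.focal_position,
        focal_frequency=focal_freq,
        focal_extinct=focal_freq == 0.0,
    )
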