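"""Allele-frequency estimation from sparse diploid calls.

Ancient cohorts yield few individuals and many missing genotypes, so point
frequencies come with exact (Clopper-Pearson) binomial confidence intervals
and missing calls reduce the denominator rather than being imputed.  The
module also carries the plink-style dataset filter (individual missingness,
then minor allele frequency) and the two-sided Fisher exact test used to
compare allele frequencies between populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel dosage for a missing diploid call


class NoCalledAllelesError(ValueError):
    """Raised when a frequency is requested from zero called alleles."""


@dataclass(frozen=True)
class FrequencyEstimate:
    """Derived-allele frequency with an exact two-sided confidence interval.

    Attributes
    ----------
    k : int
        Derived-allele count.
    n : int
        Called allele total (2 x called individuals for diploids).
    freq : float
        Point estimate ``k / n``.
    ci_lower, ci_upper : float
        Exact Clopper-Pearson bounds at ``confidence``.
    confidence : float
        Two-sided confidence level, default 0.95.
    """

    k: int
    n: int
    freq: float
    ci_lower: float
    ci_upper: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.ci_lower <= self.freq <= self.ci_upper <= 1):
            raise ValueError("CI bounds must bracket the point estimate in [0, 1]")
        if self.k > self.n:
            raise ValueError("k cannot exceed n")


def estimate_frequency(k: int, n: int, confidence: float = 0.95) -> FrequencyEstimate:
    """Exact binomial frequency estimate.

    The interval is Clopper-Pearson: ``ci_lower`` is the Beta(k, n-k+1)
    quantile at alpha/2 (0 when k = 0) and ``ci_upper`` the Beta(k+1, n-k)
    quantile at 1 - alpha/2 (1 when k = n).  Conservative by construction,
    which suits the very small ancient sample sizes this package targets.
    """
    if n < 1:
        raise NoCalledAllelesError("no called alleles (n = 0)")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    ci = stats.binomtest(k, n).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return FrequencyEstimate(
        k=int(k),
        n=int(n),
        freq=k / n,
        ci_lower=float(ci.low),
        ci_upper=float(ci.high),
        confidence=confidence,
    )


@dataclass
class GenotypeTable:
    """Diploid dosage matrix with population labels.

    ``calls`` holds the derived-allele dosage per individual x variant in
    {0, 1, 2}, with :data:`MISSING` (-1) for no call.  ``individuals`` is a
    DataFrame with columns ``sample`` and ``population``; ``variants`` has
    ``chrom``, ``pos`` (1-based), ``ref``, ``alt`` and may carry a
    ``derived`` allele column.
    """

    individuals: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray  # shape (n_individuals, n_variants), int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.variants)):
            raise ValueError("calls shape must be (n_individuals, n_variants)")
        valid = np.isin(self.calls, [MISSING, 0, 1, 2])
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")
        if "sample" not in self.individuals or "population" not in self.individuals:
            raise ValueError("individuals needs 'sample' and 'population' columns")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def populations(self) -> List[str]:
        return sorted(self.individuals["population"].unique())

    def variant_index(self, chrom: str, pos: int) -> int:
        mask = (self.variants["chrom"].astype(str) == str(chrom)) & (
            self.variants["pos"] == pos
        )
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"variant {chrom}:{pos} not in table")
        return int(idx[0])

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            self.individuals.loc[mask].reset_index(drop=True),
            self.variants.copy(),
            self.calls[mask],
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            self.individuals.copy(),
            self.variants.loc[mask].reset_index(drop=True),
            self.calls[:, mask],
        )


def allele_counts(dosages: np.ndarray) -> tuple[int, int]:
    """(derived count, called allele total) from a dosage vector."""
    called = dosages != MISSING
    k = int(dosages[called].sum())
    n = 2 * int(called.sum())
    return k, n


def population_frequencies(
    table: GenotypeTable,
    variant_index: int,
    confidence: float = 0.95,
) -> Dict[str, Optional[FrequencyEstimate]]:
    """Per-population frequency estimate at one variant.

    Missing calls are excluded from numerator and denominator alike.  A
    population where every call is missing maps to ``None`` ("no data"),
    never to frequency zero.
    """
    if not 0 <= variant_index < table.n_variants:
        raise IndexError("variant_index out of range")
    dosages = table.calls[:, variant_index]
    pops = table.individuals["population"].to_numpy()
    out: Dict[str, Optional[FrequencyEstimate]] = {}
    for pop in table.populations():
        k, n = allele_counts(dosages[pops == pop])
        out[pop] = estimate_frequency(k, n, confidence) if n > 0 else None
    return out


def fisher_exact_2x2(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p-value for allele counts in two populations.

    The 2x2 table is (derived, ancestral) x (pop1, pop2); two-sidedness is by
    the probability-mass criterion (all tables with hypergeometric probability
    <= the observed table's contribute).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate table: a population has no called alleles")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def individual_missingness(table: GenotypeTable) -> np.ndarray:
    """Fraction of missing calls per individual."""
    return (table.calls == MISSING).mean(axis=1)


def variant_maf(table: GenotypeTable) -> np.ndarray:
    """Minor-allele frequency per variant over called genotypes (NaN if none)."""
    maf = np.full(table.n_variants, np.nan)
    for j in range(table.n_variants):
        k, n = allele_counts(table.calls[:, j])
        if n > 0:
            f = k / n
            maf[j] = min(f, 1 - f)
    return maf


def filter_dataset(
    table: GenotypeTable,
    max_individual_missingness: float = 0.5,
    min_maf: float = 0.01,
) -> GenotypeTable:
    """plink-style dataset filter: individuals first, then variants.

    Individuals whose missing fraction exceeds ``max_individual_missingness``
    (``--mind``) are dropped; minor allele frequencies are then recomputed on
    the survivors and variants with MAF below ``min_maf`` (``--maf``) are
    dropped.  The order is fixed and matters: MAF is always computed on the
    post-``mind`` individual set.
    """
    for name, value in (
        ("max_individual_missingness", max_individual_missingness),
        ("min_maf", min_maf),
    ):
        if not 0 <= value <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    keep_ind = individual_missingness(table) <= max_individual_missingness
    trimmed = table.subset_individuals(keep_ind)
    maf = variant_maf(trimmed)
    keep_var = np.nan_to_num(maf, nan=-1.0) >= min_maf
    out = trimmed.subset_variants(keep_var)
    logger.info(
        "filter_dataset: individuals %d -> %d, variants %d -> %d",
        table.n_individuals,
        out.n_individuals,
        table.n_variants,
        out.n_variants,
    )
    if out.n_individuals == 0 or out.n_variants == 0:
        logger.warning("filter_dataset produced an empty table")
    return out
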