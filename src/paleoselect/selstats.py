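"""Site-frequency-spectrum and differentiation statistics on phased haplotypes.

Implements the neutrality tests run around the focal variant: classic and
haplotype-specific Tajima's D, the outgroup versions of Fu & Li's D and F,
a sliding-window Tajima's D scan, Hudson / Weir-Cockerham F_ST, and the
exact conditional Hardy-Weinberg test.  Significantly negative SFS scores
indicate an excess of rare variants — positive selection or expansion.

All statistics operate on a :class:`HaplotypeMatrix` of binary alleles
(0 = ancestral, 1 = derived when polarised).  Sites with any missing call
are dropped before computing a statistic (complete-case), matching the use
of imputed, complete haplotype panels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

MISSING = -1


class PolarisationError(ValueError):
    """An outgroup-based statistic was requested on unpolarised haplotypes."""


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes with physical positions.

    ``alleles`` is (n_haplotypes, n_sites) with entries in {0, 1} plus -1 for
    missing; ``positions`` are bp coordinates, strictly increasing.  When
    ``polarised`` is True, 1 means the derived allele (required for Fu & Li's
    outgroup statistics and for choosing an EHH core allele by state).
    """

    alleles: np.ndarray
    positions: np.ndarray
    polarised: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("positions must match the number of sites")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.alleles, [MISSING, 0, 1]).all():
            raise ValueError("alleles must be 0, 1 or missing (-1)")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def site_index(self, position: int) -> int:
        idx = np.searchsorted(self.positions, position)
        if idx >= self.n_sites or self.positions[idx] != position:
            raise KeyError(f"no site at position {position}")
        return int(idx)

    def subset_sites(self, mask: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.alleles[:, mask], self.positions[mask], self.polarised
        )

    def subset_haplotypes(self, mask: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.alleles[mask], self.positions.copy(), self.polarised
        )

    def complete_sites(self) -> "HaplotypeMatrix":
        """Drop sites with any missing call (complete-case)."""
        return self.subset_sites((self.alleles != MISSING).all(axis=0))


@dataclass(frozen=True)
class DiversitySummary:
    """Sufficient statistics for the SFS-based tests.

    ``pi`` is the mean number of pairwise differences (a count, not a
    per-site rate); ``eta`` equals ``S`` under the infinite-sites assumption
    of biallelic data; ``eta_e`` is the count of external (derived singleton)
    mutations and is None when the input is unpolarised.
    """

    n: int
    S: int
    eta: int
    eta_e: Optional[int]
    pi: float


@dataclass(frozen=True)
class SelectionStatResult:
    """A named statistic value with an optional significance class."""

    name: str
    value: Optional[float]
    p_value: Optional[float] = None
    significance: str = "none"  # none / P<0.05 / P<0.02 / P<0.01

    @property
    def defined(self) -> bool:
        return self.value is not None


def _significance_class(p: Optional[float]) -> str:
    if p is None:
        return "none"
    if p < 0.01:
        return "P<0.01"
    if p < 0.02:
        return "P<0.02"
    if p < 0.05:
        return "P<0.05"
    return "none"


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def diversity_summary(h: HaplotypeMatrix) -> DiversitySummary:
    """Compute S, pi and (if polarised) the singleton count eta_e.

    pi is averaged over all C(n, 2) haplotype pairs; with derived count d_j
    at site j it equals sum_j d_j (n - d_j) / C(n, 2).  eta_e counts sites
    where the derived allele occurs exactly once.
    """
    if h.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    hc = h.complete_sites()
    n = hc.n_haplotypes
    derived = hc.alleles.sum(axis=0).astype(np.int64)
    poly = (derived > 0) & (derived < n)
    S = int(poly.sum())
    npairs = n * (n - 1) / 2
    pi = float((derived * (n - derived)).sum() / npairs)
    eta_e = int((derived == 1).sum()) if h.polarised else None
    return DiversitySummary(n=n, S=S, eta=S, eta_e=eta_e, pi=pi)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict:
    """The variance constants of Tajima's D for sample size n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    a1 = _harmonic(n, 1)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _tajima_beta_p(d: float, n: int, e2: float, a1: float) -> Optional[float]:
    """Two-sided p-value for Tajima's D from the beta approximation.

    D is assumed to range over (D_min, D_max) with mean 0 and variance 1 and
    to follow a generalised beta there; D_min arises when every mutation is a
    singleton, D_max when every mutation is at frequency 1/2.
    """
    sqrt_e2 = math.sqrt(e2)
    d_min = (2 / n - 1 / a1) / sqrt_e2
    if n % 2 == 0:
        pi_max = n / (2 * (n - 1))
    else:
        pi_max = (n + 1) / (2 * n)
    d_max = (pi_max - 1 / a1) / sqrt_e2
    if not d_min < 0 < d_max:
        return None
    alpha = -(1 + d_min * d_max) * d_max / (d_max - d_min)
    beta = (1 + d_min * d_max) * d_min / (d_max - d_min)
    if alpha <= 0 or beta <= 0:
        return None
    x = (d - d_min) / (d_max - d_min)
    x = min(max(x, 0.0), 1.0)
    cdf = float(sps.beta.cdf(x, beta, alpha))
    return min(1.0, 2 * min(cdf, 1 - cdf))


def tajimas_d(h: HaplotypeMatrix) -> SelectionStatResult:
    """Tajima's D: standardised difference between pi and Watterson's S/a1.

    Returns an undefined result (value None) when there are no segregating
    sites — never a silent zero.  Significance uses the beta-distribution
    approximation to the null density of D.
    """
    summary = diversity_summary(h)
    n, S, pi = summary.n, summary.S, summary.pi
    if S == 0:
        return SelectionStatResult("tajimas_d", None)
    c = tajima_constants(n)
    num = pi - S / c["a1"]
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        # n = 2 (and n = 3): pi == S/a1 identically, so D is 0, not undefined
        if abs(num) < 1e-12:
            return SelectionStatResult("tajimas_d", 0.0)
        return SelectionStatResult("tajimas_d", None)
    d = num / math.sqrt(var)
    p = _tajima_beta_p(d, n, c["e2"], c["a1"])
    return SelectionStatResult("tajimas_d", float(d), p, _significance_class(p))


# ---------------------------------------------------------------------------
# Fu & Li's D and F (outgroup versions)
# ---------------------------------------------------------------------------

def fu_li_constants(n: int) -> dict:
    """Variance constants u_D, v_D, u_F, v_F for Fu & Li's D and F.

    Uses the corrected expressions in standard use (the widely adopted fix
    to the original u_F): with a_n = sum 1/i, b_n = sum 1/i^2 over i < n,

        c_n = 2 (n a_n - 2 (n - 1)) / ((n - 1)(n - 2))          (c_2 = 1)
        v_D = 1 + a_n^2 / (b_n + a_n^2) * (c_n - (n + 1)/(n - 1))
        u_D = a_n - 1 - v_D
        v_F = [c_n + 2 (n^2 + n + 3) / (9 n (n - 1)) - 2/(n - 1)]
              / (a_n^2 + b_n)
        u_F = [1 + (n + 1)/(3 (n - 1))
               - 4 (n + 1)/(n - 1)^2 * (a_{n+1} - 2 n/(n + 1))] / a_n - v_F
    """
    if n < 3:
        raise ValueError("Fu & Li constants require n >= 3")
    an = _harmonic(n, 1)
    bn = _harmonic(n, 2)
    an1 = an + 1.0 / n  # a_{n+1}
    cn = 1.0 if n == 2 else 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1 + an**2 / (bn + an**2) * (cn - (n + 1) / (n - 1))
    u_d = an - 1 - v_d
    v_f = (cn + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) - 2 / (n - 1)) / (
        an**2 + bn
    )
    u_f = (
        1
        + (n + 1) / (3 * (n - 1))
        - 4 * (n + 1) / (n - 1) ** 2 * (an1 - 2 * n / (n + 1))
    ) / an - v_f
    return {"an": an, "bn": bn, "cn": cn,
            "u_d": u_d, "v_d": v_d, "u_f": u_f, "v_f": v_f}


def _check_polarised(h: HaplotypeMatrix) -> None:
    if not h.polarised:
        raise PolarisationError(
            "Fu & Li's outgroup statistics need polarised haplotypes; "
            "the starred within-sample variants are intentionally not "
            "substituted silently"
        )


def _fu_li(
    h: HaplotypeMatrix,
    which: str,
    significance: str,
    n_reps: int,
    seed: Optional[int],
) -> SelectionStatResult:
    _check_polarised(h)
    summary = diversity_summary(h)
    n, eta, eta_e, pi = summary.n, summary.eta, summary.eta_e, summary.pi
    name = f"fu_li_{which}"
    if eta == 0:
        return SelectionStatResult(name, None)
    c = fu_li_constants(n)
    if which == "d":
        num = eta - c["an"] * eta_e
        var = c["u_d"] * eta + c["v_d"] * eta**2
    else:
        num = pi - eta_e
        var = c["u_f"] * eta + c["v_f"] * eta**2
    if var <= 0:
        return SelectionStatResult(name, None)
    value = num / math.sqrt(var)
    p = None
    if significance == "simulated":
        theta_w = eta / c["an"]
        p = _simulated_null_p(value, n, theta_w, which, n_reps, seed)
    return SelectionStatResult(name, float(value), p, _significance_class(p))


def fu_li_d(
    h: HaplotypeMatrix,
    significance: str = "none",
    n_reps: int = 2000,
    seed: Optional[int] = None,
) -> SelectionStatResult:
    """Fu & Li's D: contrasts total mutations eta against a_n * eta_e.

    External-branch (singleton derived) mutations are young; a deficit of
    them relative to eta drives D positive, an excess drives it negative.
    ``significance="simulated"`` computes a two-sided empirical p-value from
    a seeded neutral-coalescent null conditioned on Watterson's theta.
    """
    return _fu_li(h, "d", significance, n_reps, seed)


def fu_li_f(
    h: HaplotypeMatrix,
    significance: str = "none",
    n_reps: int = 2000,
    seed: Optional[int] = None,
) -> SelectionStatResult:
    """Fu & Li's F: contrasts mean pairwise diversity pi against eta_e."""
    return _fu_li(h, "f", significance, n_reps, seed)


@lru_cache(maxsize=32)
def _fu_li_null(
    n: int, theta_key: float, n_reps: int, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Neutral-coalescent null draws of Fu & Li's (D, F) for sample size n.

    Replicates are standard no-recombination coalescent samples (msprime)
    with the mutation rate set so the locus-wide theta matches the
    data-estimated Watterson theta; each replicate's unfolded SFS yields
    eta, eta_e and pi, hence one (D, F) pair.  Cached so the D and F tests
    on the same panel share one set of replicates.
    """
    import msprime

    theta = float(theta_key)
    pop_size = 1.0  # haploid: pairwise coalescence in pop_size generations
    mu = theta / (2 * pop_size)
    c = fu_li_constants(n)
    counts = np.arange(1, n)
    npairs = n * (n - 1) / 2
    ds, fs = [], []
    replicates = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=pop_size,
        sequence_length=1,
        discrete_genome=False,
        num_replicates=n_reps,
        random_seed=max(1, seed),
    )
    for i, ts in enumerate(replicates):
        mts = msprime.sim_mutations(
            ts, rate=mu, random_seed=max(1, seed) + i + 1,
            discrete_genome=False,
        )
        afs = mts.allele_frequency_spectrum(
            mode="site", span_normalise=False, polarised=True
        )
        sfs = afs[1:n]
        eta = float(sfs.sum())
        if eta == 0:
            continue
        eta_e = float(sfs[0])
        pi = float((sfs * counts * (n - counts)).sum() / npairs)
        var_d = c["u_d"] * eta + c["v_d"] * eta**2
        var_f = c["u_f"] * eta + c["v_f"] * eta**2
        if var_d > 0:
            ds.append((eta - c["an"] * eta_e) / math.sqrt(var_d))
        if var_f > 0:
            fs.append((pi - eta_e) / math.sqrt(var_f))
    return np.asarray(ds), np.asarray(fs)


def _simulated_null_p(
    observed: float,
    n: int,
    theta: float,
    which: str,
    n_reps: int,
    seed: Optional[int],
) -> float:
    """Two-sided empirical p for Fu & Li's D or F under the neutral null.

    Replicates with eta = 0 are skipped (the statistic is undefined there,
    as it is on the data); the +1/m term keeps the empirical p away from an
    impossible zero.
    """
    ds, fs = _fu_li_null(
        n, round(float(theta), 6), n_reps,
        seed if seed is not None else 2**20 + n,
    )
    values = ds if which == "d" else fs
    if len(values) == 0:
        return 1.0
    lower = (values <= observed).mean()
    upper = (values >= observed).mean()
    return float(min(1.0, 2 * min(lower, upper) + 1.0 / len(values)))


# ---------------------------------------------------------------------------
# Haplotype-specific statistics
# ---------------------------------------------------------------------------

def haplotype_partition(
    h: HaplotypeMatrix,
    focal_position: int,
    focal_allele: int = 1,
    min_class_size: int = 4,
) -> Tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """Split haplotypes into carriers / non-carriers of a focal allele.

    The focal column is removed from both classes (it is monomorphic within
    each), so haplotype-specific statistics are not distorted by the
    partitioning site itself.  Class sizes always sum to n; a class smaller
    than ``min_class_size`` is logged as underpowered and an empty class is
    logged explicitly.
    """
    idx = h.site_index(focal_position)
    col = h.alleles[:, idx]
    carrier_mask = col == focal_allele
    site_mask = np.ones(h.n_sites, dtype=bool)
    site_mask[idx] = False
    carriers = h.subset_haplotypes(carrier_mask).subset_sites(site_mask)
    non_carriers = h.subset_haplotypes(~carrier_mask).subset_sites(site_mask)
    for label, cls in (("carrier", carriers), ("non-carrier", non_carriers)):
        if cls.n_haplotypes == 0:
            logger.warning("haplotype_partition: %s class is empty", label)
        elif cls.n_haplotypes < min_class_size:
            logger.warning(
                "haplotype_partition: %s class has %d haplotypes "
                "(underpowered, < %d)",
                label, cls.n_haplotypes, min_class_size,
            )
    return carriers, non_carriers


def sliding_tajima(
    h: HaplotypeMatrix,
    window_bp: int = 40_000,
    step_bp: int = 100,
    region: Optional[Tuple[int, int]] = None,
) -> List[Tuple[int, int, SelectionStatResult]]:
    """Sliding-window Tajima's D over a physical region.

    Windows are half-open ``[start, start + window_bp)`` anchored at the
    region start and advanced by ``step_bp``; a window with no segregating
    sites yields an undefined result rather than zero.  Returns
    ``(window_start, window_end, result)`` triples.
    """
    if region is None:
        region = (int(h.positions[0]), int(h.positions[-1]) + 1)
    start, end = region
    if window_bp > end - start:
        raise ValueError("window_bp exceeds the region span")
    if step_bp < 1:
        raise ValueError("step_bp must be >= 1")
    out: List[Tuple[int, int, SelectionStatResult]] = []
    w = start
    while w + window_bp <= end:
        mask = (h.positions >= w) & (h.positions < w + window_bp)
        if mask.any():
            res = tajimas_d(h.subset_sites(mask))
        else:
            res = SelectionStatResult("tajimas_d", None)
        out.append((w, w + window_bp, res))
        w += step_bp
    return out


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _hudson_components(p1, n1, p2, n2):
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _wc_components(p1, n1, p2, n2):
    # Weir & Cockerham (1984) for allele-count data, r = 2 populations
    r = 2
    nbar = (n1 + n2) / 2
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    return a, a + b


def fst(
    k1: Sequence[int],
    n1: Sequence[int],
    k2: Sequence[int],
    n2: Sequence[int],
    estimator: str = "hudson",
) -> Optional[float]:
    """F_ST between two populations from per-site allele counts.

    ``k`` is the derived (or alt) allele count and ``n`` the called allele
    total at each site.  Hudson's estimator is the default; Weir-Cockerham
    (allele-count form) is available via ``estimator="wc"``.  Multi-site
    scopes (gene, chromosome) combine as a ratio of averages: mean numerator
    over mean denominator.  Sites monomorphic in both populations are
    excluded; if every site is excluded the value is undefined (None).
    Because the unbiased numerator can dip below zero at weak
    differentiation while the parameter itself is non-negative, estimates
    are truncated to [0, 1].
    """
    k1 = np.atleast_1d(np.asarray(k1, dtype=float))
    n1 = np.atleast_1d(np.asarray(n1, dtype=float))
    k2 = np.atleast_1d(np.asarray(k2, dtype=float))
    n2 = np.atleast_1d(np.asarray(n2, dtype=float))
    if not k1.shape == n1.shape == k2.shape == n2.shape:
        raise ValueError("count vectors must share a shape")
    usable = (n1 > 1) & (n2 > 1)
    p1 = np.divide(k1, n1, out=np.zeros_like(k1), where=n1 > 0)
    p2 = np.divide(k2, n2, out=np.zeros_like(k2), where=n2 > 0)
    poly = ~((p1 == 0) & (p2 == 0)) & ~((p1 == 1) & (p2 == 1))
    keep = usable & poly
    if not keep.any():
        return None
    if estimator == "hudson":
        num, den = _hudson_components(p1[keep], n1[keep], p2[keep], n2[keep])
    elif estimator == "wc":
        num, den = _wc_components(p1[keep], n1[keep], p2[keep], n2[keep])
    else:
        raise ValueError("estimator must be 'hudson' or 'wc'")
    mean_den = float(np.mean(den))
    if mean_den == 0:
        return None
    value = float(np.mean(num) / mean_den)
    return float(np.clip(value, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    the observed one.  The probability of ``h`` heterozygotes given ``na``
    copies of the rarer allele among ``N`` diploids is

        P(h) = N! / (nAA! nAa! naa!) * 2^h * na! nb! / (2N)!

    A monomorphic sample returns p = 1.
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    N = n_AA + n_Aa + n_aa
    if N < 1:
        raise ValueError("need at least one genotype")
    na = 2 * n_aa + n_Aa  # copies of allele a
    nb = 2 * n_AA + n_Aa
    rare = min(na, nb)
    if rare == 0:
        return 1.0

    lgamma = math.lgamma

    def log_prob(h: int) -> float:
        n_hom_rare = (rare - h) // 2
        n_hom_common = (max(na, nb) - h) // 2
        return (
            lgamma(N + 1)
            - lgamma(n_hom_rare + 1)
            - lgamma(h + 1)
            - lgamma(n_hom_common + 1)
            + h * math.log(2)
            + lgamma(na + 1)
            + lgamma(nb + 1)
            - lgamma(2 * N + 1)
        )

    h_values = [h for h in range(rare % 2, rare + 1, 2)]
    log_probs = np.array([log_prob(h) for h in h_values])
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    observed = probs[h_values.index(n_Aa)]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))
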