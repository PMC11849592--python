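"""Linkage-disequilibrium structure: D'/r2, Gabriel blocks, EHH curves.

Haplotype blocks follow the Gabriel confidence-interval definition: a pair
of sites is in "strong LD" when the one-sided D' confidence bounds are high
(lower >= 0.70, upper >= 0.98), shows "strong recombination" when the upper
bound is below 0.90, and a block is a run of sites in which at least 95% of
the informative pairs are strong-LD.  Extended haplotype homozygosity (EHH)
measures the probability that two haplotypes carrying a core allele are
identical from the core out to a given position; slow decay on the derived
background is the classic signature of a recent positive sweep.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from paleoselect.selstats import MISSING, HaplotypeMatrix


@dataclass(frozen=True)
class LDPair:
    """Pairwise LD between two sites, with a D' confidence interval."""

    i: int
    j: int
    d_prime: float
    r2: float
    ci_lower: float
    ci_upper: float

    def __post_init__(self) -> None:
        if not 0 <= self.ci_lower <= self.ci_upper <= 1:
            raise ValueError("D' CI must be within [0, 1] and ordered")


@dataclass(frozen=True)
class LDBlock:
    """A Gabriel haplotype block."""

    start: int
    end: int
    sites: Tuple[int, ...]
    strong_fraction: float

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class EHHCurve:
    """EHH values at every analysed site around a core allele."""

    core_position: int
    core_allele: int
    positions: np.ndarray
    values: np.ndarray
    n_carriers: int

    def area(self) -> float:
        """Trapezoid integral of EHH over physical distance (both sides)."""
        total = 0.0
        core_idx = int(np.searchsorted(self.positions, self.core_position))
        for side in (
            slice(core_idx, len(self.positions)),
            slice(core_idx, None, -1),
        ):
            pos = np.abs(self.positions[side] - self.core_position)
            total += float(np.trapezoid(self.values[side], pos))
        return total


def _two_locus_counts(
    h: HaplotypeMatrix, i: int, j: int
) -> Optional[Tuple[np.ndarray, float, float]]:
    """Complete-case 2x2 haplotype counts and allele frequencies."""
    a = h.alleles[:, i]
    b = h.alleles[:, j]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) == 0:
        return None
    counts = np.zeros((2, 2))
    for x in (0, 1):
        for y in (0, 1):
            counts[x, y] = np.sum((a == x) & (b == y))
    p = a.mean()
    q = b.mean()
    if p in (0.0, 1.0) or q in (0.0, 1.0):
        return None
    return counts, float(p), float(q)


def _d_prime_r2(counts: np.ndarray, p: float, q: float) -> Tuple[float, float, float]:
    n = counts.sum()
    p11 = counts[1, 1] / n
    d = p11 - p * q
    if d >= 0:
        d_max = min(p * (1 - q), (1 - p) * q)
    else:
        d_max = min(p * q, (1 - p) * (1 - q))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p * (1 - p) * q * (1 - q))
    return min(d_prime, 1.0), min(r2, 1.0), d


def _d_prime_ci(
    counts: np.ndarray, p: float, q: float, d_sign: float, grid: int = 200
) -> Tuple[float, float]:
    """Likelihood-profile confidence bounds on |D'|.

    The multinomial likelihood of the four observed haplotype counts is
    evaluated on a |D'| grid (allele frequencies held at their estimates,
    sign of D fixed at the observed sign), normalised to a distribution, and
    the 5% / 95% cumulative points are returned — the construction the
    block-definition literature uses.
    """
    if d_sign >= 0:
        d_max = min(p * (1 - q), (1 - p) * q)
        sign = 1.0
    else:
        d_max = min(p * q, (1 - p) * (1 - q))
        sign = -1.0
    ds = np.linspace(0, 1, grid + 1)
    eps = 1e-12
    log_liks = np.empty_like(ds)
    for idx, dp in enumerate(ds):
        d = sign * dp * d_max
        freqs = np.array(
            [
                [(1 - p) * (1 - q) + d, (1 - p) * q - d],
                [p * (1 - q) - d, p * q + d],
            ]
        )
        freqs = np.clip(freqs, eps, None)
        freqs /= freqs.sum()
        log_liks[idx] = float((counts * np.log(freqs)).sum())
    weights = np.exp(log_liks - log_liks.max())
    weights /= weights.sum()
    # step-out bounds: accumulate 5% of the mass from each end, then step
    # one grid point back toward the interior of the distribution
    low_cum = np.cumsum(weights)
    i = int(np.searchsorted(low_cum, 0.05, side="right"))
    lower = float(ds[max(i - 1, 0)])
    high_cum = np.cumsum(weights[::-1])
    j = int(np.searchsorted(high_cum, 0.05, side="right"))
    upper = float(ds[grid - max(j - 1, 0)])
    return lower, max(upper, lower)


def pairwise_ld(
    h: HaplotypeMatrix,
    min_maf: float = 0.05,
    max_missing: float = 0.25,
) -> List[LDPair]:
    """All-pairs D', r2 and D' CI over sites passing MAF/missingness filters.

    Pairs monomorphic after complete-case reduction are excluded.  Site
    indices in the returned pairs refer to the input matrix.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    n = h.n_haplotypes
    keep = []
    for s in range(h.n_sites):
        col = h.alleles[:, s]
        called = col != MISSING
        if n and (1 - called.mean()) > max_missing:
            continue
        if called.sum() == 0:
            continue
        f = col[called].mean()
        if min(f, 1 - f) < min_maf:
            continue
        keep.append(s)
    if len(keep) < 2:
        raise ValueError("fewer than 2 sites pass the LD site filters")
    pairs: List[LDPair] = []
    for a_idx in range(len(keep)):
        for b_idx in range(a_idx + 1, len(keep)):
            i, j = keep[a_idx], keep[b_idx]
            obs = _two_locus_counts(h, i, j)
            if obs is None:
                continue
            counts, p, q = obs
            d_prime, r2, d = _d_prime_r2(counts, p, q)
            lo, hi = _d_prime_ci(counts, p, q, d)
            pairs.append(LDPair(i, j, d_prime, r2, lo, hi))
    return pairs


def gabriel_blocks(
    pairs: Sequence[LDPair],
    positions: Sequence[int],
    strong_lower: float = 0.70,
    strong_upper: float = 0.98,
    recomb_upper: float = 0.90,
    min_strong_fraction: float = 0.95,
) -> List[LDBlock]:
    """Gabriel-definition haplotype blocks from precomputed LD pairs.

    A pair is strong-LD when its D' CI satisfies ``lower >= strong_lower``
    and ``upper >= strong_upper``; it shows strong recombination when
    ``upper < recomb_upper``; only such pairs are informative.  A candidate
    block is a contiguous site run whose bounding pair is strong-LD and in
    which the strong-LD share of informative pairs is at least
    ``min_strong_fraction``.  Maximal non-overlapping blocks are returned,
    chosen longest-span first with leftmost start as tie-break.
    """
    positions = np.asarray(positions)
    strong = {}
    informative = {}
    for p in pairs:
        is_strong = p.ci_lower >= strong_lower and p.ci_upper >= strong_upper
        is_recomb = p.ci_upper < recomb_upper
        if is_strong or is_recomb:
            informative[(p.i, p.j)] = True
            strong[(p.i, p.j)] = is_strong
    site_ids = sorted({s for p in pairs for s in (p.i, p.j)})
    candidates: List[LDBlock] = []
    for a_idx in range(len(site_ids)):
        for b_idx in range(a_idx + 1, len(site_ids)):
            i, j = site_ids[a_idx], site_ids[b_idx]
            if not strong.get((i, j), False):
                continue
            members = [s for s in site_ids if i <= s <= j]
            inf = str_cnt = 0
            for x_idx in range(len(members)):
                for y_idx in range(x_idx + 1, len(members)):
                    key = (members[x_idx], members[y_idx])
                    if informative.get(key, False):
                        inf += 1
                        str_cnt += strong[key]
            if inf == 0:
                continue
            frac = str_cnt / inf
            if frac >= min_strong_fraction:
                candidates.append(
                    LDBlock(
                        start=int(positions[i]),
                        end=int(positions[j]),
                        sites=tuple(members),
                        strong_fraction=frac,
                    )
                )
    candidates.sort(key=lambda b: (-b.span, b.start))
    chosen: List[LDBlock] = []
    for cand in candidates:
        if all(
            cand.end <= c.start or cand.start >= c.end for c in chosen
        ):
            chosen.append(cand)
    chosen.sort(key=lambda b: b.start)
    return chosen


def ehh(
    h: HaplotypeMatrix, core_position: int, core_allele: int
) -> EHHCurve:
    """Extended haplotype homozygosity around a core allele.

    Carriers of ``core_allele`` at the core site are grouped by identity
    over the interval from the core to each site; EHH at distance x is
    sum_g C(n_g, 2) / C(n_c, 2) over identity groups g.  Computed outward
    in both directions at every site of the matrix; a missing call makes a
    haplotype unique from that point on (conservative).  EHH is 1 at the
    core and non-increasing with distance by construction.
    """
    core_idx = h.site_index(core_position)
    carrier_mask = h.alleles[:, core_idx] == core_allele
    n_c = int(carrier_mask.sum())
    if n_c < 2:
        raise ValueError(
            f"fewer than 2 haplotypes carry allele {core_allele} at the core"
        )
    carriers = h.alleles[carrier_mask]
    denom = n_c * (n_c - 1) / 2
    values = np.ones(h.n_sites)

    def _homozygosity(keys: List[tuple]) -> float:
        counts = np.array(list(Counter(keys).values()))
        return float((counts * (counts - 1) / 2).sum() / denom)

    for direction in (1, -1):
        keys: List[tuple] = [() for _ in range(n_c)]
        rng_sites = (
            range(core_idx + 1, h.n_sites)
            if direction == 1
            else range(core_idx - 1, -1, -1)
        )
        for s in rng_sites:
            col = carriers[:, s]
            keys = [
                keys[k] + ((col[k],) if col[k] != MISSING else (("m", k),))
                for k in range(n_c)
            ]
            values[s] = _homozygosity(keys)
    return EHHCurve(
        core_position=int(core_position),
        core_allele=int(core_allele),
        positions=h.positions.copy(),
        values=values,
        n_carriers=n_c,
    )
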