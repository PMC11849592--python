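"""Construction of putatively neutral genomic regions by interval subtraction.

Neutral regions are what remains of the genome after removing (buffered) genes,
segmental duplications, copy-number variants, conserved elements, CpG islands,
repeats, centromeres and chromosome ends, then dropping fragments shorter than
a minimum length.  Variants inside these regions supply the empirical null for
the admixture-informed outlier test.

Coordinates are 0-based half-open throughout (BED native); conversion to and
from 1-based VCF positions happens at I/O boundaries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]


class ChromosomeRegistryError(KeyError):
    """An interval refers to a chromosome absent from the length registry."""


def _normalise(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or adjacent intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: List[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class IntervalSet:
    """Chromosome-keyed set of sorted, non-overlapping half-open intervals.

    Parameters
    ----------
    intervals
        Mapping of chromosome label to a list of ``(start, end)`` pairs.
        Normalised (sorted, merged, clipped-invalid removed) on construction.
    chrom_lengths
        Optional registry of chromosome lengths.  Required for operations that
        need chromosome bounds (buffering, edge exclusion, complementing).
    """

    intervals: Dict[str, List[Interval]] = field(default_factory=dict)
    chrom_lengths: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {
            c: _normalise(ivs) for c, ivs in self.intervals.items() if ivs
        }
        self.intervals = {c: ivs for c, ivs in self.intervals.items() if ivs}
        for c, ivs in self.intervals.items():
            length = self.chrom_lengths.get(c)
            if length is not None and ivs and ivs[-1][1] > length:
                raise ValueError(
                    f"interval {ivs[-1]} exceeds length {length} of chromosome {c}"
                )

    # -- basic protocol ----------------------------------------------------
    def chromosomes(self) -> List[str]:
        return sorted(self.intervals)

    def total_length(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def n_intervals(self) -> int:
        return sum(len(ivs) for ivs in self.intervals.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __contains__(self, item: Tuple[str, int]) -> bool:
        chrom, pos = item
        for s, e in self.intervals.get(chrom, []):
            if s <= pos < e:
                return True
        return False

    def to_records(self) -> List[Tuple[str, int, int]]:
        return [
            (c, s, e) for c in self.chromosomes() for s, e in self.intervals[c]
        ]

    @classmethod
    def from_records(
        cls,
        records: Iterable[Tuple[str, int, int]],
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> "IntervalSet":
        by_chrom: Dict[str, List[Interval]] = {}
        for chrom, start, end in records:
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        return cls(by_chrom, dict(chrom_lengths or {}))

    @classmethod
    def whole_genome(cls, chrom_lengths: Mapping[str, int]) -> "IntervalSet":
        return cls(
            {c: [(0, int(n))] for c, n in chrom_lengths.items()},
            dict(chrom_lengths),
        )


def union(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Union of several interval sets; registries are merged."""
    by_chrom: Dict[str, List[Interval]] = {}
    lengths: Dict[str, int] = {}
    for s in sets:
        lengths.update(s.chrom_lengths)
        for c, ivs in s.intervals.items():
            by_chrom.setdefault(c, []).extend(ivs)
    return IntervalSet(by_chrom, lengths)


def buffer_intervals(intervals: IntervalSet, flank_bp: int) -> IntervalSet:
    """Extend every interval by ``flank_bp`` on both sides.

    Extended intervals are clipped to ``[0, chromosome length)`` and merged.
    A chromosome missing from the registry raises
    :class:`ChromosomeRegistryError` (clipping needs the right bound).
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    if flank_bp == 0:
        return IntervalSet(dict(intervals.intervals), dict(intervals.chrom_lengths))
    out: Dict[str, List[Interval]] = {}
    for chrom, ivs in intervals.intervals.items():
        length = intervals.chrom_lengths.get(chrom)
        if length is None:
            raise ChromosomeRegistryError(
                f"chromosome {chrom!r} not in length registry"
            )
        out[chrom] = [
            (max(0, s - flank_bp), min(length, e + flank_bp)) for s, e in ivs
        ]
    return IntervalSet(out, dict(intervals.chrom_lengths))


def _subtract_one_chrom(
    universe: List[Interval], holes: List[Interval]
) -> List[Interval]:
    """Subtract normalised ``holes`` from normalised ``universe``."""
    if not holes:
        return list(universe)
    out: List[Interval] = []
    for s, e in universe:
        cur = s
        for hs, he in holes:
            if he <= cur:
                continue
            if hs >= e:
                break
            if hs > cur:
                out.append((cur, min(hs, e)))
            cur = max(cur, he)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def subtract(universe: IntervalSet, exclusions: Sequence[IntervalSet]) -> IntervalSet:
    """Set difference: ``universe`` minus the union of ``exclusions``."""
    holes = union(list(exclusions)) if exclusions else IntervalSet()
    out = {
        chrom: _subtract_one_chrom(ivs, holes.intervals.get(chrom, []))
        for chrom, ivs in universe.intervals.items()
    }
    return IntervalSet(out, dict(universe.chrom_lengths))


def exclude_chromosome_edges(
    intervals: IntervalSet,
    edge_bp: int,
    centromeres: IntervalSet | None = None,
) -> IntervalSet:
    """Remove ``edge_bp`` at both chromosome extremities plus centromeres.

    A chromosome shorter than ``2 * edge_bp`` ends up empty.
    """
    if edge_bp < 0:
        raise ValueError("edge_bp must be non-negative")
    holes: Dict[str, List[Interval]] = {}
    for chrom in intervals.intervals:
        length = intervals.chrom_lengths.get(chrom)
        if length is None:
            raise ChromosomeRegistryError(
                f"chromosome {chrom!r} not in length registry"
            )
        holes[chrom] = [(0, min(edge_bp, length)), (max(0, length - edge_bp), length)]
    exclusion_sets = [IntervalSet(holes, dict(intervals.chrom_lengths))]
    if centromeres is not None:
        exclusion_sets.append(centromeres)
    return subtract(intervals, exclusion_sets)


def drop_short(intervals: IntervalSet, min_bp: int) -> IntervalSet:
    """Remove intervals shorter than ``min_bp`` (length == min_bp is kept)."""
    if min_bp < 0:
        raise ValueError("min_bp must be non-negative")
    out = {
        chrom: [(s, e) for s, e in ivs if e - s >= min_bp]
        for chrom, ivs in intervals.intervals.items()
    }
    return IntervalSet(out, dict(intervals.chrom_lengths))


def build_neutral_regions(
    genes: IntervalSet,
    segdups: IntervalSet,
    cnvs: IntervalSet,
    conserved: IntervalSet,
    cpg_islands: IntervalSet,
    repeats: IntervalSet,
    centromeres: IntervalSet,
    chrom_lengths: Mapping[str, int],
    flank_bp: int = 100_000,
    edge_bp: int = 40_000,
    min_bp: int = 1_000,
) -> IntervalSet:
    """Run the full neutral-region exclusion cascade.

    Pipeline: whole genome minus genes buffered by ``flank_bp`` (roughly
    0.1 cM at the human average), minus segmental duplications, CNVs,
    conserved elements, CpG islands and repeats, minus centromeres and
    ``edge_bp`` at each chromosome end, then fragments shorter than
    ``min_bp`` are dropped.  Only the gene set is buffered; the remaining
    feature sets are subtracted as given.  Fully deterministic.
    """
    if not chrom_lengths:
        raise ChromosomeRegistryError("chromosome length registry is required")
    lengths = dict(chrom_lengths)
    genome = IntervalSet.whole_genome(lengths)

    def _with_registry(s: IntervalSet) -> IntervalSet:
        return IntervalSet(dict(s.intervals), lengths)

    buffered_genes = buffer_intervals(_with_registry(genes), flank_bp)
    remaining = subtract(
        genome,
        [
            buffered_genes,
            _with_registry(segdups),
            _with_registry(cnvs),
            _with_registry(conserved),
            _with_registry(cpg_islands),
            _with_registry(repeats),
        ],
    )
    remaining = exclude_chromosome_edges(remaining, edge_bp, _with_registry(centromeres))
    return drop_short(remaining, min_bp)


def overlap_length(a: IntervalSet, b: IntervalSet) -> int:
    """Total bp shared between two interval sets (0 means disjoint)."""
    total = 0
    for chrom, ivs_a in a.intervals.items():
        ivs_b = b.intervals.get(chrom, [])
        if not ivs_b:
            continue
        starts_a = np.array([s for s, _ in ivs_a])
        ends_a = np.array([e for _, e in ivs_a])
        for s, e in ivs_b:
            lo = np.maximum(starts_a, s)
            hi = np.minimum(ends_a, e)
            total += int(np.clip(hi - lo, 0, None).sum())
    return total
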