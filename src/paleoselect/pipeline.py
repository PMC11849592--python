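"""End-to-end orchestration: trajectory tests and selection scans.

The two entry points mirror the two halves of the analysis.
:func:`run_trajectory` takes a diploid genotype table, a focal variant and a
list of admixture events and produces per-population frequency estimates,
pairwise Fisher tests and the expected-range binomial test per event.
:func:`run_selection` takes a phased, polarised haplotype panel around the
focal site and produces the Table-style statistics (classic and
haplotype-specific Tajima's D and Fu & Li's D/F), EHH curves for both core
alleles, Gabriel LD blocks and a sliding-window Tajima's D track.

Both are deterministic given their inputs; attrition at every filtering
stage is logged with record counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from paleoselect import admixture as adm
from paleoselect import ld as ldmod
from paleoselect import popfreq as pf
from paleoselect import selstats as ss

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Fixed constants of the analysis, with the standard defaults."""

    confidence: float = 0.95
    alpha: float = 0.05
    lower_percentile: float = 2.5
    upper_percentile: float = 97.5
    max_individual_missingness: float = 0.5
    min_maf: float = 0.01
    window_bp: int = 40_000
    step_bp: int = 100
    flank_bp: int = 100_000
    edge_bp: int = 40_000
    min_region_bp: int = 1_000
    min_class_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.lower_percentile < self.upper_percentile <= 100:
            raise ValueError("percentiles must be ordered within [0, 100]")


def run_trajectory(
    table: pf.GenotypeTable,
    focal_chrom: str,
    focal_pos: int,
    events: Sequence[Tuple[str, adm.AdmixtureEvent]],
    config: AnalysisConfig | None = None,
) -> Dict:
    """Frequency trajectory of the focal variant across populations.

    ``events`` pairs each offspring population label with its
    :class:`~paleoselect.admixture.AdmixtureEvent`.  The report contains one
    frequency row per population, all pairwise Fisher p-values, and one
    expected-range binomial test per event.  Populations with no called
    alleles appear as explicit no-data rows, never as frequency zero.
    """
    config = config or AnalysisConfig()
    vidx = table.variant_index(focal_chrom, focal_pos)
    freqs = pf.population_frequencies(table, vidx, config.confidence)
    logger.info(
        "trajectory: %d populations, focal variant %s:%d",
        len(freqs), focal_chrom, focal_pos,
    )

    fisher: Dict[Tuple[str, str], Optional[float]] = {}
    pops = sorted(freqs)
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            e1, e2 = freqs[p1], freqs[p2]
            fisher[(p1, p2)] = (
                pf.fisher_exact_2x2(e1.k, e1.n, e2.k, e2.n)
                if e1 is not None and e2 is not None
                else None
            )

    event_results = []
    for offspring, event in events:
        fx = freqs.get(event.parent_x)
        fy = freqs.get(event.parent_y)
        fo = freqs.get(offspring)
        if fx is None or fy is None or fo is None:
            logger.warning(
                "trajectory: event %s <- (%s, %s) skipped (missing data)",
                offspring, event.parent_x, event.parent_y,
            )
            event_results.append(
                {"offspring": offspring, "event": event, "result": None}
            )
            continue
        rng = adm.expected_range(fx, fy, event)
        res = adm.admixture_binomial_test(fo.k, fo.n, rng)
        event_results.append(
            {"offspring": offspring, "event": event, "range": rng,
             "result": res}
        )
    return {
        "frequencies": freqs,
        "fisher": fisher,
        "events": event_results,
        "config": config,
    }


def _stat_block(
    h: ss.HaplotypeMatrix, significance_seed: int
) -> Dict[str, ss.SelectionStatResult]:
    return {
        "tajimas_d": ss.tajimas_d(h),
        "fu_li_d": ss.fu_li_d(
            h, significance="simulated", seed=significance_seed
        ),
        "fu_li_f": ss.fu_li_f(
            h, significance="simulated", seed=significance_seed + 1
        ),
    }


def run_selection(
    h: ss.HaplotypeMatrix,
    focal_position: int,
    focal_allele: int = 1,
    config: AnalysisConfig | None = None,
    region: Optional[Tuple[int, int]] = None,
) -> Dict:
    """Selection scan around a focal allele on a phased, polarised panel.

    Produces classic statistics on the full panel, haplotype-specific
    statistics within the carrier and non-carrier classes (a class below
    ``min_class_size`` haplotypes is reported as not computed rather than
    silently dropped), EHH curves for both core alleles, Gabriel blocks and
    a sliding-window Tajima's D track when the panel spans at least one
    window.
    """
    if not h.polarised:
        raise ss.PolarisationError("run_selection requires polarised haplotypes")
    config = config or AnalysisConfig()
    report: Dict = {"config": config, "n_haplotypes": h.n_haplotypes}

    report["classic"] = _stat_block(h, config.seed)
    carriers, non_carriers = ss.haplotype_partition(
        h, focal_position, focal_allele, config.min_class_size
    )
    classes = {}
    for label, cls in (("carrier", carriers), ("non_carrier", non_carriers)):
        if cls.n_haplotypes < config.min_class_size:
            logger.warning(
                "selection: %s class not computed (%d haplotypes < %d)",
                label, cls.n_haplotypes, config.min_class_size,
            )
            classes[label] = {
                "n_haplotypes": cls.n_haplotypes, "status": "not_computed",
            }
        else:
            classes[label] = {
                "n_haplotypes": cls.n_haplotypes,
                "status": "ok",
                **_stat_block(cls, config.seed + 2),
            }
    report["classes"] = classes

    ehh_curves = {}
    for allele in (1, 0):
        try:
            ehh_curves[
                "derived" if allele == 1 else "ancestral"
            ] = ldmod.ehh(h, focal_position, allele)
        except ValueError as exc:
            logger.warning("selection: EHH for allele %d undefined: %s",
                           allele, exc)
    report["ehh"] = ehh_curves

    try:
        pairs = ldmod.pairwise_ld(h)
        report["ld_blocks"] = ldmod.gabriel_blocks(pairs, h.positions)
    except ValueError as exc:
        logger.warning("selection: LD blocks not computed: %s", exc)
        report["ld_blocks"] = []

    span = (
        region
        if region is not None
        else (int(h.positions[0]), int(h.positions[-1]) + 1)
    )
    if span[1] - span[0] >= config.window_bp:
        report["sliding_tajima"] = ss.sliding_tajima(
            h, config.window_bp, config.step_bp, span
        )
    else:
        logger.info("selection: region shorter than one window; scan skipped")
        report["sliding_tajima"] = []
    return report


def hwe_from_table(
    table: pf.GenotypeTable, variant_index: int
) -> Dict[str, Optional[float]]:
    """Per-population exact Hardy-Weinberg p-values at one variant."""
    out: Dict[str, Optional[float]] = {}
    pops = table.individuals["population"].to_numpy()
    dosages = table.calls[:, variant_index]
    for pop in table.populations():
        d = dosages[(pops == pop)]
        d = d[d != pf.MISSING]
        if len(d) == 0:
            out[pop] = None
            continue
        out[pop] = ss.hwe_exact(
            int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())
        )
    return out


def fst_between_tables(
    t1: pf.GenotypeTable,
    t2: pf.GenotypeTable,
    variant_mask: Optional[np.ndarray] = None,
    estimator: str = "hudson",
) -> Optional[float]:
    """F_ST between two genotype tables sharing a variant list.

    ``variant_mask`` selects the scope (one SNV, a gene's variants, or a
    whole chromosome); by default all shared variants enter the
    ratio-of-averages combination.
    """
    if t1.n_variants != t2.n_variants:
        raise ValueError("tables must share their variant list")
    mask = (
        np.ones(t1.n_variants, dtype=bool)
        if variant_mask is None
        else np.asarray(variant_mask, dtype=bool)
    )
    k1, n1, k2, n2 = [], [], [], []
    for j in np.flatnonzero(mask):
        a1 = pf.allele_counts(t1.calls[:, j])
        a2 = pf.allele_counts(t2.calls[:, j])
        k1.append(a1[0]); n1.append(a1[1])
        k2.append(a2[0]); n2.append(a2[1])
    return ss.fst(k1, n1, k2, n2, estimator=estimator)
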