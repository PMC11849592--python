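"""Readers and writers for VCF, BED and the tabular side files.

VCF output is plain-text VCF 4.2; genotype tables are written unphased
("0/1", "./.") and haplotype matrices phased ("0|1"), two haplotypes per
sample.  Reading goes through cyvcf2, so round-trips double as a
standards-compliance check.  BED is three-column, 0-based half-open;
chromosome sizes and population maps are two-column TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from paleoselect.popfreq import MISSING, GenotypeTable
from paleoselect.regions import IntervalSet
from paleoselect.selstats import HaplotypeMatrix

_VCF_HEADER = """##fileformat=VCFv4.2
##source=paleoselect
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _check_sorted(variants: pd.DataFrame) -> None:
    for _, group in variants.groupby("chrom", sort=False):
        pos = group["pos"].to_numpy()
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise ValueError("variant positions must be strictly increasing")


def write_vcf(data: GenotypeTable | HaplotypeMatrix, path: str | Path, *,
              chrom: str = "1", sample_prefix: str = "hap") -> None:
    """Write a genotype table or haplotype matrix as VCF 4.2.

    Haplotype matrices must have an even number of haplotypes; consecutive
    pairs become phased diploid samples.  Unsorted positions are rejected.
    """
    path = Path(path)
    if isinstance(data, GenotypeTable):
        _write_genotype_vcf(data, path)
    elif isinstance(data, HaplotypeMatrix):
        _write_haplotype_vcf(data, path, chrom, sample_prefix)
    else:
        raise TypeError("expected GenotypeTable or HaplotypeMatrix")


def _write_genotype_vcf(table: GenotypeTable, path: Path) -> None:
    _check_sorted(table.variants)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    samples = list(table.individuals["sample"])
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        contigs = table.variants["chrom"].astype(str).unique()
        for c in contigs:
            sub = table.variants[table.variants["chrom"].astype(str) == c]
            fh.write(f"##contig=<ID={c},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, var in table.variants.iterrows():
            info = "."
            if "derived" in table.variants.columns:
                ancestral = (
                    var["ref"] if var["derived"] == var["alt"] else var["alt"]
                )
                info = f"AA={ancestral}"
            gts = "\t".join(gt_map[int(d)] for d in table.calls[:, j])
            fh.write(
                f"{var['chrom']}\t{var['pos']}\t.\t{var['ref']}\t{var['alt']}"
                f"\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def _write_haplotype_vcf(
    h: HaplotypeMatrix, path: Path, chrom: str, sample_prefix: str
) -> None:
    if h.n_haplotypes % 2 != 0:
        raise ValueError("haplotype count must be even to form diploid samples")
    n_samples = h.n_haplotypes // 2
    samples = [f"{sample_prefix}{i}" for i in range(n_samples)]
    sym = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            f"##contig=<ID={chrom},length={int(h.positions[-1]) + 1000}>\n"
            if h.n_sites
            else f"##contig=<ID={chrom},length=1000>\n"
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(h.n_sites):
            gts = "\t".join(
                f"{sym[int(h.alleles[2 * i, j])]}|{sym[int(h.alleles[2 * i + 1, j])]}"
                for i in range(n_samples)
            )
            # positions are 0-based internally, VCF is 1-based
            fh.write(
                f"{chrom}\t{int(h.positions[j]) + 1}\t.\tA\tG\t.\tPASS\t"
                f"AA=A\tGT\t{gts}\n"
            )


def read_genotype_table(
    vcf_path: str | Path,
    population_map: Mapping[str, str] | None = None,
) -> GenotypeTable:
    """Read diploid genotypes from a VCF into a :class:`GenotypeTable`.

    ``population_map`` maps sample name to population label; unmapped
    samples fall into population "unknown".
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    pops = [
        (population_map or {}).get(s, "unknown") for s in samples
    ]
    chroms, positions, refs, alts, derived = [], [], [], [], []
    rows = []
    for variant in vcf:
        chroms.append(str(variant.CHROM))
        positions.append(int(variant.POS))
        refs.append(variant.REF)
        alt = variant.ALT[0] if variant.ALT else "."
        alts.append(alt)
        aa = variant.INFO.get("AA")
        derived.append(alt if aa == variant.REF else (variant.REF if aa == alt else alt))
        gts = variant.genotypes  # [allele0, allele1, phased]
        row = []
        for g in gts:
            a, b = g[0], g[1]
            row.append(MISSING if a < 0 or b < 0 else a + b)
        rows.append(row)
    vcf.close()
    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    individuals = pd.DataFrame({"sample": samples, "population": pops})
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts,
         "derived": derived}
    )
    return GenotypeTable(individuals, variants, calls)


def read_haplotype_matrix(vcf_path: str | Path) -> HaplotypeMatrix:
    """Read phased haplotypes from a VCF (two haplotypes per sample).

    Sites are polarised via the AA INFO tag when present (derived = the
    non-ancestral allele); without AA tags the matrix is flagged
    unpolarised and 1 simply means the ALT allele.
    """
    vcf = VCF(str(vcf_path))
    n_samples = len(vcf.samples)
    positions, columns = [], []
    any_aa = False
    for variant in vcf:
        aa = variant.INFO.get("AA")
        flip = bool(aa is not None and variant.ALT and aa == variant.ALT[0])
        any_aa = any_aa or aa is not None
        col = np.empty(2 * n_samples, dtype=np.int8)
        for i, g in enumerate(variant.genotypes):
            for k in (0, 1):
                a = g[k]
                if a < 0:
                    col[2 * i + k] = MISSING
                else:
                    col[2 * i + k] = (1 - a) if flip else a
        positions.append(int(variant.POS) - 1)  # to 0-based
        columns.append(col)
    vcf.close()
    alleles = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((2 * n_samples, 0), dtype=np.int8)
    )
    return HaplotypeMatrix(alleles, np.asarray(positions), polarised=any_aa)


# ---------------------------------------------------------------------------
# BED and TSV side files
# ---------------------------------------------------------------------------

def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write an interval set as BED3."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals.to_records():
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(
    path: str | Path, chrom_lengths: Mapping[str, int] | None = None
) -> IntervalSet:
    """Read a BED3+ file (extra columns ignored) into an IntervalSet."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            records.append((fields[0], int(fields[1]), int(fields[2])))
    return IntervalSet.from_records(records, chrom_lengths)


def read_chrom_sizes(path: str | Path) -> Dict[str, int]:
    """Two-column TSV: chromosome, length."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def read_population_map(path: str | Path) -> Dict[str, str]:
    """Two-column TSV: sample, population."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"])
    return dict(zip(df["sample"].astype(str), df["population"].astype(str)))


def read_admixture_events(path: str | Path) -> pd.DataFrame:
    """TSV of admixture events: offspring, parent_x, parent_y, a_x."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["offspring", "parent_x", "parent_y", "a_x"],
    )
    if ((df["a_x"] < 0) | (df["a_x"] > 1)).any():
        raise ValueError("a_x must be in [0, 1]")
    return df
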