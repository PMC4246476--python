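"""SNP density per mRNA region class, split by common/rare MAF.

Purifying selection on functional sequence shows up as depleted common-SNP
density: deleterious alleles are removed before they can reach appreciable
frequency, while rare (young) variants accumulate at the neutral rate.
Comparing seed-site (MRESS) density against the surrounding 3'UTR therefore
separates selection from mutation-rate differences.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable

from .io import Snp

MAF_COMMON = "common"
MAF_RARE = "rare"
MAF_UNKNOWN = "unknown"
MAF_CLASSES = (MAF_COMMON, MAF_RARE, MAF_UNKNOWN)


@dataclass(frozen=True)
class DensityReport:
    region: str
    maf_class: str
    snp_count: int
    total_kb: float
    density: float | None  # SNPs per kb; None when the region class is empty
    flagged: bool = False


def classify_maf(
    snp: Snp, common_threshold: float = 0.01, min_chromosomes: int = 100
) -> str:
    """``unknown`` when frequency data are absent or observed on too few
    chromosomes to be trusted; otherwise common/rare at the MAF threshold."""
    if snp.maf is None or snp.n_chromosomes < min_chromosomes:
        return MAF_UNKNOWN
    return MAF_COMMON if snp.maf >= common_threshold else MAF_RARE


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> dict[str, list[tuple[int, int]]]:
    """Merge possibly-overlapping (chrom, start, end) intervals per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def _contains(merged: dict[str, list[tuple[int, int]]], chrom: str, pos: int) -> bool:
    ivs = merged.get(chrom)
    if not ivs:
        return False
    i = bisect_right(ivs, (pos, float("inf"))) - 1
    return i >= 0 and ivs[i][0] <= pos < ivs[i][1]


def region_density(
    snps: list[Snp],
    region_intervals: dict[str, list[tuple[str, int, int]]],
    common_threshold: float = 0.01,
    min_chromosomes: int = 100,
) -> list[DensityReport]:
    """Density (SNPs/kb) per region class and MAF class.

    ``region_intervals`` maps a region class (e.g. ``5UTR``, ``CDS``,
    ``3UTR``, ``MRESS``) to genomic intervals; intervals are merged before
    length summation so no base is double-counted, and a SNP is counted in
    every region class containing it.
    """
    reports = []
    for region in sorted(region_intervals):
        merged = merge_intervals(region_intervals[region])
        total_bases = sum(e - s for ivs in merged.values() for s, e in ivs)
        total_kb = total_bases / 1000.0
        counts = dict.fromkeys(MAF_CLASSES, 0)
        for snp in snps:
            if _contains(merged, snp.chrom, snp.pos):
                counts[classify_maf(snp, common_threshold, min_chromosomes)] += 1
        for maf_class in MAF_CLASSES:
            if total_bases == 0:
                reports.append(DensityReport(region, maf_class, 0, 0.0, None, True))
            else:
                n = counts[maf_class]
                reports.append(DensityReport(region, maf_class, n, total_kb, n / total_kb))
    return reports
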