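"""GWAS p-value inheritance through LD proxies, QQ data, enrichment odds ratio.

A seed-site SNP is usually not genotyped on the array; its association
evidence is carried by proxies — genotyped SNPs in complete LD (D' >= 1 by
default) with it. The SNP inherits the minimum p-value over itself (if
genotyped) and its proxies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class GwasAssignment:
    mress_snp_id: str
    dataset_id: str
    proxy_ids: tuple[str, ...]
    inherited_p: float


@dataclass(frozen=True)
class EnrichmentOR:
    """2x2 enrichment of small p-values among seed-site SNPs.

    Cells: a = MRESS & p<=alpha, b = MRESS & p>alpha, c = background &
    p<=alpha, d = background & p>alpha. ``haldane`` marks a zero cell handled
    by adding 0.5 to every cell before forming the ratio.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    fisher_p: float
    haldane: bool


def assign_pvalues(
    mress_snp_ids: list[str],
    gwas_table: dict[str, float],
    ld_pairs: list[tuple[str, str, float, float]],
    dprime_min: float = 1.0,
    dataset_id: str = "",
) -> tuple[list[GwasAssignment], dict[str, int]]:
    """Inherit the minimum GWAS p-value over each SNP's D'-proxies.

    Proxies are genotyped SNPs with D' >= ``dprime_min`` to the seed-site
    SNP, plus the SNP itself when genotyped. SNPs without any proxy are
    absent from the output and counted in the report.
    """
    neighbors: dict[str, set[str]] = {}
    for a, b, dp, _r2 in ld_pairs:
        if dp >= dprime_min:
            neighbors.setdefault(a, set()).add(b)
            neighbors.setdefault(b, set()).add(a)
    assignments = []
    report = {"assigned": 0, "no_proxy": 0}
    for snp in sorted(set(mress_snp_ids)):
        proxies = {t for t in neighbors.get(snp, ()) if t in gwas_table}
        if snp in gwas_table:
            proxies.add(snp)
        if not proxies:
            report["no_proxy"] += 1
            continue
        inherited = min(gwas_table[t] for t in proxies)
        assignments.append(
            GwasAssignment(snp, dataset_id, tuple(sorted(proxies)), inherited)
        )
        report["assigned"] += 1
    return assignments, report


def qq_data(
    pvalues: list[float], p_floor: float = 1e-300
) -> list[tuple[float, float]]:
    """(expected, observed) -log10(p) pairs for a QQ plot.

    Observed values are sorted descending; the expected value at rank i is
    -log10((i - 0.5) / n), the usual uniform-order-statistic midpoint.
    """
    if not pvalues:
        raise ValueError("qq_data requires at least one p-value")
    capped = []
    for p in pvalues:
        if p <= 0:
            warnings.warn(f"p-value {p} <= 0 capped at {p_floor}")
            p = p_floor
        capped.append(p)
    observed = sorted((-math.log10(p) for p in capped), reverse=True)
    n = len(observed)
    return [(-math.log10((i - 0.5) / n), obs) for i, obs in enumerate(observed, start=1)]


def enrichment_or(
    assigned_pvalues: list[float],
    background_pvalues: list[float],
    alpha: float = 0.05,
) -> EnrichmentOR:
    """Over-representation of seed-site SNPs among nominally significant SNPs."""
    a = sum(p <= alpha for p in assigned_pvalues)
    b = len(assigned_pvalues) - a
    c = sum(p <= alpha for p in background_pvalues)
    d = len(background_pvalues) - c
    _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = 0 in (a, b, c, d)
    if haldane:
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsr = (a * d) / (b * c)
    return EnrichmentOR(a, b, c, d, oddsr, float(fisher_p), haldane)
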