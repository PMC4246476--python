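"""End-to-end orchestration: from inputs to candidate causal seed-site SNPs.

The stages mirror the analysis workflow: scan 3'UTRs allele-aware for
seed-site gains/losses, inherit GWAS p-values through LD proxies, apply the
biological-context filter, then score and annotate the candidates.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from .context import ContextSelection, run_context_selection
from .gwas import GwasAssignment, assign_pvalues
from .io import PipelineConfig, Snp, Transcript
from .seeds import AllelicSiteEffect, SeedGroup, call_allelic_effects, extract_seeds


def snps_in_utr3(
    transcripts: list[Transcript], snps: list[Snp]
) -> dict[str, list[Snp]]:
    """Map each transcript to the SNPs inside its 3'UTR."""
    by_chrom: dict[str, list[Snp]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.pos)
    out: dict[str, list[Snp]] = {}
    for t in transcripts:
        lst = by_chrom.get(t.chrom, [])
        positions = [s.pos for s in lst]
        hits: list[Snp] = []
        for gs, ge in t.utr3_genomic_intervals():
            lo = bisect_left(positions, gs)
            hi = bisect_right(positions, ge - 1)
            hits.extend(lst[lo:hi])
        if hits:
            out[t.transcript_id] = hits
    return out


@dataclass
class ScanResult:
    effects: list[AllelicSiteEffect]
    snp_genes: dict[str, set[str]]
    mress_snp_ids: set[str]
    snp_site_types: dict[str, set[str]] = field(default_factory=dict)


def scan_all_effects(
    transcripts: list[Transcript],
    snps: list[Snp],
    seed_groups: list[SeedGroup],
    flank: int = 50,
) -> ScanResult:
    """Allele-aware scan of every 3'UTR SNP against every seed group.

    A SNP with at least one create/loss effect is a seed-site (MRESS) SNP.
    """
    by_tx = snps_in_utr3(transcripts, snps)
    effects: list[AllelicSiteEffect] = []
    snp_genes: dict[str, set[str]] = {}
    site_types: dict[str, set[str]] = {}
    for t in transcripts:
        for snp in by_tx.get(t.transcript_id, []):
            effs = call_allelic_effects(t, snp, seed_groups, flank=flank)
            effects.extend(effs)
            for e in effs:
                snp_genes.setdefault(e.snp_id, set()).add(e.gene)
                site_types.setdefault(e.snp_id, set()).add(e.site_type)
    return ScanResult(
        effects=effects,
        snp_genes=snp_genes,
        mress_snp_ids=set(snp_genes),
        snp_site_types=site_types,
    )


@dataclass
class DatasetResult:
    dataset_id: str
    assignments: list[GwasAssignment]
    assignment_report: dict[str, int]
    selection: ContextSelection


def run_selection(
    scan: ScanResult,
    gwas: dict[str, dict[str, float]],
    ld_pairs: list[tuple[str, str, float, float]],
    disease_genes: dict[str, set[str]],
    annotations: dict[str, set[str]],
    background_genes: set[str],
    config: PipelineConfig | None = None,
) -> dict[str, DatasetResult]:
    """LD-proxy assignment plus context selection for every GWAS dataset."""
    config = config or PipelineConfig()
    results: dict[str, DatasetResult] = {}
    for ds in sorted(gwas):
        assignments, report = assign_pvalues(
            sorted(scan.mress_snp_ids), gwas[ds], ld_pairs,
            dprime_min=config.dprime_min, dataset_id=ds,
        )
        selection = run_context_selection(
            ds,
            assignments,
            scan.snp_genes,
            disease_genes.get(ds, set()),
            annotations,
            background_genes,
            p_snp=config.p_snp,
            p_go=config.p_go,
        )
        results[ds] = DatasetResult(ds, assignments, report, selection)
    return results


def seed_groups_from_mirnas(mirnas: list[tuple[str, str]]) -> list[SeedGroup]:
    return extract_seeds(mirnas)
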