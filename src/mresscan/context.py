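"""Biological-context selection of candidate causal seed-site SNPs.

Instead of multiple-testing correction, credibility comes from context: host
genes of nominally significant (p <= 0.01) seed-site SNPs are tested for
GO biological-process enrichment, the enriched terms are intersected with
the terms enriched among known disease genes, and only SNPs whose host gene
is annotated to an overlapping term survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats

from .gwas import GwasAssignment


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric upper-tail enrichment of one term in a query gene set."""

    term_id: str
    k: int  # query genes annotated to the term
    K: int  # background genes annotated to the term
    n: int  # query size
    N: int  # background size
    p: float


@dataclass(frozen=True)
class ContextSelection:
    dataset_id: str
    enriched_query_terms: frozenset[str]
    enriched_disease_terms: frozenset[str]
    overlap_terms: frozenset[str]
    overlap_fisher_p: float
    candidate_snps: frozenset[str]
    candidate_genes: frozenset[str]


def go_enrich(
    query_genes: set[str],
    annotations: dict[str, set[str]],
    background_genes: set[str],
    p_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """One raw hypergeometric upper-tail test per term with >= 1 query gene.

    p = P(X >= k) under Hypergeometric(N, K, n). No multiple-testing
    correction is applied by default: the selection design deliberately
    trades corrected term lists for the downstream overlap filter (see
    :func:`overlap_test`). Use :func:`enriched_terms` to threshold.
    """
    if not query_genes:
        warnings.warn("empty query gene set; no enrichment computed")
        return []
    if not query_genes <= background_genes:
        raise ValueError("query genes must be a subset of the background")
    N = len(background_genes)
    n = len(query_genes)
    term_background: dict[str, int] = {}
    term_query: dict[str, int] = {}
    for gene in background_genes:
        for term in annotations.get(gene, ()):
            term_background[term] = term_background.get(term, 0) + 1
    for gene in query_genes:
        for term in annotations.get(gene, ()):
            term_query[term] = term_query.get(term, 0) + 1
    results = []
    for term in sorted(term_query):
        k = term_query[term]
        K = term_background[term]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, K, n, N, min(p, 1.0)))
    return results


def enriched_terms(results: list[EnrichmentResult], p_threshold: float = 0.05) -> set[str]:
    return {r.term_id for r in results if r.p <= p_threshold}


def overlap_test(
    enriched_query_terms: set[str],
    enriched_disease_terms: set[str],
    term_universe: set[str],
) -> tuple[set[str], float]:
    """One-sided Fisher exact test for over-representation of shared terms.

    The 2x2 table partitions the term universe into (in both lists,
    query-only, disease-only, neither).
    """
    if not term_universe:
        raise ValueError("empty term universe")
    if not (enriched_query_terms <= term_universe and enriched_disease_terms <= term_universe):
        raise ValueError("term sets must be subsets of the universe")
    both = enriched_query_terms & enriched_disease_terms
    a = len(both)
    b = len(enriched_query_terms - enriched_disease_terms)
    c = len(enriched_disease_terms - enriched_query_terms)
    d = len(term_universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return both, float(p)


def select_candidates(
    assignments: list[GwasAssignment],
    snp_genes: dict[str, set[str]],
    overlap_terms: set[str],
    annotations: dict[str, set[str]],
    p_snp: float = 0.01,
) -> tuple[set[str], set[str]]:
    """Candidate SNPs: inherited p <= ``p_snp`` AND a host gene annotated to
    at least one overlap term. Returns (candidate SNPs, candidate genes).

    ``snp_genes`` maps each SNP to its host genes (a SNP in two genes' 3'UTRs
    counts for both).
    """
    candidate_snps: set[str] = set()
    candidate_genes: set[str] = set()
    for a in assignments:
        if a.inherited_p > p_snp:
            continue
        hits = {
            g
            for g in snp_genes.get(a.mress_snp_id, ())
            if annotations.get(g, set()) & overlap_terms
        }
        if hits:
            candidate_snps.add(a.mress_snp_id)
            candidate_genes.update(hits)
    return candidate_snps, candidate_genes


def run_context_selection(
    dataset_id: str,
    assignments: list[GwasAssignment],
    snp_genes: dict[str, set[str]],
    disease_genes: set[str],
    annotations: dict[str, set[str]],
    background_genes: set[str],
    p_snp: float = 0.01,
    p_go: float = 0.05,
    term_universe: set[str] | None = None,
) -> ContextSelection:
    """The full selection workflow for one GWAS dataset.

    1. host genes of SNPs with inherited p <= ``p_snp``;
    2. GO enrichment of those hosts and of the disease gene list, both
       against ``background_genes``;
    3. one-sided Fisher overlap test of the two enriched-term lists over the
       term universe (by default every term with >= 1 annotated background
       gene);
    4. candidates = significant SNPs whose host gene carries an overlap term.
    """
    sig_snps = [a for a in assignments if a.inherited_p <= p_snp]
    query_genes = set().union(*(snp_genes.get(a.mress_snp_id, set()) for a in sig_snps)) if sig_snps else set()
    query_genes &= background_genes
    disease_in_bg = disease_genes & background_genes
    q_terms = enriched_terms(go_enrich(query_genes, annotations, background_genes), p_go) if query_genes else set()
    d_terms = enriched_terms(go_enrich(disease_in_bg, annotations, background_genes), p_go) if disease_in_bg else set()
    if term_universe is None:
        term_universe = set().union(
            *(annotations.get(g, set()) for g in background_genes)
        ) if background_genes else set()
    if term_universe and (q_terms or d_terms):
        overlap, fisher_p = overlap_test(q_terms & term_universe, d_terms & term_universe, term_universe)
    else:
        overlap, fisher_p = set(), 1.0
    snps, genes = select_candidates(assignments, snp_genes, overlap, annotations, p_snp)
    return ContextSelection(
        dataset_id=dataset_id,
        enriched_query_terms=frozenset(q_terms),
        enriched_disease_terms=frozenset(d_terms),
        overlap_terms=frozenset(overlap),
        overlap_fisher_p=fisher_p,
        candidate_snps=frozenset(snps),
        candidate_genes=frozenset(genes),
    )
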