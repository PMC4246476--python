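"""MicroRNA-gene-disease three-way interactions.

A validated microRNA-gene interaction whose two partners are independently
linked to the same disease is taken to be disease-associated itself; any
seed-site SNP able to create or abolish that interaction is then a
disease-relevant perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seeds import AllelicSiteEffect


@dataclass(frozen=True)
class TrilateralInteraction:
    mirna: str
    gene: str
    disease: str


def normalize_disease(name: str, synonyms: dict[str, str] | None = None) -> str:
    key = " ".join(name.strip().casefold().split())
    if synonyms:
        key = synonyms.get(key, key)
    return key


def build_trilateral(
    mirna_gene: list[tuple[str, str]],
    mirna_disease: list[tuple[str, str]],
    gene_disease: list[tuple[str, str]],
    synonyms: dict[str, str] | None = None,
) -> list[TrilateralInteraction]:
    """All (microRNA, gene, disease) triples where the interaction partners
    share the disease; deduplicated, deterministic order."""
    mir_dis: dict[str, set[str]] = {}
    for m, d in mirna_disease:
        mir_dis.setdefault(m, set()).add(normalize_disease(d, synonyms))
    gene_dis: dict[str, set[str]] = {}
    for g, d in gene_disease:
        gene_dis.setdefault(g, set()).add(normalize_disease(d, synonyms))
    triples = {
        TrilateralInteraction(m, g, d)
        for m, g in set(mirna_gene)
        for d in mir_dis.get(m, set()) & gene_dis.get(g, set())
    }
    return sorted(triples, key=lambda t: (t.mirna, t.gene, t.disease))


def snps_perturbing(
    interactions: list[TrilateralInteraction],
    effects: list[AllelicSiteEffect],
) -> dict[str, set[str]]:
    """SNPs whose create/loss effects touch a disease-linked interaction.

    Returns ``{snp_id: diseases}``; a SNP hitting several triples gets all
    their diseases on one record.
    """
    pair_diseases: dict[tuple[str, str], set[str]] = {}
    for t in interactions:
        pair_diseases.setdefault((t.mirna, t.gene), set()).add(t.disease)
    flagged: dict[str, set[str]] = {}
    for eff in effects:
        for mirna in eff.members:
            diseases = pair_diseases.get((mirna, eff.gene))
            if diseases:
                flagged.setdefault(eff.snp_id, set()).update(diseases)
    return flagged
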