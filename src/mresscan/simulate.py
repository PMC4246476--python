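"""Synthetic input generator with the statistical structure the pipeline assumes.

Everything the pipeline consumes can be generated here with planted ground
truth: seed-match sites written into random 3'UTRs, SNPs that create or
abolish those sites, purifying selection on site footprints (thinned
common-SNP rate), LD blocks whose genotyped members carry the association
signal of a causal block, GO annotations that make causal host genes share
biological context with the disease gene list, negatively correlated
co-expression for causal-affected interactions, and a mouse ortholog with
planted sites protected from divergence.

One integer seed drives a single numpy Generator stream; identical seeds
give byte-identical output directories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .io import EvidenceBundle, Snp, Transcript, to_file_coords
from .seeds import RNA_COMPLEMENT, revcomp

BASES = np.array(list("ACGU"))
DNA_OF = {"A": "A", "C": "C", "G": "G", "U": "T"}
DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    The defaults are the conditions every downstream test assumes; override
    sizes for quick runs, not the signal structure.
    """

    seed: int = 0
    n_genes: int = 2000
    n_mirnas: int = 200
    n_snps: int = 50_000
    n_datasets: int = 1
    utr_length_range: tuple[int, int] = (200, 2000)
    utr5_length_range: tuple[int, int] = (100, 300)
    cds_length_range: tuple[int, int] = (300, 1500)
    sites_per_gene_max: int = 3
    # purifying selection: multiplicative thinning of common SNPs in MRESSs
    mress_common_snp_multiplier: float = 0.5
    maf_class_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)  # common, rare, unknown
    # causal signal
    n_causal: int = 20
    frac_causal: float | None = None  # overrides n_causal as a fraction of planted sites
    causal_p_beta: tuple[float, float] = (0.1, 1.0)
    # LD structure
    ld_block_size: int = 5
    dprime_within_block: float = 1.0
    genotyped_frac: float = 0.6
    # biological context
    go_terms: int = 500
    terms_per_gene: int = 4
    n_disease_terms: int = 12
    disease_term_overlap: float = 0.75
    n_disease_genes: int = 100
    # co-expression
    coexpr_true_dist: tuple[float, float] = (-0.2, 0.15)
    coexpr_null_dist: tuple[float, float] = (0.05, 0.2)
    n_coexpr_background: int = 2000
    # mouse ortholog
    mouse_divergence: float = 0.15
    site_conservation: float = 1.0
    # positives list
    positives_frac_of_causal: float = 0.6
    positives_background_rate: float = 0.02

    def validate(self) -> None:
        for name in ("mress_common_snp_multiplier", "genotyped_frac", "disease_term_overlap",
                     "site_conservation", "positives_frac_of_causal", "positives_background_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        if self.frac_causal is not None and not (0.0 <= self.frac_causal <= 1.0):
            raise ConfigError("frac_causal must lie in [0,1]")
        if abs(sum(self.maf_class_probs) - 1.0) > 1e-9:
            raise ConfigError("maf_class_probs must sum to 1")
        if self.utr_length_range[0] < 60:
            raise ConfigError("minimum 3'UTR length must be >= 60 to hold planted sites")
        if self.ld_block_size < 2:
            raise ConfigError("ld_block_size must be >= 2")


@dataclass(frozen=True)
class PlantedSite:
    transcript_id: str
    gene: str
    start: int
    end: int
    site_type: str
    mirna: str


@dataclass(frozen=True)
class PlantedEffect:
    snp_id: str
    transcript_id: str
    gene: str
    mirna: str
    effect: str
    site_type: str
    utr_offset: int


@dataclass
class TruthSet:
    causal_snps: set[str] = field(default_factory=set)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    disease_terms: set[str] = field(default_factory=set)


@dataclass
class SimBundle:
    """In-memory result of one simulation."""

    config: SimConfig
    mirnas: list[tuple[str, str]]
    transcripts: list[Transcript]
    snps: list[Snp]
    mouse_utr3: dict[str, str]
    evidence: EvidenceBundle
    mirna_gene: list[tuple[str, str]]
    truth: TruthSet

    def region_intervals(self) -> dict[str, list[tuple[str, int, int]]]:
        """Genomic intervals per region class, including the MRESS class."""
        out: dict[str, list[tuple[str, int, int]]] = {"5UTR": [], "CDS": [], "3UTR": [], "MRESS": []}
        by_id = {t.transcript_id: t for t in self.transcripts}
        for t in self.transcripts:
            for rt, s, e in t.regions:
                out[rt].append((t.chrom, s, e))
        for site in self.truth.planted_sites:
            t = by_id[site.transcript_id]
            gpos = sorted(t.utr_offset_to_genomic(o) for o in range(site.start, site.end))
            out["MRESS"].append((t.chrom, gpos[0], gpos[-1] + 1))
        return out

    def write(self, outdir: str | Path) -> None:
        write_bundle(self, Path(outdir))


def _rand_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(BASES[rng.integers(0, 4, size=n)])


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in "ACGU" if b not in exclude]
    return choices[int(rng.integers(0, len(choices)))]


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Generate the full input bundle in memory."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- microRNAs -------------------------------------------------------
    mirnas = [
        (f"syn-miR-{i + 1:03d}", "".join(_rand_seq(rng, 22)))
        for i in range(config.n_mirnas)
    ]
    mirna_ids = [m for m, _ in mirnas]
    mirna_seq = dict(mirnas)

    # --- transcripts with planted seed-match sites -----------------------
    transcripts: list[Transcript] = []
    utr_seqs: dict[str, list[str]] = {}
    planted_sites: list[PlantedSite] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    cursors: dict[str, int] = {}
    site_type_choices = ["7mer(1-7)", "7mer(2-8)", "8mer-1a", "8mer"]

    for gi in range(config.n_genes):
        tx_id = f"NM_SYN{gi + 1:06d}"
        gene = f"GENE{gi + 1:04d}"
        chrom = str(1 + gi % 22)
        strand = "+" if rng.random() < 0.5 else "-"
        l5 = int(rng.integers(*config.utr5_length_range))
        lc = int(rng.integers(*config.cds_length_range))
        l3 = int(rng.integers(*config.utr_length_range))
        seq = _rand_seq(rng, l3)
        occ: list[tuple[int, int]] = []
        n_sites = int(rng.integers(1, config.sites_per_gene_max + 1))
        for _ in range(n_sites):
            mirna = mirna_ids[int(rng.integers(0, len(mirna_ids)))]
            mat = mirna_seq[mirna]
            stype = site_type_choices[int(rng.integers(0, 4))]
            if stype == "8mer-1a" and mat[0] == "U":
                stype = "8mer"  # an A opposite position 1 U is a full 8mer
            for _attempt in range(20):
                pos = int(rng.integers(1, l3 - 10))
                width = 8 if stype in ("8mer", "8mer-1a") else 7
                lo, hi = pos - 1, pos + width + 1
                if all(hi <= s or lo >= e for s, e in occ):
                    break
            else:
                continue
            if stype == "7mer(1-7)":
                pattern = revcomp(mat[0:7])
                seq[pos : pos + 7] = list(pattern)
                seq[pos - 1] = _other_base(rng, RNA_COMPLEMENT[mat[7]])
                end = pos + 7
            elif stype == "7mer(2-8)":
                pattern = revcomp(mat[1:8])
                seq[pos : pos + 7] = list(pattern)
                seq[pos + 7] = _other_base(rng, RNA_COMPLEMENT[mat[0]], "A")
                end = pos + 7
            elif stype == "8mer-1a":
                pattern = revcomp(mat[1:8]) + "A"
                seq[pos : pos + 8] = list(pattern)
                end = pos + 8
            else:  # 8mer
                pattern = revcomp(mat[0:8])
                seq[pos : pos + 8] = list(pattern)
                end = pos + 8
            occ.append((pos - 1, end + 1))
            planted_sites.append(PlantedSite(tx_id, gene, pos, end, stype, mirna))
        occupied[tx_id] = occ
        utr_seqs[tx_id] = seq

        cur = cursors.get(chrom, 1000)
        if strand == "+":
            regions = [
                ("5UTR", cur, cur + l5),
                ("CDS", cur + l5, cur + l5 + lc),
                ("3UTR", cur + l5 + lc, cur + l5 + lc + l3),
            ]
        else:
            regions = [
                ("3UTR", cur, cur + l3),
                ("CDS", cur + l3, cur + l3 + lc),
                ("5UTR", cur + l3 + lc, cur + l3 + lc + l5),
            ]
        cursors[chrom] = cur + l5 + lc + l3 + 500
        transcripts.append(
            Transcript(tx_id, gene, chrom, strand, regions, "".join(seq))
        )

    by_id = {t.transcript_id: t for t in transcripts}

    # --- causal SNPs (half loss, half create) ----------------------------
    n_causal = config.n_causal
    if config.frac_causal is not None:
        n_causal = int(round(config.frac_causal * len(planted_sites)))
    genes_with_sites = sorted({s.transcript_id for s in planted_sites})
    if n_causal > len(genes_with_sites):
        raise ConfigError(
            f"{n_causal} causal SNPs requested but only {len(genes_with_sites)} "
            "genes carry planted sites"
        )
    truth = TruthSet()
    causal_records: list[tuple[Snp, PlantedEffect]] = []
    site_by_tx: dict[str, list[PlantedSite]] = {}
    for s in planted_sites:
        site_by_tx.setdefault(s.transcript_id, []).append(s)
    chosen_tx = [genes_with_sites[i] for i in rng.choice(len(genes_with_sites), size=n_causal, replace=False)] if n_causal else []
    for ci, tx_id in enumerate(sorted(chosen_tx)):
        t = by_id[tx_id]
        snp_id = f"rsC{ci + 1:05d}"
        if ci % 2 == 0:
            # loss: break a planted site at its most G/C-stacked core position
            # (causal variants are planted where the thermodynamic consequence
            # is largest, the premise behind comparing candidate |ddG|)
            site = site_by_tx[tx_id][0]
            seq_site = t.utr3_sequence[site.start : site.end]

            def stack_weight(p: int) -> int:
                return sum(seq_site[q] in "GC" for q in (p - 1, p, p + 1))

            core = range(1, len(seq_site) - 1)
            p_best = max(core, key=lambda p: (stack_weight(p), -p))
            off = site.start + p_best
            ref_sense = t.utr3_sequence[off]
            alt_sense = _other_base(rng, ref_sense)
            effect = "loss"
            stype, mirna = site.site_type, site.mirna
        else:
            # create: a near-site whose alternate allele completes the match;
            # prefer a G/C-rich seed so the created duplex is strong
            draws = [mirna_ids[int(rng.integers(0, len(mirna_ids)))] for _ in range(5)]
            mirna = max(draws, key=lambda m: sum(b in "GC" for b in mirna_seq[m][1:8]))
            mat = mirna_seq[mirna]
            pattern = list(revcomp(mat[1:8]))
            seq = list(t.utr3_sequence)
            occ = occupied[tx_id]
            for _attempt in range(50):
                pos = int(rng.integers(1, len(seq) - 10))
                if all(pos + 9 <= s or pos - 1 >= e for s, e in occ):
                    break
            else:
                raise ConfigError("could not place a create-type causal SNP; enlarge UTRs")
            correct = pattern[3]
            wrong = _other_base(rng, correct)
            pattern[3] = wrong
            seq[pos : pos + 7] = pattern
            seq[pos + 7] = _other_base(rng, RNA_COMPLEMENT[mat[0]], "A")
            occ.append((pos - 1, pos + 9))
            t.utr3_sequence = "".join(seq)
            off = pos + 3
            ref_sense, alt_sense = wrong, correct
            effect = "create"
            stype = "7mer(2-8)"
        gpos = t.utr_offset_to_genomic(off)
        ref_dna = DNA_OF[ref_sense] if t.strand == "+" else DNA_COMP[DNA_OF[ref_sense]]
        alt_dna = DNA_OF[alt_sense] if t.strand == "+" else DNA_COMP[DNA_OF[alt_sense]]
        snp = Snp(snp_id, t.chrom, gpos, ref_dna, alt_dna,
                  maf=float(rng.uniform(0.05, 0.5)), n_chromosomes=2000)
        eff = PlantedEffect(snp_id, tx_id, t.gene_symbol, mirna, effect, stype, off)
        causal_records.append((snp, eff))
        truth.causal_snps.add(snp_id)
        truth.planted_effects.append(eff)
    truth.planted_sites = planted_sites

    # --- background SNPs over all regions, with purifying selection ------
    flat: list[tuple[str, int, int, str, str]] = []  # chrom, start, end, region, tx
    for t in transcripts:
        for rt, s, e in t.regions:
            flat.append((t.chrom, s, e, rt, t.transcript_id))
    lengths = np.array([e - s for _, s, e, _, _ in flat])
    cum = np.concatenate([[0], np.cumsum(lengths)])
    total = int(cum[-1])
    n_draw = min(config.n_snps, total)
    linear = rng.choice(total, size=n_draw, replace=False)
    linear.sort()
    idx = np.searchsorted(cum, linear, side="right") - 1
    maf_class = rng.choice(3, size=n_draw, p=list(config.maf_class_probs))
    keep_u = rng.random(n_draw)

    # genomic MRESS footprints for the thinning test
    mress_pos: set[tuple[str, int]] = set()
    for site in planted_sites:
        t = by_id[site.transcript_id]
        for o in range(site.start, site.end):
            mress_pos.add((t.chrom, t.utr_offset_to_genomic(o)))

    causal_pos = {(s.chrom, s.pos) for s, _ in causal_records}
    snps: list[Snp] = [s for s, _ in causal_records]
    maf_vals = rng.random(n_draw)
    chrom_small = rng.integers(2, 99, size=n_draw)
    for j in range(n_draw):
        ci = int(idx[j])
        chrom, rs, _re, region, tx_id = flat[ci]
        gpos = int(rs + (linear[j] - cum[ci]))
        if (chrom, gpos) in causal_pos:
            continue
        cls = int(maf_class[j])
        in_mress = (chrom, gpos) in mress_pos
        if cls == 0 and in_mress and keep_u[j] >= config.mress_common_snp_multiplier:
            continue  # purifying selection removes the common variant
        t = by_id[tx_id]
        if region == "3UTR":
            off = t.genomic_to_utr_offset(gpos)
            sense_ref = t.utr3_sequence[off]
            ref = DNA_OF[sense_ref] if t.strand == "+" else DNA_COMP[DNA_OF[sense_ref]]
        else:
            ref = "ACGT"[int(rng.integers(0, 4))]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
        if cls == 0:
            maf, nchrom = 0.01 + 0.49 * float(maf_vals[j]), 2000
        elif cls == 1:
            maf, nchrom = 0.0005 + 0.0095 * float(maf_vals[j]), 2000
        else:
            maf, nchrom = 0.5 * float(maf_vals[j]), int(chrom_small[j])
        snps.append(Snp(f"rsB{j + 1:06d}", chrom, gpos, ref, alt, maf=maf, n_chromosomes=nchrom))
    snps.sort(key=lambda s: (int(s.chrom), s.pos, s.snp_id))

    # --- LD blocks and GWAS p-values -------------------------------------
    evidence = EvidenceBundle()
    blocks: list[list[Snp]] = [
        snps[i : i + config.ld_block_size] for i in range(0, len(snps), config.ld_block_size)
    ]
    genotyped: list[str] = []
    causal_block_geno: dict[int, list[str]] = {}
    for bi, block in enumerate(blocks):
        ids = [s.snp_id for s in block]
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                evidence.ld_pairs.append(
                    (a, b, config.dprime_within_block, float(rng.uniform(0.8, 1.0)))
                )
        geno = [sid for sid in ids if rng.random() < config.genotyped_frac]
        if not geno:
            geno = [ids[int(rng.integers(0, len(ids)))]]
        genotyped.extend(geno)
        if any(sid in truth.causal_snps for sid in ids):
            causal_block_geno[bi] = geno
    causal_geno = {sid for geno in causal_block_geno.values() for sid in geno}
    a_beta, b_beta = config.causal_p_beta
    for ds in range(config.n_datasets):
        table: dict[str, float] = {}
        for sid in genotyped:
            if sid in causal_geno:
                p = float(rng.beta(a_beta, b_beta))
            else:
                p = float(rng.uniform(0.0, 1.0))
            table[sid] = min(max(p, 1e-300), 1.0)
        evidence.gwas[f"ds{ds + 1}"] = table

    # --- GO annotations and disease genes --------------------------------
    all_terms = [f"GO:{i + 1:07d}" for i in range(config.go_terms)]
    disease_terms = all_terms[: config.n_disease_terms]
    truth.disease_terms = set(disease_terms)
    causal_genes = {e.gene for e in truth.planted_effects}
    annotations: dict[str, set[str]] = {}
    for t in transcripts:
        g = t.gene_symbol
        if g in annotations:
            continue
        terms: set[str] = set()
        biased = g in causal_genes
        while len(terms) < config.terms_per_gene:
            if biased and rng.random() < config.disease_term_overlap:
                terms.add(disease_terms[int(rng.integers(0, len(disease_terms)))])
            else:
                terms.add(all_terms[int(rng.integers(0, len(all_terms)))])
        annotations[g] = terms
    evidence.go_annotations = annotations
    non_causal = sorted(set(annotations) - causal_genes)
    picked = [non_causal[i] for i in rng.choice(len(non_causal), size=min(config.n_disease_genes, len(non_causal)), replace=False)]
    for g in picked:
        terms = set()
        while len(terms) < config.terms_per_gene:
            if rng.random() < config.disease_term_overlap:
                terms.add(disease_terms[int(rng.integers(0, len(disease_terms)))])
            else:
                terms.add(all_terms[int(rng.integers(0, len(all_terms)))])
        annotations[g] = terms
    for ds in range(config.n_datasets):
        evidence.disease_genes[f"ds{ds + 1}"] = set(picked)

    # --- trilateral evidence and co-expression ---------------------------
    disease = "synthetic disease"
    mirna_gene = sorted({(e.mirna, e.gene) for e in truth.planted_effects})
    extra = [(mirna_ids[int(rng.integers(0, len(mirna_ids)))], f"GENE{int(rng.integers(0, config.n_genes)) + 1:04d}") for _ in range(50)]
    mirna_gene = sorted(set(mirna_gene) | set(extra))
    evidence.mirna_disease = sorted({(m, disease) for m, _ in mirna_gene if rng.random() < 0.7})
    evidence.gene_disease = sorted({(g, disease) for _, g in mirna_gene if rng.random() < 0.7})
    mu1, s1 = config.coexpr_true_dist
    mu0, s0 = config.coexpr_null_dist
    for m, g in sorted({(e.mirna, e.gene) for e in truth.planted_effects}):
        evidence.coexpression[(m, g)] = float(np.clip(rng.normal(mu1, s1), -1, 1))
    for _ in range(config.n_coexpr_background):
        m = mirna_ids[int(rng.integers(0, len(mirna_ids)))]
        g = f"GENE{int(rng.integers(0, config.n_genes)) + 1:04d}"
        if (m, g) not in evidence.coexpression:
            evidence.coexpression[(m, g)] = float(np.clip(rng.normal(mu0, s0), -1, 1))

    # --- positives -------------------------------------------------------
    for sid in sorted(truth.causal_snps):
        if rng.random() < config.positives_frac_of_causal:
            evidence.positives.add(sid)
    for s in snps:
        if s.snp_id not in truth.causal_snps and rng.random() < config.positives_background_rate:
            if (s.chrom, s.pos) in mress_pos:
                evidence.positives.add(s.snp_id)

    # --- mouse orthologs --------------------------------------------------
    protected: dict[str, set[int]] = {t.transcript_id: set() for t in transcripts}
    for site in planted_sites:
        if rng.random() < config.site_conservation:
            protected[site.transcript_id].update(range(site.start, site.end))
    mouse: dict[str, str] = {}
    for t in transcripts:
        seq = list(t.utr3_sequence)
        subs = rng.random(len(seq)) < config.mouse_divergence
        for i in np.flatnonzero(subs):
            if int(i) in protected[t.transcript_id]:
                continue
            seq[int(i)] = _other_base(rng, seq[int(i)])
        mouse[t.transcript_id] = "".join(seq)

    evidence.validate()
    return SimBundle(
        config=config,
        mirnas=mirnas,
        transcripts=transcripts,
        snps=snps,
        mouse_utr3=mouse,
        evidence=evidence,
        mirna_gene=mirna_gene,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Disk output


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_bundle(bundle: SimBundle, outdir: Path) -> None:
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    _write_fasta(outdir / "mirna.fa", bundle.mirnas)
    _write_fasta(outdir / "utr3_human.fa", [(t.transcript_id, t.utr3_sequence) for t in bundle.transcripts])
    _write_fasta(outdir / "utr3_mouse.fa", sorted(bundle.mouse_utr3.items()))
    with open(outdir / "regions.tsv", "w") as fh:
        fh.write("transcript\tgene\tchrom\tstrand\tregion_type\tstart\tend\n")
        for t in bundle.transcripts:
            for rt, s, e in t.regions:
                fh.write(f"{t.transcript_id}\t{t.gene_symbol}\t{t.chrom}\t{t.strand}\t{rt}\t{to_file_coords(s)}\t{e}\n")
    with open(outdir / "snps.tsv", "w") as fh:
        fh.write("snp_id\tchrom\tpos\tref\talt\tmaf\tn_chromosomes\n")
        for s in bundle.snps:
            maf = "" if s.maf is None else format(s.maf, ".6g")
            fh.write(f"{s.snp_id}\t{s.chrom}\t{to_file_coords(s.pos)}\t{s.ref_allele}\t{s.alt_allele}\t{maf}\t{s.n_chromosomes}\n")
    ev = bundle.evidence
    with open(outdir / "gwas.tsv", "w") as fh:
        fh.write("dataset\tsnp_id\tp\n")
        for ds in sorted(ev.gwas):
            for sid, p in sorted(ev.gwas[ds].items()):
                fh.write(f"{ds}\t{sid}\t{format(p, '.10g')}\n")
    with open(outdir / "ld.tsv", "w") as fh:
        fh.write("snpA\tsnpB\tdprime\tr2\n")
        for a, b, dp, r2 in ev.ld_pairs:
            fh.write(f"{a}\t{b}\t{format(dp, '.6g')}\t{format(r2, '.6g')}\n")
    with open(outdir / "go.tsv", "w") as fh:
        fh.write("gene\tterm\n")
        for g in sorted(ev.go_annotations):
            for term in sorted(ev.go_annotations[g]):
                fh.write(f"{g}\t{term}\n")
    with open(outdir / "disease_genes.tsv", "w") as fh:
        fh.write("dataset\tgene\n")
        for ds in sorted(ev.disease_genes):
            for g in sorted(ev.disease_genes[ds]):
                fh.write(f"{ds}\t{g}\n")
    with open(outdir / "coexpression.tsv", "w") as fh:
        fh.write("mirna\tgene\tr\n")
        for (m, g), r in sorted(ev.coexpression.items()):
            fh.write(f"{m}\t{g}\t{format(r, '.6g')}\n")
    with open(outdir / "mirna_gene.tsv", "w") as fh:
        fh.write("mirna\tgene\n")
        for m, g in bundle.mirna_gene:
            fh.write(f"{m}\t{g}\n")
    with open(outdir / "mirna_disease.tsv", "w") as fh:
        fh.write("mirna\tdisease\n")
        for m, d in ev.mirna_disease:
            fh.write(f"{m}\t{d}\n")
    with open(outdir / "gene_disease.tsv", "w") as fh:
        fh.write("gene\tdisease\n")
        for g, d in ev.gene_disease:
            fh.write(f"{g}\t{d}\n")
    (outdir / "positives.txt").write_text("".join(f"{s}\n" for s in sorted(ev.positives)))
    with open(outdir / "truth" / "causal_snps.tsv", "w") as fh:
        fh.write("snp_id\n")
        for sid in sorted(bundle.truth.causal_snps):
            fh.write(sid + "\n")
    with open(outdir / "truth" / "sites.tsv", "w") as fh:
        fh.write("transcript\tgene\tstart\tend\tsite_type\tmirna\n")
        for s in bundle.truth.planted_sites:
            fh.write(f"{s.transcript_id}\t{s.gene}\t{s.start}\t{s.end}\t{s.site_type}\t{s.mirna}\n")
    with open(outdir / "truth" / "effects.tsv", "w") as fh:
        fh.write("snp_id\ttranscript\tgene\tmirna\teffect\tsite_type\tutr_offset\n")
        for e in bundle.truth.planted_effects:
            fh.write(f"{e.snp_id}\t{e.transcript_id}\t{e.gene}\t{e.mirna}\t{e.effect}\t{e.site_type}\t{e.utr_offset}\n")
    cfg = asdict(bundle.config)
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def simulate(config: SimConfig, outdir: str | Path) -> SimBundle:
    """Generate and write the full input bundle; returns the in-memory bundle."""
    bundle = simulate_bundle(config)
    bundle.write(outdir)
    return bundle


def truth_compare(candidate_snps: set[str], truth_causal: set[str]) -> dict[str, float | None]:
    """Recall/precision of a candidate set against the planted causal set."""
    hits = candidate_snps & truth_causal
    recall = len(hits) / len(truth_causal) if truth_causal else 0.0
    precision = len(hits) / len(candidate_snps) if candidate_snps else None
    return {"recall": recall, "precision": precision, "n_hits": len(hits), "n_candidates": len(candidate_snps)}
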