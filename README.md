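# mresscan

Candidate causal SNP discovery in microRNA target seed sites, combining
allele-aware seed-site prediction, GWAS p-value inheritance through linkage
disequilibrium (LD) proxies, and biological-context filtering — plus the
supporting analyses that make the candidates credible: SNP-density
purifying-selection contrasts, co-expression decile enrichment,
nearest-neighbor binding-free-energy alternation (ΔΔG) and haplotype
scores.

## Who this is for

Researchers prioritising 3′UTR variants for experimental follow-up. A SNP
in a microRNA recognition element seed site (MRESS) can abolish or create a
microRNA–mRNA interaction; genome-wide association studies (GWAS) carry the
disease signal but multiple-testing thresholds (p ≤ 10⁻⁵) discard most of
it. `mresscan` keeps a moderate threshold and restores specificity through
context instead.

## The method

1. **Seed-site scanning.** Each microRNA contributes two 7-nt seeds
   (mature positions 1–7 and 2–8). A site is the reverse complement of the
   seed in the 3′UTR, typed `7mer(1-7)`, `7mer(2-8)`, `8mer-1a`
   (A anchored opposite position 1) or `8mer`. Both alleles of every 3′UTR
   SNP are scanned in identical ±50-nt windows: wild-only sites are
   **losses**, mutant-only sites **creates**. An optional human–mouse
   global-alignment filter keeps conserved sites only.
2. **p-value inheritance.** A seed-site SNP inherits
   `p = min{p(self), p(proxies)}` over genotyped SNPs at D′ ≥ 1.
3. **Context selection.** Hosts of SNPs with p ≤ 0.01 are tested for GO
   biological-process enrichment (hypergeometric upper tail); so are the
   disease's known genes; the enriched-term lists are intersected (one-sided
   Fisher exact over the term universe) and candidates are the significant
   SNPs whose host gene carries an overlap term.
4. **Credibility checks.** Sensitivity/precision against documented
   positives with a hypergeometric over-representation tail; co-expression
   decile enrichment of candidate-affected pairs; per-SNP
   ΔΔG = ΔG37(alt) − ΔG37(ref) from nearest-neighbor RNA/RNA
   thermodynamics (ΔG37 = ΔH − 310.15·ΔS, cal/mol), accumulated into
   haplotype scores over LD-linked SNPs in one 3′UTR.

A full synthetic-data generator (`mresscan.simulate`) produces every input
with planted ground truth — sites, create/loss SNPs, purifying selection,
LD-block association signal, context-concordant GO annotations,
co-expression structure and a protected mouse ortholog — so the whole
pipeline is testable offline. See `docs/methods.md` for the model details
and assumptions.

## Worked example

```python
from mresscan.simulate import SimConfig, simulate_bundle, truth_compare
from mresscan.pipeline import scan_all_effects, run_selection, seed_groups_from_mirnas

cfg = SimConfig(seed=7, n_genes=1000, n_mirnas=150, n_snps=30_000,
                n_causal=20, n_disease_genes=60)
bundle = simulate_bundle(cfg)
groups = seed_groups_from_mirnas(bundle.mirnas)
scan = scan_all_effects(bundle.transcripts, bundle.snps, groups)
print(f"seed-site (MRESS) SNPs: {len(scan.mress_snp_ids)}")

background = {t.gene_symbol for t in bundle.transcripts}
res = run_selection(scan, bundle.evidence.gwas, bundle.evidence.ld_pairs,
                    bundle.evidence.disease_genes,
                    bundle.evidence.go_annotations, background)["ds1"]
sel = res.selection
print(f"enriched GO terms (hosts | disease genes): "
      f"{len(sel.enriched_query_terms)} | {len(sel.enriched_disease_terms)}")
print(f"overlap terms: {len(sel.overlap_terms)}  (Fisher p = {sel.overlap_fisher_p:.2e})")
print(f"candidate causal seed-site SNPs: {len(sel.candidate_snps)}")
print(truth_compare(set(sel.candidate_snps), bundle.truth.causal_snps))
```

prints

```
seed-site (MRESS) SNPs: 3262
enriched GO terms (hosts | disease genes): 15 | 12
overlap terms: 7  (Fisher p = 3.19e-09)
candidate causal seed-site SNPs: 43
{'recall': 0.85, 'precision': 0.3953488372093023, 'n_hits': 17, 'n_candidates': 43}
```

Of 30,000 simulated SNPs, 3,262 sit in predicted seed sites. The host
genes of the nominally significant ones share 7 enriched GO terms with the
disease gene list (far more overlap than chance, Fisher p ≈ 3×10⁻⁹), and
the 43 SNPs surviving the context filter recover 17 of the 20 planted
causal SNPs — against a p-threshold-only baseline that admits about twice
as many false positives.

The same stages are available from a shell:

```sh
mresscan simulate --config sim.yaml --seed 7 --out inputs/
mresscan run-all --indir inputs/ --out results/
# or stage by stage: scan, density, gwas-link, select, evaluate,
#                    coexpr, energy, trilateral
```

Input dialects: FASTA for microRNA/UTR sequences; a 7-column region table
(`transcript, gene, chrom, strand, region_type, start, end`, 1-based
inclusive); TSVs for SNPs, GWAS p-values, LD pairs, GO annotations,
disease genes, co-expression, disease links; one SNP id per line for
positives. SNP alleles are forward-strand DNA; all file coordinates are
1-based inclusive.

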