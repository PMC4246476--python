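# Methods

## The problem

A microRNA represses an mRNA mainly through Watson–Crick pairing of its
5′-end *seed* to a complementary stretch in the mRNA's 3′UTR (a microRNA
recognition element seed site, MRESS). A SNP inside such a site can abolish
the interaction, and a SNP just outside a near-match can create one; both
are plausible disease mechanisms. Genome-wide association studies measure
per-SNP disease association, but the multiple-testing thresholds needed to
control the genome-wide false-positive rate discard most true seed-site
signals, whose effect sizes are modest. `mresscan` implements the
alternative strategy: keep a *moderate* association threshold (p ≤ 0.01)
and recover credibility from biological context — the host genes of the
surviving seed-site SNPs must share Gene Ontology biological-process
context with genes already known for the disease.

## Seed-site model

Two seed definitions run in parallel: mature positions 1–7 and 2–8. A site
is the reverse complement of the seed in the 3′UTR (antiparallel pairing),
typed by its extensions:

* `7mer(1-7)`: match to positions 1–7 only.
* `8mer`: a 1–7 match whose 5′-adjacent UTR base also pairs position 8, or
  a 2–8 match whose 3′-adjacent base pairs position 1 (same 8-nt footprint
  found through either definition; reported once).
* `8mer-1a`: a 2–8 match followed 3′-ward by an adenosine that is *not* a
  position-1 pair. The A is anchored opposite position 1 regardless of
  identity; when position 1 is U, an A-followed match is a full 8mer and is
  typed 8mer.
* `7mer(2-8)`: a 2–8 match with neither extension.

One located occurrence receives exactly one type (8mer > 8mer-1a > 7mer),
so the four classes partition sites. MicroRNAs sharing a seed are grouped;
a group's members may type the same occurrence differently (they differ at
the extension base), in which case the member sets are split per type.

**Allele-aware calls.** For each 3′UTR SNP the ±50-nt windows (truncated at
UTR boundaries) carrying the reference and the alternate allele are both
scanned; only sites whose footprint covers the SNP are compared. Wild-only
records are *losses*, mutant-only records *creates*; a site persisting
under both alleles is reported in neither class. A SNP with at least one
effect is a seed-site (MRESS) SNP. Swapping ref/alt provably swaps the two
labels. SNP alleles arrive on the forward genomic strand (dbSNP
convention) and are complemented into minus-strand transcripts.

**Conservation.** A site is conserved iff its whole footprint aligns
gap-free to identical mouse bases in a global pairwise alignment
(match +1, mismatch −1, gap open −10, gap extend −4; Biopython's
`PairwiseAligner`, where the first gap base costs the open score and each
further base the extend score). For mutant-created sites the footprint is
assessed on the reference sequence with the SNP position exempted from base
identity (it cannot be identical by construction) though still required to
be aligned. This is deliberately the stricter reading of "entirely matched
to the aligned region": both gap-free and base-identical.

## GWAS p-value inheritance

Seed-site SNPs are rarely genotyped directly; each inherits the minimum
p-value over itself (if genotyped) and its proxies — genotyped SNPs at
D′ ≥ 1.0 (threshold configurable; r² is carried in the data model and can
drive haplotype grouping instead). QQ data use the uniform order-statistic
midpoints, expected₍ᵢ₎ = −log10((i − 0.5)/n) against observed −log10 p
sorted descending. The p ≤ 0.05 over-representation odds ratio is the
plain 2×2 cross-product with a two-sided Fisher p; zero cells fall back to
the Haldane (+0.5) correction, flagged. The minimum rule makes inherited
p-values stochastically smaller than uniform even without signal, so null
calibration of the OR test is assessed on like-for-like groups (genotyped
seed-site SNPs' own p-values vs other genotyped SNPs).

## Context selection

For each GWAS dataset: (1) hosts of seed-site SNPs with inherited p ≤ 0.01
form the query gene set; (2) the query and the disease gene list are each
tested for GO-BP enrichment against the full transcript background with a
raw upper-tail hypergeometric p at 0.05 — deliberately uncorrected, since
the false positives of the term lists are absorbed by the next step (a
Benjamini–Hochberg option exists but is off by default); (3) the two
enriched-term lists are intersected and the overlap tested one-sided by
Fisher's exact test over the term universe (every term with ≥ 1 annotated
background gene, configurable); (4) candidates are the significant SNPs
whose host gene carries at least one overlap term. Candidates are monotone
in the p threshold. A SNP inside two genes' UTRs counts for both.

## Evaluation

Against an externally curated positives list: sensitivity = hits/positives,
precision = hits/selected, per-type precision over caller-supplied
per-type universes, and the upper-tail hypergeometric probability of the
hit count under random selection from the mapped-SNP universe. On the
worked example's counts (universe 12,892, positives 368, selected 286,
hits 27) that tail is 4.96 × 10⁻⁸.

## Duplex thermodynamics

Binding free energy of the seed duplex is the nearest-neighbor sum
ΔG37 = ΔH − 310.15·ΔS (cal/mol) over consecutive base-pair stacks plus an
initiation term. Stack ΔH/ΔS are the published 1 M Na⁺ RNA/RNA
Watson–Crick measurements shipped in `data/rna_nn_params.tsv` (provenance
column per row); at 1 M Na⁺ no salt correction applies, and melting
temperature (the only quantity sensitive to strand concentration) is out of
scope. Stacks containing a non-Watson–Crick pair (single internal
mismatches, G·U wobbles) are priced by a configurable destabilising
fallback (ΔG37 +1000 cal/mol, ΔH 0) and flagged — the pipeline's reported
quantity, ΔΔG = ΔG37(alt) − ΔG37(ref), is a *difference of identical
architectures*, so the initiation term, the three complementary clamp pairs
appended to both duplex ends (default C·G; needed because the
decomposition has no terminal-mismatch terms), and any stacks away from the
SNP cancel exactly. These cancellation identities, and exact antisymmetry
under allele swap, are asserted in the test suite. For seed groups whose
members differ over the duplex segment (8mer-1a groups can differ at
position 1) the per-member ΔΔG values are averaged and flagged. The duplex
is the seed footprint only — 7 or 8 microRNA 5′ bases per site type — with
no 3′-supplementary pairing, matching the seed-site model used throughout.

**Haplotype scores.** Within one transcript's 3′UTR, seed-site SNPs are
grouped into connected components of the LD graph (edges D′ ≥ 1.0 by
default; r² rule available); components of ≥ 2 SNPs are emitted with the
sum of members' |ΔΔG| (per-SNP |ΔΔG| is the mean over that SNP's effect
records). Connected components rather than cliques: under D′ = 1 LD is
transitive in practice, and the component rule is deterministic.

## Synthetic data

The generator emulates every input at once with planted ground truth:

* random 22-nt microRNAs and three-region transcripts (5UTR/CDS/3UTR laid
  out per chromosome, both strands), with 1–3 seed-match sites of
  controlled type written into each 3′UTR;
* SNPs placed uniformly over region bases, with MAF classes (40% common /
  30% rare / 30% frequency-unknown, the last via < 100 observed
  chromosomes); common SNPs falling in site footprints are thinned by the
  purifying-selection multiplier (default 0.5);
* causal SNPs (default 20): half *losses* placed at the most G/C-stacked
  core position of a planted site, half *creates* completing a one-base
  near-match of a G/C-rich seed — functional variants are planted where the
  thermodynamic consequence is largest, which is the premise behind
  comparing candidate |ΔΔG| with the background;
* LD blocks of 5 consecutive SNPs with uniform within-block D′ = 1;
  ~60% of SNPs genotyped (at least one per block). The association signal
  is a property of the causal *block*: every genotyped SNP in a block
  containing a causal SNP draws its p-value from Beta(0.1, 1), everything
  else from Uniform(0, 1). This is how tag-SNP association behaves — the
  signal appears at every proxy — and it is what makes the minimum-p
  inheritance rule recover causal SNPs at high recall;
* GO annotations: 500 terms, 4 per gene; causal hosts and disease genes
  draw 75% of their terms from a 12-term disease set, everything else
  uniformly — yielding the enriched-term overlap the selection step relies
  on;
* co-expression r ~ N(−0.2, 0.15) for causal-affected microRNA–gene pairs
  vs N(0.05, 0.2) for background pairs (clipped to [−1, 1]);
* a mouse ortholog per UTR by per-base substitution at rate 0.15 with
  planted sites protected; positives lists; microRNA/gene–disease tables
  wired so causal interactions form three-way triples.

One integer seed drives a single numpy `Generator`; identical seeds give
byte-identical output directories.

**What the generator does not model**: coalescent LD (blocks are uniform
and rectangular), mutation-spectrum and GC-content heterogeneity, GO graph
structure (annotations are flat), expression-level dilution across tissues,
and overlapping transcripts. Passing tests therefore demonstrate the
pipeline's statistical machinery under its own assumptions, not performance
on real genomes.

## Replicated experiments and problem sizes

`mresscan.experiments` fixes the study conditions used by the test suite
and the reproduction script:

* **recovery** (20 replicates): 1,000 genes, 150 microRNAs, 30,000 SNPs,
  20 causal, 60 disease genes — proportions that keep background seed-site
  SNPs in the low thousands against tens of causal SNPs, mirroring the
  scale relationship of real studies. Mean recall of context selection and
  its precision ratio over the p ≤ 0.01-only baseline are reported.
* **null calibration** (200 replicates): 300 genes, 80 microRNAs, 8,000
  SNPs, no causal signal; rejection rates of the overlap Fisher test and
  the OR Fisher test at 0.05.
* **purifying selection**: one default-scale simulation (2,000 genes,
  50,000 SNPs, no causal SNPs); the common-SNP density in site footprints
  against the site-free 3′UTR remainder is an unbiased estimator of the
  planted multiplier, reported with its Poisson Monte-Carlo s.e.
* **direction checks** (20 replicates each): decile log-ratios of
  candidate-pair co-expression, and mean candidate vs background |ΔΔG|,
  at 200 genes / 5,000 SNPs.

## Numerical and convention choices

* Internal coordinates 0-based half-open; all files 1-based inclusive.
* Report TSVs: schema-fixed column order, full-row lexicographic sort,
  fixed float precision (`%.10g`) — reruns are byte-identical.
* Interval sets are merged per region class before density denominators are
  computed, so no genomic base is double-counted.
* Decile edges for the co-expression analysis are candidate-set quantiles
  with midpoint interpolation at ties; bins are (low, high] with the
  outermost edges extended to ±1; the statistic is a log10 ratio of
  *proportions*, hence invariant to the two set sizes.
* QQ p-values of 0 are floored at 1e-300 with a warning.
* Aligner ties resolve toward diagonal moves (Biopython's deterministic
  first alignment); identical inputs give identical alignments.
* Degenerate inputs: empty selections flag precision as undefined rather
  than raising; empty region classes and empty decile cells are flagged;
  SNPs whose stated reference allele contradicts the UTR base raise an
  integrity error naming the SNP.

## Known limitations

* No non-canonical sites (bulges, offset seeds, 3′-compensatory pairing)
  and no context-level site scoring; site calls are exact seed matches.
* Mismatch duplex energetics use the uniform fallback term, so |ΔΔG|
  *magnitudes* for mismatch-containing duplexes are coarse; directions and
  cancellation identities are unaffected.
* The per-type precision denominators are whatever per-type universes the
  caller supplies; the package does not decide between "positives by type"
  and "candidates by type" readings.
* GO annotations are consumed flat; no ancestor propagation.
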