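"""Replicated validation experiments on synthetic data.

Each experiment regenerates its inputs from a seed, runs the relevant
pipeline stages, and returns summary statistics. They are used both by the
test suite and by the reproduction script, always with explicit seeds.

Problem sizes are chosen so each experiment preserves the proportions that
matter for its statistic (background seed-site SNPs greatly outnumbering
causal ones; disease genes a small fraction of all genes; GO terms numerous
relative to disease-linked terms) while completing in seconds per replicate.
"""

from __future__ import annotations

import numpy as np

from .coexpression import decile_enrichment
from .density import region_density
from .energy import load_params, snp_delta
from .gwas import enrichment_or
from .pipeline import run_selection, scan_all_effects, seed_groups_from_mirnas
from .simulate import SimConfig, simulate_bundle, truth_compare

# study conditions for the planted-signal and null experiments
RECOVERY_CONFIG = dict(n_genes=1000, n_mirnas=150, n_snps=30_000, n_causal=20,
                       n_disease_genes=60)
NULL_CONFIG = dict(n_genes=300, n_mirnas=80, n_snps=8_000, n_causal=0,
                   n_disease_genes=40)
DIRECTION_CONFIG = dict(n_genes=200, n_mirnas=60, n_snps=5_000, n_causal=20,
                        n_disease_genes=30)


def _select(bundle):
    groups = seed_groups_from_mirnas(bundle.mirnas)
    scan = scan_all_effects(bundle.transcripts, bundle.snps, groups)
    background = {t.gene_symbol for t in bundle.transcripts}
    results = run_selection(
        scan, bundle.evidence.gwas, bundle.evidence.ld_pairs,
        bundle.evidence.disease_genes, bundle.evidence.go_annotations, background,
    )
    return scan, results["ds1"]


def recovery_experiment(seed: int, n_reps: int = 20) -> dict[str, float]:
    """Planted-signal recovery: context selection vs the p-threshold baseline.

    20 causal seed-site SNPs carry Beta(0.1, 1) association p-values through
    their LD blocks against a uniform background; returns the mean recall of
    the context method and the mean precision ratio over the p <= 0.01-only
    baseline across replicates.
    """
    recalls, ratios = [], []
    for r in range(n_reps):
        bundle = simulate_bundle(SimConfig(seed=seed + r, **RECOVERY_CONFIG))
        scan, ds = _select(bundle)
        ctx = truth_compare(set(ds.selection.candidate_snps), bundle.truth.causal_snps)
        baseline = truth_compare(
            {a.mress_snp_id for a in ds.assignments if a.inherited_p <= 0.01},
            bundle.truth.causal_snps,
        )
        recalls.append(ctx["recall"])
        if ctx["precision"] is not None and baseline["precision"]:
            ratios.append(ctx["precision"] / baseline["precision"])
    return {
        "mean_recall": float(np.mean(recalls)),
        "mean_precision_ratio": float(np.mean(ratios)),
        "n_reps": n_reps,
    }


def null_calibration(seed: int, n_reps: int = 200) -> dict[str, float]:
    """Size of the overlap Fisher test and the enrichment-OR Fisher test
    under no planted signal.

    The OR null compares two groups drawn from the same uniform p-value
    distribution (the seed-site SNPs' own genotyped p-values against the
    rest), as the min-over-proxies rule deliberately biases inherited
    p-values downward and is not itself a calibrated statistic.
    """
    overlap_sig = or_sig = 0
    for r in range(n_reps):
        bundle = simulate_bundle(SimConfig(seed=seed + r, **NULL_CONFIG))
        scan, ds = _select(bundle)
        if ds.selection.overlap_fisher_p <= 0.05:
            overlap_sig += 1
        gwas = bundle.evidence.gwas["ds1"]
        mress_geno = [gwas[s] for s in scan.mress_snp_ids if s in gwas]
        bg = [p for sid, p in gwas.items() if sid not in scan.mress_snp_ids]
        if mress_geno and bg and enrichment_or(mress_geno, bg).fisher_p <= 0.05:
            or_sig += 1
    return {
        "overlap_sig_rate": overlap_sig / n_reps,
        "or_sig_rate": or_sig / n_reps,
        "n_reps": n_reps,
    }


def purifying_selection_recovery(seed: int) -> dict[str, float]:
    """Estimate the planted common-SNP density multiplier on seed sites.

    Compares common-SNP density inside planted site footprints against the
    remainder of the 3'UTR (site bases excluded), which is an unbiased
    estimator of the thinning multiplier; returns the estimate and its
    Monte-Carlo standard error (Poisson counts).
    """
    bundle = simulate_bundle(SimConfig(seed=seed, n_causal=0))
    iv = bundle.region_intervals()
    reports = region_density(bundle.snps, {"3UTR": iv["3UTR"], "MRESS": iv["MRESS"]})
    by = {(r.region, r.maf_class): r for r in reports}
    m = by[("MRESS", "common")]
    u = by[("3UTR", "common")]
    d_mress = m.snp_count / m.total_kb
    d_rest = (u.snp_count - m.snp_count) / (u.total_kb - m.total_kb)
    ratio = d_mress / d_rest
    # first-order MC error from the two Poisson counts
    se = ratio * np.sqrt(1 / max(m.snp_count, 1) + 1 / max(u.snp_count - m.snp_count, 1))
    return {
        "density_ratio": float(ratio),
        "mc_se": float(se),
        "planted_multiplier": bundle.config.mress_common_snp_multiplier,
        "n_mress_common": m.snp_count,
    }


def coexpression_direction(seed: int, n_reps: int = 20) -> dict[str, float]:
    """Mean decile log-ratio in negative- vs positive-correlation intervals
    for causal-affected pairs."""
    neg_means, pos_means = [], []
    for r in range(n_reps):
        bundle = simulate_bundle(SimConfig(seed=seed + r, n_causal=30, **{
            k: v for k, v in DIRECTION_CONFIG.items() if k != "n_causal"}))
        cand_pairs = {(e.mirna, e.gene) for e in bundle.truth.planted_effects}
        coexpr = bundle.evidence.coexpression
        cand_r = [v for p, v in coexpr.items() if p in cand_pairs]
        rows = decile_enrichment(cand_r, list(coexpr.values()))
        neg = [x.log_ratio for x in rows if x.high < 0 and x.log_ratio is not None]
        pos = [x.log_ratio for x in rows if x.low > 0 and x.log_ratio is not None]
        if neg:
            neg_means.append(float(np.mean(neg)))
        if pos:
            pos_means.append(float(np.mean(pos)))
    return {
        "mean_log_ratio_negative_r": float(np.mean(neg_means)),
        "mean_log_ratio_positive_r": float(np.mean(pos_means)),
        "n_reps": n_reps,
    }


def energy_direction(seed: int, n_reps: int = 20) -> dict[str, float]:
    """Mean |ddG| of causal-SNP effects vs all seed-site SNP effects."""
    params = load_params()
    cand_means, bg_means = [], []
    for r in range(n_reps):
        bundle = simulate_bundle(SimConfig(seed=seed + r, **DIRECTION_CONFIG))
        groups = seed_groups_from_mirnas(bundle.mirnas)
        scan = scan_all_effects(bundle.transcripts, bundle.snps, groups)
        seqs = dict(bundle.mirnas)
        deltas = [snp_delta(e, seqs, params) for e in scan.effects]
        cand = [d.abs_ddg for d in deltas if d.snp_id in bundle.truth.causal_snps]
        cand_means.append(float(np.mean(cand)))
        bg_means.append(float(np.mean([d.abs_ddg for d in deltas])))
    return {
        "mean_abs_ddg_candidates": float(np.mean(cand_means)),
        "mean_abs_ddg_background": float(np.mean(bg_means)),
        "n_reps": n_reps,
    }
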