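"""Scoring candidate SNP sets against a known-positive list.

Sensitivity and precision are computed against an externally curated list of
SNPs documented as deleterious; the significance of the observed hit count
is the upper tail of a hypergeometric null (drawing ``n_selected`` SNPs
without replacement from the mapped universe).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class EvaluationReport:
    n_universe: int
    n_positives: int
    n_selected: int
    n_hits: int
    sensitivity: float
    precision: float | None  # None when nothing was selected
    per_type: dict[str, tuple[int, int, float]]
    hyper_p: float
    flagged: bool = False


def hypergeom_upper_tail(n_universe: int, n_positives: int, n_selected: int, n_hits: int) -> float:
    """P(X >= n_hits) for X ~ Hypergeometric(n_universe, n_positives, n_selected)."""
    return float(stats.hypergeom.sf(n_hits - 1, n_universe, n_positives, n_selected))


def per_type_precision(
    positives: set[str], universe_by_type: dict[str, set[str]]
) -> dict[str, tuple[int, int, float]]:
    """Per-site-type ``(hits, total, precision)`` rows.

    A SNP with several site types counts once per type; types with an empty
    universe are omitted.
    """
    out = {}
    for site_type in sorted(universe_by_type):
        total = len(universe_by_type[site_type])
        if total == 0:
            continue
        hits = len(positives & universe_by_type[site_type])
        out[site_type] = (hits, total, hits / total)
    return out


def evaluate(
    selected: set[str],
    positives: set[str],
    universe: set[str],
    universe_by_type: dict[str, set[str]] | None = None,
) -> EvaluationReport:
    """Sensitivity, precision, per-type precision and hypergeometric p."""
    if not selected <= universe or not positives <= universe:
        raise ValueError("selected and positives must be subsets of the universe")
    hits = selected & positives
    n_sel, n_pos, n_hit = len(selected), len(positives), len(hits)
    sensitivity = n_hit / n_pos if n_pos else 0.0
    precision = n_hit / n_sel if n_sel else None
    per_type = {}
    if universe_by_type:
        restricted = {t: s & universe for t, s in universe_by_type.items()}
        per_type = per_type_precision(positives, restricted)
    return EvaluationReport(
        n_universe=len(universe),
        n_positives=n_pos,
        n_selected=n_sel,
        n_hits=n_hit,
        sensitivity=sensitivity,
        precision=precision,
        per_type=per_type,
        hyper_p=hypergeom_upper_tail(len(universe), n_pos, n_sel, n_hit),
        flagged=n_sel == 0,
    )
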