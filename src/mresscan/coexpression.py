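"""Decile enrichment of candidate-affected pairs over co-expression r.

MicroRNA repression predicts negatively correlated microRNA-mRNA
co-expression. Candidate-affected interactions are split into ten aliquots
by their Pearson r; within each interval the candidate proportion is
compared with the proportion of the full predicted-interaction set, on a
log10 scale, so a positive value means the candidates are enriched there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CoexprEnrichment:
    low: float
    high: float  # interval is (low, high]
    n_candidate: int
    n_total: int
    log_ratio: float | None  # None (flagged) when the total count is zero
    flagged: bool = False


def decile_enrichment(
    candidate_r: list[float],
    total_r: list[float],
    n_bins: int = 10,
    log_base: float = 10.0,
) -> list[CoexprEnrichment]:
    """Candidate-defined decile intervals with log proportion ratios.

    Interval edges are the candidate-set quantiles (ties broken by midpoint
    interpolation); membership is (low, high]; the outermost edges are
    extended to -1 and +1 so every correlation is binned. The statistic is
    log10((n_cand/N_cand) / (n_tot/N_tot)) — a ratio of proportions, hence
    scale-free in the two set sizes.
    """
    cand = np.asarray(candidate_r, dtype=float)
    tot = np.asarray(total_r, dtype=float)
    if cand.size < n_bins:
        raise ValueError(f"need at least {n_bins} candidate correlations, got {cand.size}")
    if np.any(np.abs(cand) > 1) or np.any(np.abs(tot) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(cand, qs, method="midpoint")
    edges[0] = -1.0
    edges[-1] = 1.0

    def bin_counts(values: np.ndarray) -> np.ndarray:
        counts = np.zeros(n_bins, dtype=int)
        if values.size == 0:
            return counts
        idx = np.searchsorted(edges, values, side="left") - 1
        idx = np.clip(idx, 0, n_bins - 1)
        for i in idx:
            counts[i] += 1
        return counts

    nc = bin_counts(cand)
    nt = bin_counts(tot)
    Nc, Nt = cand.size, tot.size
    out = []
    for i in range(n_bins):
        if nt[i] == 0 or nc[i] == 0:
            # empty cell on either side: the log ratio is undefined
            ratio, flag = None, True
        else:
            ratio = math.log((nc[i] / Nc) / (nt[i] / Nt), log_base)
            flag = False
        out.append(
            CoexprEnrichment(float(edges[i]), float(edges[i + 1]), int(nc[i]), int(nt[i]), ratio, flag)
        )
    return out
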