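"""Regulon enrichment against the DEG list and Activated/Inhibited calls.

A transcription factor's regulon (its target-gene set) is tested for
over-representation of DEG with the one-sided hypergeometric tail
(equivalent to a one-sided Fisher exact test), conditioning on the
analysis universe. P-values are Benjamini-Hochberg adjusted over the
whole tested collection; regulons surviving the FDR cutoff are scored
with the same impact/flux machinery used for pathways, and the flux sign
yields the predicted state: positive = Activated, negative = Inhibited,
exactly zero = Indeterminate.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .impact import compute_impact, select_deg
from .model import (
    DEGTable,
    EnrichmentResult,
    GeneSetCollection,
    TFState,
    TFStateResult,
)

__all__ = [
    "hypergeom_pvalue",
    "bh_adjust",
    "enrich_collection",
    "call_state",
    "tf_state_report",
]


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation tail P(X >= k) for X hypergeometric
    with N items, K successes, n draws, via log-space summation of the
    probability mass. k = 0 returns exactly 1."""
    for name, value in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(value, (int, np.integer)) or value < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {value!r}")
    if K > N or n > N or k > min(K, n):
        raise ValidationError(
            f"inconsistent arguments: need k <= min(K, n) <= N, K <= N, n <= N "
            f"(got k={k}, K={K}, n={n}, N={N})"
        )
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    log_p = hypergeom.logpmf(support, N, K, n)
    p = float(np.exp(logsumexp(log_p)))
    return min(max(p, 5e-324), 1.0)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted P-values, capped at 1 and
    returned in the input order."""
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        return []
    if np.any(~np.isfinite(ps)) or np.any(ps <= 0) or np.any(ps > 1):
        raise ValidationError("all p-values must lie in (0, 1]")
    adjusted = multipletests(ps, method="fdr_bh")[1]
    return [float(q) for q in adjusted]


def enrich_collection(
    collection: GeneSetCollection,
    deg: Iterable[str],
    table: DEGTable,
) -> list[EnrichmentResult]:
    """Test every set in the collection for DEG over-representation.

    Backgrounds are members ∩ universe; sets with empty background are
    reported with p = 1. FDR is adjusted over all tested sets. Ranks run
    1..T by ascending p-value, ties broken by set_id; output is in rank
    order."""
    deg = frozenset(deg)
    if not deg <= table.universe:
        extra = sorted(deg - table.universe)[:5]
        raise ValidationError(f"DEG not in universe: {extra}")
    N, n = len(table.universe), len(deg)
    rows: list[tuple[str, int, int, float, tuple[str, ...]]] = []
    for gs in collection:
        background = gs.members & table.universe
        overlap = tuple(sorted(background & deg))
        K, k = len(background), len(overlap)
        p = 1.0 if K == 0 else hypergeom_pvalue(k, K, n, N)
        rows.append((gs.set_id, K, k, p, overlap))
    fdrs = bh_adjust([row[3] for row in rows])
    order = sorted(range(len(rows)), key=lambda i: (rows[i][3], rows[i][0]))
    results = []
    for rank, i in enumerate(order, start=1):
        set_id, K, k, p, overlap = rows[i]
        results.append(
            EnrichmentResult(
                set_id=set_id,
                n_universe=N,
                n_deg=n,
                n_set=K,
                n_overlap=k,
                pvalue=p,
                fdr=fdrs[i],
                rank=rank,
                overlap_genes=overlap,
            )
        )
    return results


def call_state(flux: float) -> TFState:
    """Predicted regulon state from the flux sign."""
    if not math.isfinite(flux):
        raise ValidationError(f"flux must be finite, got {flux!r}")
    if flux > 0:
        return TFState.ACTIVATED
    if flux < 0:
        return TFState.INHIBITED
    return TFState.INDETERMINATE


def tf_state_report(
    collection: GeneSetCollection,
    table: DEGTable,
    fdr_cutoff_deg: float = 0.10,
    fdr_cutoff_tf: float = 0.05,
) -> list[TFStateResult]:
    """Full regulon pipeline: select DEG, test every regulon, keep those
    at or below the TF FDR cutoff, score impact/flux on each survivor and
    call its state. Output sorted by enrichment rank."""
    if not (0.0 < fdr_cutoff_tf <= 1.0):
        raise ValidationError(f"fdr_cutoff_tf must lie in (0, 1], got {fdr_cutoff_tf!r}")
    deg = select_deg(table, fdr_cutoff_deg)
    enriched = enrich_collection(collection, deg, table)
    report: list[TFStateResult] = []
    for enr in enriched:
        if enr.fdr > fdr_cutoff_tf:
            continue
        scored = compute_impact(collection[enr.set_id], table, fdr_cutoff_deg, deg=deg)
        report.append(
            TFStateResult(
                enrichment=enr,
                impact=scored.impact,
                flux=scored.flux,
                state=call_state(scored.flux),
            )
        )
    return report
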