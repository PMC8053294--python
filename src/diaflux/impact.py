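"""Impact and flux scoring of gene sets against a DE table.

For a gene set with background B (members present in the analysis
universe) and DEG subset D (members passing the FDR cutoff):

    proportion    pi = |D| / |B|
    magnitude     m  = mean over D of |log2fc|
    significance  s  = mean over D of -log10(P)
    impact        I  = 100 * pi * m * s
    direction     d  = sum(log2fc) / sum(|log2fc|)   (0 if denominator 0)
    flux          F  = I * d

so |F| <= I always, with equality exactly when all DEG in the set share
one sign of log2 fold-change. Empty D (or empty B) yields a zero result.

Scores for a whole collection can be aggregated over a pathway hierarchy
(arithmetic mean of impact and of flux per subcategory/category) and
ranked into top up-/downregulated lists by impact within a flux sign.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Iterable, Sequence

from .errors import ValidationError
from .model import (
    AggregateResult,
    DEGTable,
    DirectionCounts,
    GeneSet,
    GeneSetCollection,
    ImpactResult,
    PathwayHierarchy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "select_deg",
    "count_by_direction",
    "compute_impact",
    "score_collection",
    "aggregate_hierarchy",
    "rank_top",
]


def select_deg(table: DEGTable, fdr_cutoff: float = 0.10) -> frozenset[str]:
    """Genes with FDR at or below the cutoff (inclusive boundary)."""
    if not (0.0 < fdr_cutoff <= 1.0):
        raise ValidationError(f"fdr_cutoff must lie in (0, 1], got {fdr_cutoff!r}")
    return frozenset(r.gene_id for r in table if r.fdr <= fdr_cutoff)


def count_by_direction(deg: Iterable[str], table: DEGTable) -> DirectionCounts:
    """Count up- (log2fc > 0) and downregulated (log2fc < 0) genes among
    ``deg``; genes with log2fc exactly 0 are counted in neither and
    reported on the ``n_zero`` attribute."""
    n_up = n_down = n_zero = 0
    for gene_id in deg:
        if gene_id not in table:
            raise ValidationError(f"gene {gene_id!r} not present in the DEG table")
        lfc = table[gene_id].log2fc
        if lfc > 0:
            n_up += 1
        elif lfc < 0:
            n_down += 1
        else:
            n_zero += 1
    return DirectionCounts(n_up, n_down, n_zero)


def compute_impact(
    gene_set: GeneSet,
    table: DEGTable,
    fdr_cutoff: float = 0.10,
    deg: frozenset[str] | None = None,
    use_adjusted_p: bool = False,
    direction_method: str = "magnitude",
) -> ImpactResult:
    """Score one gene set.

    ``deg`` may carry a precomputed DEG selection (must match the cutoff).
    ``use_adjusted_p`` switches the significance term from the raw to the
    FDR-adjusted P-value. ``direction_method`` is ``"magnitude"`` for
    d = sum(log2fc)/sum(|log2fc|) or ``"count"`` for (n_up - n_down)/n_deg;
    only the magnitude-weighted form guarantees |flux| <= impact.
    """
    if direction_method not in ("magnitude", "count"):
        raise ValidationError(f"unknown direction_method {direction_method!r}")
    if deg is None:
        deg = select_deg(table, fdr_cutoff)
    background = gene_set.members & table.universe
    deg_members = tuple(sorted(background & deg))
    n_b, n_d = len(background), len(deg_members)
    if n_b == 0 or n_d == 0:
        return ImpactResult(
            set_id=gene_set.set_id,
            n_background=n_b,
            n_deg=0,
            proportion=0.0,
            magnitude=0.0,
            significance=0.0,
            impact=0.0,
            direction=0.0,
            flux=0.0,
            deg_members=(),
        )
    stats = [table[g] for g in deg_members]
    lfc = [r.log2fc for r in stats]
    pvals = [r.fdr if use_adjusted_p else r.pvalue for r in stats]
    proportion = n_d / n_b
    magnitude = sum(abs(x) for x in lfc) / n_d
    significance = sum(-math.log10(max(p, 5e-324)) for p in pvals) / n_d
    impact = 100.0 * proportion * magnitude * significance
    if direction_method == "count":
        n_up = sum(1 for x in lfc if x > 0)
        n_down = sum(1 for x in lfc if x < 0)
        direction = (n_up - n_down) / n_d
    else:
        denom = sum(abs(x) for x in lfc)
        direction = (sum(lfc) / denom) if denom > 0 else 0.0
    direction = max(-1.0, min(1.0, direction))
    return ImpactResult(
        set_id=gene_set.set_id,
        n_background=n_b,
        n_deg=n_d,
        proportion=proportion,
        magnitude=magnitude,
        significance=significance,
        impact=impact,
        direction=direction,
        flux=impact * direction,
        deg_members=deg_members,
    )


def score_collection(
    collection: GeneSetCollection,
    table: DEGTable,
    fdr_cutoff: float = 0.10,
    use_adjusted_p: bool = False,
    direction_method: str = "magnitude",
) -> list[ImpactResult]:
    """Score every set in the collection; output ordered by descending
    impact, ties broken by set_id."""
    if len(collection) == 0:
        raise ValidationError("collection must contain at least one set")
    deg = select_deg(table, fdr_cutoff)
    results = [
        compute_impact(
            gs,
            table,
            fdr_cutoff,
            deg=deg,
            use_adjusted_p=use_adjusted_p,
            direction_method=direction_method,
        )
        for gs in collection
    ]
    results.sort(key=lambda r: (-r.impact, r.set_id))
    return results


def aggregate_hierarchy(
    results: Sequence[ImpactResult],
    hierarchy: PathwayHierarchy,
    level: str,
) -> list[AggregateResult]:
    """Average impact and flux per subcategory or category.

    Pathways absent from the hierarchy are skipped with a warning, as are
    pathways with an empty background (n_background = 0); groups left with
    no eligible pathway are omitted. Output ordered by descending impact,
    ties by group_id."""
    if level not in ("subcategory", "category"):
        raise ValidationError(f"unknown aggregation level {level!r}")
    groups: dict[str, list[ImpactResult]] = defaultdict(list)
    for res in results:
        if res.set_id not in hierarchy:
            logger.warning("pathway %r not in hierarchy; skipped", res.set_id)
            continue
        if res.n_background == 0:
            continue
        groups[hierarchy.group_of(res.set_id, level)].append(res)
    aggregates = [
        AggregateResult(
            group_id=gid,
            level=level,
            impact=sum(r.impact for r in members) / len(members),
            flux=sum(r.flux for r in members) / len(members),
            n_pathways=len(members),
        )
        for gid, members in groups.items()
    ]
    aggregates.sort(key=lambda a: (-a.impact, a.group_id))
    return aggregates


def rank_top(results: Sequence[ImpactResult], n: int, mode: str) -> list[ImpactResult]:
    """Top ``n`` sets by impact among those with positive (mode ``"up"``)
    or negative (mode ``"down"``) flux; fewer are returned if fewer
    qualify."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n!r}")
    if mode == "up":
        qualifying = [r for r in results if r.flux > 0]
    elif mode == "down":
        qualifying = [r for r in results if r.flux < 0]
    else:
        raise ValidationError(f"mode must be 'up' or 'down', got {mode!r}")
    qualifying.sort(key=lambda r: (-r.impact, r.set_id))
    return qualifying[:n]
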