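"""Core domain types.

The analysis universe is the set of genes present in the differential
expression (DE) statistics table; every proportion, background and
enrichment test downstream conditions on it. Gene sets are plain named
memberships and serve both as pathway catalogs and transcription-factor
(TF) regulons. Pathways may additionally carry a two-level hierarchy
(subcategory, category) and an undirected link graph used for
neighborhood expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ValidationError

__all__ = [
    "GeneStat",
    "DEGTable",
    "GeneSet",
    "GeneSetCollection",
    "HierarchyEntry",
    "PathwayHierarchy",
    "PathwayGraph",
    "ImpactResult",
    "AggregateResult",
    "DirectionCounts",
    "EnrichmentResult",
    "TFState",
    "TFStateResult",
]


@dataclass(frozen=True)
class GeneStat:
    """Per-gene DE statistics: log2 fold-change (treatment vs control),
    raw P-value and FDR-adjusted P-value.

    A raw P-value of exactly zero is rejected rather than clamped so that
    -log10(P), which enters the impact score, stays finite.
    """

    gene_id: str
    log2fc: float
    pvalue: float
    fdr: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be a non-empty string")
        if not math.isfinite(self.log2fc):
            raise ValidationError(f"{self.gene_id}: log2fc must be finite")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(
                f"{self.gene_id}: pvalue must lie in (0, 1], got {self.pvalue!r}"
            )
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(
                f"{self.gene_id}: fdr must lie in [0, 1], got {self.fdr!r}"
            )


def deduplicate_gene_stats(records: Iterable[GeneStat]) -> list[GeneStat]:
    """Collapse duplicate gene_ids, keeping per gene the record with the
    smallest raw P-value (ties: smallest ``|log2fc|``, then first occurrence).
    Output preserves the input order of the surviving records.
    """
    best: dict[str, tuple[float, float, int]] = {}
    chosen: dict[str, GeneStat] = {}
    order: list[str] = []
    for pos, rec in enumerate(records):
        key = (rec.pvalue, abs(rec.log2fc), pos)
        if rec.gene_id not in best:
            best[rec.gene_id] = key
            chosen[rec.gene_id] = rec
            order.append(rec.gene_id)
        elif key < best[rec.gene_id]:
            best[rec.gene_id] = key
            chosen[rec.gene_id] = rec
    return [chosen[g] for g in order]


class DEGTable:
    """Ordered collection of :class:`GeneStat` with unique gene ids.

    The table's gene ids define the analysis universe.
    """

    def __init__(self, records: Sequence[GeneStat]):
        records = tuple(records)
        index: dict[str, GeneStat] = {}
        for rec in records:
            if rec.gene_id in index:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
            index[rec.gene_id] = rec
        if not records:
            raise ValidationError("DEG table must contain at least one record")
        self._records = records
        self._index = index
        self._universe = frozenset(index)

    @property
    def records(self) -> tuple[GeneStat, ...]:
        return self._records

    @property
    def universe(self) -> frozenset[str]:
        return self._universe

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __getitem__(self, gene_id: str) -> GeneStat:
        return self._index[gene_id]

    def __iter__(self) -> Iterator[GeneStat]:
        return iter(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DEGTable):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"DEGTable({len(self)} genes)"


@dataclass(frozen=True)
class GeneSet:
    """A named gene membership (pathway or TF regulon)."""

    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValidationError("set_id must be non-empty")
        if not self.members:
            raise ValidationError(f"{self.set_id}: members must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))


class GeneSetCollection:
    """Mapping of unique set_id -> :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet], library_name: str = ""):
        mapping: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.set_id in mapping:
                raise ValidationError(f"duplicate set_id {gs.set_id!r}")
            mapping[gs.set_id] = gs
        self.sets: dict[str, GeneSet] = mapping
        self.library_name = library_name

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]


@dataclass(frozen=True)
class HierarchyEntry:
    pathway_name: str
    subcategory: str
    category: str


class PathwayHierarchy:
    """pathway_id -> (pathway_name, subcategory, category)."""

    def __init__(self, entries: Mapping[str, HierarchyEntry]):
        self.entries: dict[str, HierarchyEntry] = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.entries

    def __getitem__(self, pathway_id: str) -> HierarchyEntry:
        return self.entries[pathway_id]

    def group_of(self, pathway_id: str, level: str) -> str:
        entry = self.entries[pathway_id]
        if level == "subcategory":
            return entry.subcategory
        if level == "category":
            return entry.category
        raise ValidationError(f"unknown hierarchy level {level!r}")


class PathwayGraph:
    """Undirected pathway-link graph; no self-loops, edges deduplicated."""

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]):
        self.nodes: frozenset[str] = frozenset(nodes)
        edge_set: set[frozenset[str]] = set()
        for a, b in edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValidationError(f"edge ({a!r}, {b!r}) has endpoint outside nodes")
            edge_set.add(frozenset((a, b)))
        self.edges: frozenset[frozenset[str]] = frozenset(edge_set)
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for edge in self.edges:
            a, b = tuple(edge)
            adj[a].add(b)
            adj[b].add(a)
        self._adj = adj

    def neighbors(self, node: str) -> frozenset[str]:
        return frozenset(self._adj[node])

    def edge_pairs(self) -> list[tuple[str, str]]:
        """Edges as sorted (low, high) tuples, lexicographically ordered."""
        return sorted(tuple(sorted(e)) for e in self.edges)

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class ImpactResult:
    """Impact/flux scores for one gene set.

    With background B = members ∩ universe and D = B ∩ DEG:
    proportion π = |D|/|B|, magnitude m = mean |log2fc| over D,
    significance s = mean −log10 P over D, impact I = 100·π·m·s,
    direction d = Σ log2fc / Σ |log2fc| (0 when the denominator is 0),
    flux F = I·d. Hence |F| ≤ I always, with equality iff the set's DEG
    all share one fold-change sign.
    """

    set_id: str
    n_background: int
    n_deg: int
    proportion: float
    magnitude: float
    significance: float
    impact: float
    direction: float
    flux: float
    deg_members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.direction <= 1.0 + 1e-12):
            raise ValidationError(
                f"{self.set_id}: direction {self.direction} outside [-1, 1]"
            )
        if self.n_deg > self.n_background:
            raise ValidationError(f"{self.set_id}: n_deg > n_background")


@dataclass(frozen=True)
class AggregateResult:
    """Mean impact/flux over the pathways of one subcategory or category."""

    group_id: str
    level: str
    impact: float
    flux: float
    n_pathways: int

    def __post_init__(self) -> None:
        if self.level not in ("subcategory", "category"):
            raise ValidationError(f"unknown aggregation level {self.level!r}")
        if self.n_pathways < 1:
            raise ValidationError(f"{self.group_id}: n_pathways must be >= 1")


class DirectionCounts(tuple):
    """(n_up, n_down) with zero-fold-change genes reported separately."""

    def __new__(cls, n_up: int, n_down: int, n_zero: int = 0):
        obj = super().__new__(cls, (n_up, n_down))
        obj.n_zero = n_zero
        return obj

    @property
    def n_up(self) -> int:
        return self[0]

    @property
    def n_down(self) -> int:
        return self[1]


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one set against the DEG list.

    N = universe size, n = number of DEG, K = set background size,
    k = overlap; pvalue is the one-sided tail P(X >= k).
    """

    set_id: str
    n_universe: int
    n_deg: int
    n_set: int
    n_overlap: int
    pvalue: float
    fdr: float
    rank: int
    overlap_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_set, self.n_deg):
            raise ValidationError(f"{self.set_id}: overlap exceeds min(K, n)")
        if self.rank < 1:
            raise ValidationError(f"{self.set_id}: rank must be positive")


class TFState(str, Enum):
    ACTIVATED = "Activated"
    INHIBITED = "Inhibited"
    INDETERMINATE = "Indeterminate"


@dataclass(frozen=True)
class TFStateResult:
    """Enrichment evidence joined with impact/flux and the state call."""

    enrichment: EnrichmentResult
    impact: float
    flux: float
    state: TFState

    @property
    def set_id(self) -> str:
        return self.enrichment.set_id
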