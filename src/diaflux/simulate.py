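"""Seeded synthetic data: DE tables with planted regulon signals.

The generator emulates the shape of an edgeR-style output table over a
universe of ~10^4 genes. Null genes get log2 fold-changes drawn from
Normal(0, se); each planted set has a fraction of "responding" members
whose log2fc is drawn from direction * Normal(effect_mu, effect_sd).
P-values are the two-sided normal tail of z = log2fc / se — the simplest
mechanism producing jointly consistent (log2fc, p, fdr) triples — and
FDR is Benjamini-Hochberg over all genes. With the defaults (10,000
genes, 50 sets of 40, 5 activated + 5 inhibited planted sets,
effect_mu 1.5, effect_sd 0.3, se 0.3, 80% of planted members responding)
roughly 3-4% of genes pass FDR <= 0.10, the regime of a few hundred DEG
among ~10^4 analyzed genes.

Planted sets are sampled disjointly (so planted directions never
conflict); null sets are sampled independently and may overlap, which
gives the shared-gene pathway graph its edges. All randomness flows from
a single integer seed through numpy's PCG64 generator with three spawned
streams (gene effects, set memberships, planted effects), so output is
reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .enrich import bh_adjust
from .errors import ValidationError
from .model import (
    DEGTable,
    GeneSet,
    GeneSetCollection,
    GeneStat,
    HierarchyEntry,
    PathwayGraph,
    PathwayHierarchy,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationBundle",
    "simulate",
    "write_simulation",
    "fixture_small",
    "write_fixture",
]

_SUBCATEGORIES = ("subcat1", "subcat2", "subcat3", "subcat4", "subcat5")
_CATEGORY_OF = {
    "subcat1": "catA",
    "subcat2": "catA",
    "subcat3": "catA",
    "subcat4": "catB",
    "subcat5": "catB",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``set_size`` may be an int or an inclusive (low, high) range;
    ``effect_mu``/``effect_sd`` parameterize the planted |log2fc|;
    ``se`` is the per-gene standard error converting log2fc to a z-score;
    ``frac_responding`` is the fraction of a planted set's members given
    the effect.
    """

    n_genes: int = 10_000
    n_sets: int = 50
    set_size: int | tuple[int, int] = 40
    n_planted_up: int = 5
    n_planted_down: int = 5
    effect_mu: float = 1.5
    effect_sd: float = 0.3
    se: float = 0.3
    frac_responding: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_sets < 1:
            raise ValidationError("n_genes and n_sets must be >= 1")
        if self.n_planted_up < 0 or self.n_planted_down < 0:
            raise ValidationError("planted counts must be >= 0")
        if self.n_planted_up + self.n_planted_down > self.n_sets:
            raise ValidationError("planted sets cannot exceed n_sets")
        lo, hi = self.size_range
        if lo < 1 or hi > self.n_genes or lo > hi:
            raise ValidationError(
                f"set sizes must lie in [1, n_genes], got {self.set_size!r}"
            )
        n_planted = self.n_planted_up + self.n_planted_down
        if n_planted * hi > self.n_genes:
            raise ValidationError("planted sets cannot be sampled disjointly")
        if self.effect_mu < 0 or self.effect_sd < 0:
            raise ValidationError("effect_mu and effect_sd must be >= 0")
        if self.se <= 0:
            raise ValidationError("se must be > 0")
        if not (0.0 < self.frac_responding <= 1.0):
            raise ValidationError("frac_responding must lie in (0, 1]")

    @property
    def size_range(self) -> tuple[int, int]:
        if isinstance(self.set_size, tuple):
            return self.set_size
        return (self.set_size, self.set_size)


@dataclass(frozen=True)
class SimulationTruth:
    """Planted directions (+1 activated / -1 inhibited) and the members
    actually given the effect."""

    planted: Mapping[str, int]
    responding_genes: Mapping[str, tuple[str, ...]]


@dataclass(frozen=True)
class SimulationBundle:
    table: DEGTable
    sets: GeneSetCollection
    hierarchy: PathwayHierarchy
    graph: PathwayGraph
    truth: SimulationTruth


def _set_id(i: int) -> str:
    return f"set{i:03d}"


def simulate(config: SimulationConfig) -> SimulationBundle:
    """Generate one synthetic cohort from ``config``.

    Returns the DE table, the gene-set collection (usable both as a
    pathway catalog and a regulon library), a round-robin pathway
    hierarchy, the shared-gene pathway graph, and the planted truth.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_sets, rng_effects = (np.random.default_rng(s) for s in ss.spawn(3))

    n = config.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(1, n + 1)])
    lo, hi = config.size_range
    sizes = (
        np.full(config.n_sets, lo)
        if lo == hi
        else rng_sets.integers(lo, hi + 1, size=config.n_sets)
    )

    n_planted = config.n_planted_up + config.n_planted_down
    memberships: list[np.ndarray] = []
    # planted sets: disjoint chunks of one permutation
    perm = rng_sets.permutation(n)
    offset = 0
    for i in range(n_planted):
        memberships.append(np.sort(perm[offset : offset + sizes[i]]))
        offset += sizes[i]
    # null sets: independent draws, overlap allowed
    for i in range(n_planted, config.n_sets):
        memberships.append(np.sort(rng_sets.choice(n, size=sizes[i], replace=False)))

    directions = {
        _set_id(i + 1): (1 if i < config.n_planted_up else -1) for i in range(n_planted)
    }

    log2fc = rng_genes.normal(0.0, config.se, size=n)
    responding: dict[str, tuple[str, ...]] = {}
    for i in range(n_planted):
        sid = _set_id(i + 1)
        members = memberships[i]
        n_resp = max(1, int(round(config.frac_responding * len(members))))
        chosen = np.sort(rng_effects.choice(members, size=n_resp, replace=False))
        effects = rng_effects.normal(config.effect_mu, config.effect_sd, size=n_resp)
        log2fc[chosen] = directions[sid] * effects
        responding[sid] = tuple(gene_ids[chosen])

    z = log2fc / config.se
    pvalues = np.maximum(2.0 * norm.sf(np.abs(z)), 5e-324)
    fdrs = bh_adjust(pvalues)

    records = [
        GeneStat(gene_id=gene_ids[i], log2fc=float(log2fc[i]),
                 pvalue=float(pvalues[i]), fdr=float(fdrs[i]))
        for i in range(n)
    ]
    table = DEGTable(records)

    gene_sets = []
    for i, members in enumerate(memberships):
        sid = _set_id(i + 1)
        kind = "planted" if sid in directions else "null"
        gene_sets.append(
            GeneSet(
                set_id=sid,
                description=f"synthetic {kind} set",
                members=frozenset(gene_ids[members]),
            )
        )
    collection = GeneSetCollection(gene_sets, library_name="synthetic")

    entries = {
        gs.set_id: HierarchyEntry(
            pathway_name=f"Synthetic pathway {gs.set_id}",
            subcategory=_SUBCATEGORIES[i % len(_SUBCATEGORIES)],
            category=_CATEGORY_OF[_SUBCATEGORIES[i % len(_SUBCATEGORIES)]],
        )
        for i, gs in enumerate(collection)
    }
    hierarchy = PathwayHierarchy(entries)

    ids = [gs.set_id for gs in collection]
    member_sets = {gs.set_id: gs.members for gs in collection}
    edges = [
        (a, b)
        for idx, a in enumerate(ids)
        for b in ids[idx + 1 :]
        if member_sets[a] & member_sets[b]
    ]
    graph = PathwayGraph(nodes=ids, edges=edges)

    truth = SimulationTruth(planted=directions, responding_genes=responding)
    return SimulationBundle(table, collection, hierarchy, graph, truth)


def write_simulation(bundle: SimulationBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the four standard input files plus truth.tsv under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "deg_table": out_dir / "deg_table.tsv",
        "gene_sets": out_dir / "gene_sets.gmt",
        "hierarchy": out_dir / "hierarchy.tsv",
        "edges": out_dir / "pathway_edges.tsv",
        "truth": out_dir / "truth.tsv",
    }
    with open(paths["deg_table"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tlog2fc\tpvalue\tfdr\n")
        for r in bundle.table:
            fh.write(f"{r.gene_id}\t{r.log2fc!r}\t{r.pvalue!r}\t{r.fdr!r}\n")
    with open(paths["gene_sets"], "w", encoding="utf-8", newline="\n") as fh:
        for gs in bundle.sets:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.members)]) + "\n")
    with open(paths["hierarchy"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("pathway_id\tpathway_name\tsubcategory\tcategory\n")
        for pid in sorted(bundle.hierarchy.entries):
            e = bundle.hierarchy[pid]
            fh.write(f"{pid}\t{e.pathway_name}\t{e.subcategory}\t{e.category}\n")
    with open(paths["edges"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source_id\ttarget_id\n")
        for a, b in bundle.graph.edge_pairs():
            fh.write(f"{a}\t{b}\n")
    with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("set_id\tdirection\tresponding_genes\n")
        for sid in sorted(bundle.truth.planted):
            fh.write(
                f"{sid}\t{bundle.truth.planted[sid]}\t"
                + ",".join(bundle.truth.responding_genes[sid])
                + "\n"
            )
    return paths


def fixture_small() -> SimulationBundle:
    """Hand-built miniature cohort with exactly known scores.

    A 10-gene analysis universe (g01..g10; 4 DEG at FDR <= 0.10) plus two
    set-member ids absent from the universe (gx01, gx02; 12 distinct gene
    ids overall), across three sets:

    * S_A (background 5, DEG g01: +2 @ p 1e-4 and g02: -1 @ p 1e-2) has
      proportion 0.4, magnitude 1.5, significance 3, impact 180,
      direction 1/3, flux 60.
    * S_B has K=5 background members of which k=4 are DEG, so with N=10
      and n=4 its enrichment p is exactly 5/210.
    * S_C's two extra members exercise background filtering (K=2, k=0).

    Shared members chain the pathway graph S_A - S_B - S_C.
    """
    rows = [
        ("g01", 2.0, 1e-4, 0.020),
        ("g02", -1.0, 1e-2, 0.040),
        ("g03", 1.2, 3e-3, 0.030),
        ("g04", -0.8, 5e-3, 0.035),
        ("g05", 0.1, 0.60, 0.70),
        ("g06", -0.2, 0.50, 0.65),
        ("g07", 0.05, 0.90, 0.92),
        ("g08", -0.3, 0.40, 0.60),
        ("g09", 0.15, 0.70, 0.80),
        ("g10", -0.05, 0.95, 0.95),
    ]
    table = DEGTable([GeneStat(g, l, p, f) for g, l, p, f in rows])
    sets = GeneSetCollection(
        [
            GeneSet("S_A", "worked impact example", frozenset({"g01", "g02", "g05", "g06", "g07"})),
            GeneSet("S_B", "worked enrichment example", frozenset({"g01", "g02", "g03", "g04", "g09"})),
            GeneSet("S_C", "off-universe members", frozenset({"g08", "g09", "gx01", "gx02"})),
        ],
        library_name="fixture",
    )
    hierarchy = PathwayHierarchy(
        {
            "S_A": HierarchyEntry("Fixture pathway A", "subcat1", "catA"),
            "S_B": HierarchyEntry("Fixture pathway B", "subcat1", "catA"),
            "S_C": HierarchyEntry("Fixture pathway C", "subcat4", "catB"),
        }
    )
    graph = PathwayGraph(
        nodes=("S_A", "S_B", "S_C"), edges=(("S_A", "S_B"), ("S_B", "S_C"))
    )
    truth = SimulationTruth(planted={}, responding_genes={})
    return SimulationBundle(table, sets, hierarchy, graph, truth)


def write_fixture(out_dir: str | Path) -> dict[str, Path]:
    """Write the miniature cohort as the four standard input files."""
    return write_simulation(fixture_small(), out_dir)
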