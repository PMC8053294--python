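"""Multi-level pathway network expansion and tri-partite assembly.

Starting from seed pathways of interest, the pathway-link graph is
expanded breadth-first: every pathway within ``levels`` link steps is
retained and annotated with its graph distance from the seed set (seeds
at level 0). DEG belonging to retained pathways are attached via
membership edges, and significant TF regulons via regulation edges to
genes in their enrichment overlap — yielding a TF → gene → pathway
tri-partite view (no gene–gene, tf–tf or tf–pathway edges ever occur).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ValidationError
from .model import DEGTable, GeneSetCollection, PathwayGraph, TFStateResult

__all__ = [
    "NetworkNode",
    "NetworkEdge",
    "NetworkView",
    "expand_neighborhood",
    "map_genes_to_network",
    "attach_tf_layer",
    "export_network",
]

NODE_KINDS = ("pathway", "gene", "tf")
EDGE_KINDS = ("pathway_link", "membership", "regulation")


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    node_kind: str
    level: int
    log2fc: float | None = None  # genes only
    predicted_state: str | None = None  # tfs only

    def __post_init__(self) -> None:
        if self.node_kind not in NODE_KINDS:
            raise ValidationError(f"unknown node kind {self.node_kind!r}")
        if self.level < 0:
            raise ValidationError(f"{self.node_id}: level must be >= 0")


@dataclass(frozen=True)
class NetworkEdge:
    source_id: str
    target_id: str
    edge_kind: str

    def __post_init__(self) -> None:
        if self.edge_kind not in EDGE_KINDS:
            raise ValidationError(f"unknown edge kind {self.edge_kind!r}")


@dataclass(frozen=True)
class NetworkView:
    nodes: tuple[NetworkNode, ...]
    edges: tuple[NetworkEdge, ...]

    def node_ids(self, kind: str | None = None) -> frozenset[str]:
        return frozenset(
            n.node_id for n in self.nodes if kind is None or n.node_kind == kind
        )

    def __post_init__(self) -> None:
        ids = {n.node_id for n in self.nodes}
        for e in self.edges:
            if e.source_id not in ids or e.target_id not in ids:
                raise ValidationError(
                    f"edge {e.source_id!r} -> {e.target_id!r} has endpoint outside nodes"
                )


def bfs_levels(
    graph: PathwayGraph, seeds: Iterable[str], levels: int
) -> dict[str, int]:
    """Breadth-first distances from the seed set, truncated at ``levels``."""
    dist = {s: 0 for s in seeds}
    frontier = sorted(dist)
    depth = 0
    while frontier and depth < levels:
        depth += 1
        nxt = []
        for node in frontier:
            for nb in sorted(graph.neighbors(node)):
                if nb not in dist:
                    dist[nb] = depth
                    nxt.append(nb)
        frontier = nxt
    return dist


def expand_neighborhood(
    graph: PathwayGraph, seeds: Iterable[str], levels: int
) -> NetworkView:
    """Pathways within ``levels`` link steps of any seed, annotated with
    their BFS distance (seeds at level 0); retained edges are those with
    both endpoints retained."""
    seeds = frozenset(seeds)
    unknown = sorted(seeds - graph.nodes)
    if unknown:
        raise ValidationError(f"unknown seed pathway id(s): {', '.join(unknown)}")
    if levels < 0:
        raise ValidationError(f"levels must be >= 0, got {levels!r}")
    dist = bfs_levels(graph, seeds, levels)
    nodes = tuple(
        NetworkNode(node_id=pid, node_kind="pathway", level=dist[pid])
        for pid in sorted(dist)
    )
    edges = tuple(
        NetworkEdge(source_id=a, target_id=b, edge_kind="pathway_link")
        for a, b in graph.edge_pairs()
        if a in dist and b in dist
    )
    return NetworkView(nodes=nodes, edges=edges)


def map_genes_to_network(
    view: NetworkView,
    membership: GeneSetCollection,
    deg: Iterable[str],
    table: DEGTable,
) -> NetworkView:
    """Attach one gene node per DEG belonging to >= 1 retained pathway
    (membership keyed by pathway_id), with a membership edge to every
    retained pathway containing it. Gene nodes carry log2fc; their level
    is 1 + the smallest level among their pathways."""
    deg = frozenset(deg)
    pathway_levels = {
        n.node_id: n.level for n in view.nodes if n.node_kind == "pathway"
    }
    gene_pathways: dict[str, list[str]] = {}
    for pid in sorted(pathway_levels):
        if pid not in membership:
            continue
        for gene in sorted(membership[pid].members & deg & table.universe):
            gene_pathways.setdefault(gene, []).append(pid)
    gene_nodes = tuple(
        NetworkNode(
            node_id=gene,
            node_kind="gene",
            level=1 + min(pathway_levels[p] for p in pids),
            log2fc=table[gene].log2fc,
        )
        for gene, pids in sorted(gene_pathways.items())
    )
    gene_edges = tuple(
        NetworkEdge(source_id=gene, target_id=pid, edge_kind="membership")
        for gene, pids in sorted(gene_pathways.items())
        for pid in pids
    )
    return NetworkView(nodes=view.nodes + gene_nodes, edges=view.edges + gene_edges)


def attach_tf_layer(
    view: NetworkView, tf_results: Sequence[TFStateResult]
) -> NetworkView:
    """Attach one tf node per regulon with >= 1 regulation edge to a gene
    already in the view (edge present iff the gene is in the regulon's
    enrichment overlap); TFs with no mapped target are pruned. TF nodes
    carry the predicted state; their level is 1 + the smallest level among
    their targets. A TF whose id collides with a node already in the view
    (e.g. when one library serves as both pathway catalog and regulon
    library) is disambiguated with a ``tf:`` prefix."""
    existing_ids = {n.node_id for n in view.nodes}
    gene_levels = {n.node_id: n.level for n in view.nodes if n.node_kind == "gene"}
    tf_nodes: list[NetworkNode] = []
    tf_edges: list[NetworkEdge] = []
    for res in sorted(tf_results, key=lambda r: r.set_id):
        targets = sorted(set(res.enrichment.overlap_genes) & gene_levels.keys())
        if not targets:
            continue
        tf_id = res.set_id if res.set_id not in existing_ids else f"tf:{res.set_id}"
        tf_nodes.append(
            NetworkNode(
                node_id=tf_id,
                node_kind="tf",
                level=1 + min(gene_levels[g] for g in targets),
                predicted_state=res.state.value,
            )
        )
        tf_edges.extend(
            NetworkEdge(source_id=tf_id, target_id=g, edge_kind="regulation")
            for g in targets
        )
    return NetworkView(
        nodes=view.nodes + tuple(tf_nodes), edges=view.edges + tuple(tf_edges)
    )


def export_network(view: NetworkView, out_dir: str | Path) -> tuple[Path, Path]:
    """Write nodes.tsv (node_id, node_kind, level, log2fc, predicted_state)
    and edges.tsv (source_id, target_id, edge_kind) under ``out_dir`` in a
    deterministic order (kind, then id)."""
    out_dir = Path(out_dir)
    if not out_dir.exists():
        raise IOError(f"{out_dir}: directory does not exist")
    nodes_path = out_dir / "nodes.tsv"
    edges_path = out_dir / "edges.tsv"
    with open(nodes_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_id\tnode_kind\tlevel\tlog2fc\tpredicted_state\n")
        for n in sorted(view.nodes, key=lambda n: (n.node_kind, n.node_id)):
            lfc = "" if n.log2fc is None else format(n.log2fc, ".6g")
            state = n.predicted_state or ""
            fh.write(f"{n.node_id}\t{n.node_kind}\t{n.level}\t{lfc}\t{state}\n")
    with open(edges_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source_id\ttarget_id\tedge_kind\n")
        for e in sorted(view.edges, key=lambda e: (e.edge_kind, e.source_id, e.target_id)):
            fh.write(f"{e.source_id}\t{e.target_id}\t{e.edge_kind}\n")
    return nodes_path, edges_path
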