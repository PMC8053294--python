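"""Assemble the TF -> DEG -> pathway tri-partite network around the most
impacted pathways.

Seeds the pathway-link graph with the top up- and downregulated pathways,
expands one level of interconnected pathways, attaches DEG via membership
edges and significant TF regulons via regulation edges, and exports
results/nodes.tsv + results/edges.tsv.
"""

import argparse
from collections import Counter
from pathlib import Path

from diaflux import (
    attach_tf_layer,
    expand_neighborhood,
    export_network,
    map_genes_to_network,
    rank_top,
    read_deg_table,
    read_edges,
    read_gmt,
    score_collection,
    select_deg,
    tf_state_report,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", default="results/sim_inputs")
    parser.add_argument("--out-dir", default="results")
    parser.add_argument("--levels", type=int, default=1)
    parser.add_argument("--fdr-deg", type=float, default=0.10)
    parser.add_argument("--fdr-tf", type=float, default=0.05)
    args = parser.parse_args()

    in_dir, out_dir = Path(args.in_dir), Path(args.out_dir)
    if not (in_dir / "deg_table.tsv").exists():
        raise SystemExit(f"{in_dir}: run analysis/01_simulate_cohort.py first")
    out_dir.mkdir(parents=True, exist_ok=True)

    table = read_deg_table(in_dir / "deg_table.tsv")
    collection = read_gmt(in_dir / "gene_sets.gmt")
    graph = read_edges(in_dir / "pathway_edges.tsv")

    scores = score_collection(collection, table, args.fdr_deg)
    seeds = {
        r.set_id
        for mode in ("up", "down")
        for r in rank_top(scores, 3, mode)
        if r.set_id in graph.nodes
    }
    print(f"seed pathways: {sorted(seeds)}")

    deg = select_deg(table, args.fdr_deg)
    view = expand_neighborhood(graph, seeds, args.levels)
    view = map_genes_to_network(view, collection, deg, table)
    view = attach_tf_layer(view, tf_state_report(collection, table,
                                                 args.fdr_deg, args.fdr_tf))
    nodes_path, edges_path = export_network(view, out_dir)

    kinds = Counter(n.node_kind for n in view.nodes)
    edge_kinds = Counter(e.edge_kind for e in view.edges)
    print(f"network: {dict(kinds)} nodes, {dict(edge_kinds)} edges")
    print(f"wrote {nodes_path} and {edges_path}")


if __name__ == "__main__":
    main()
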