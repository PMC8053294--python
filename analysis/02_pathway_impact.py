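"""Score every pathway's impact and flux, aggregate over the hierarchy,
and rank the top up-/downregulated pathways.

Reads the cohort written by 01_simulate_cohort.py and writes
pathway_impact.tsv, subcategory_impact.tsv, category_impact.tsv and the
top_up/top_down lists under results/.
"""

import argparse
from pathlib import Path

from diaflux import (
    aggregate_hierarchy,
    rank_top,
    read_deg_table,
    read_gmt,
    read_hierarchy,
    score_collection,
    write_report,
)
from diaflux.model import AggregateResult, ImpactResult


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", default="results/sim_inputs")
    parser.add_argument("--out-dir", default="results")
    parser.add_argument("--fdr", type=float, default=0.10)
    parser.add_argument("--top-n", type=int, default=10)
    args = parser.parse_args()

    in_dir, out_dir = Path(args.in_dir), Path(args.out_dir)
    if not (in_dir / "deg_table.tsv").exists():
        raise SystemExit(f"{in_dir}: run analysis/01_simulate_cohort.py first")
    out_dir.mkdir(parents=True, exist_ok=True)

    table = read_deg_table(in_dir / "deg_table.tsv")
    scores = score_collection(read_gmt(in_dir / "gene_sets.gmt"), table, args.fdr)
    write_report(scores, out_dir / "pathway_impact.tsv", result_type=ImpactResult)

    hierarchy = read_hierarchy(in_dir / "hierarchy.tsv")
    for level in ("subcategory", "category"):
        aggregates = aggregate_hierarchy(scores, hierarchy, level)
        write_report(aggregates, out_dir / f"{level}_impact.tsv",
                     result_type=AggregateResult)
        print(f"most impacted {level}: "
              + ", ".join(f"{a.group_id} (I={a.impact:.1f}, F={a.flux:+.1f})"
                          for a in aggregates[:3]))

    for mode in ("up", "down"):
        top = rank_top(scores, args.top_n, mode)
        write_report(top, out_dir / f"top_{mode}.tsv", result_type=ImpactResult)
        print(f"top {mode}regulated pathways: "
              + ", ".join(f"{r.set_id} (I={r.impact:.1f})" for r in top[:5]))


if __name__ == "__main__":
    main()
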