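"""Rank TF regulons by DEG over-representation, control FDR, and call
each significant regulon Activated or Inhibited from its flux.

Reads the cohort written by 01_simulate_cohort.py, writes
results/tf_state.tsv and compares the calls against the planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from diaflux import read_deg_table, read_gmt, tf_state_report, write_report
from diaflux.model import TFStateResult


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", default="results/sim_inputs")
    parser.add_argument("--out-dir", default="results")
    parser.add_argument("--fdr-deg", type=float, default=0.10)
    parser.add_argument("--fdr-tf", type=float, default=0.05)
    args = parser.parse_args()

    in_dir, out_dir = Path(args.in_dir), Path(args.out_dir)
    if not (in_dir / "deg_table.tsv").exists():
        raise SystemExit(f"{in_dir}: run analysis/01_simulate_cohort.py first")
    out_dir.mkdir(parents=True, exist_ok=True)

    table = read_deg_table(in_dir / "deg_table.tsv")
    regulons = read_gmt(in_dir / "gene_sets.gmt")
    report = tf_state_report(regulons, table, args.fdr_deg, args.fdr_tf)
    write_report(report, out_dir / "tf_state.tsv", result_type=TFStateResult)

    print(f"{len(report)} regulons significant at FDR <= {args.fdr_tf}")
    for res in report:
        enr = res.enrichment
        print(f"  rank {enr.rank:2d}  {res.set_id}  I={res.impact:7.2f}  "
              f"F={res.flux:+8.2f}  {res.state.value:12s}  "
              f"p={enr.pvalue:.2e}  FDR={enr.fdr:.2e}")

    truth_path = in_dir / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        planted = dict(zip(truth["set_id"], truth["direction"]))
        sig = {r.set_id: r for r in report}
        hits = sum(sid in sig for sid in planted)
        correct = sum(
            1 for sid, d in planted.items()
            if sid in sig and (sig[sid].flux > 0) == (d == 1)
        )
        print(f"planted sets recovered: {hits}/{len(planted)}; "
              f"direction calls correct: {correct}/{hits}")


if __name__ == "__main__":
    main()
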