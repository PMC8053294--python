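"""End-to-end orchestration: DEG selection → pathway impact/flux →
TF state → tri-partite network, with a provenance manifest.

Every stage is a plain call into the library modules, so the pipeline's
per-stage outputs are identical to direct module-level calls on the same
inputs; identical configuration and inputs produce byte-identical output
files (the manifest records no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError, ValidationError
from .impact import (
    aggregate_hierarchy,
    count_by_direction,
    rank_top,
    score_collection,
    select_deg,
)
from .io import read_deg_table, read_edges, read_gmt, read_hierarchy, write_report
from .model import AggregateResult, TFStateResult
from .enrich import tf_state_report
from .network import attach_tf_layer, expand_neighborhood, export_network, map_genes_to_network

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, thresholds and output location for one full run.

    DEG are selected at ``fdr_cutoff_deg`` (default 0.10) for all
    downstream scoring; the stricter cutoff (default 0.05) is reported
    alongside in the DEG summary. ``regulons_gmt`` defaults to the
    pathway library when regulons are not supplied separately."""

    deg_path: str
    pathways_gmt: str
    hierarchy_path: str
    edges_path: str
    regulons_gmt: str | None = None
    fdr_cutoff_deg: float = 0.10
    fdr_cutoff_deg_strict: float = 0.05
    fdr_cutoff_tf: float = 0.05
    top_n: int = 10
    network_seeds: tuple[str, ...] = ()
    network_levels: int = 1
    output_dir: str = "results"
    uppercase_ids: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_cutoff_deg", "fdr_cutoff_deg_strict", "fdr_cutoff_tf"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ValidationError(f"{name} must lie in (0, 1], got {value!r}")
        if self.top_n < 1:
            raise ValidationError(f"top_n must be >= 1, got {self.top_n!r}")
        if self.network_levels < 0:
            raise ValidationError(f"network_levels must be >= 0")
        object.__setattr__(self, "network_seeds", tuple(self.network_seeds))


def load_config(path: str | Path) -> dict:
    """Parse a structured (YAML/JSON) or plain key=value config file into
    a keyword dictionary for :class:`PipelineConfig`."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = None
    if not isinstance(data, dict):
        data = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"{path}: expected key=value line, got {line!r}")
            key, _, value = line.partition("=")
            data[key.strip()] = yaml.safe_load(value.strip())
    if "network_seeds" in data and isinstance(data["network_seeds"], str):
        data["network_seeds"] = tuple(
            s for s in data["network_seeds"].split(",") if s
        )
    return data


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the standard outputs plus manifest.json
    into ``config.output_dir``; returns the manifest. Any stage failure
    removes the partial outputs and raises a stage-tagged
    :class:`PipelineError`."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load_inputs"
    try:
        input_paths = {
            "deg_path": config.deg_path,
            "pathways_gmt": config.pathways_gmt,
            "hierarchy_path": config.hierarchy_path,
            "edges_path": config.edges_path,
        }
        regulons_path = config.regulons_gmt or config.pathways_gmt
        input_paths["regulons_gmt"] = regulons_path
        checksums = {k: _sha256(v) for k, v in input_paths.items()}
        table = read_deg_table(config.deg_path, uppercase_ids=config.uppercase_ids)
        pathways = read_gmt(config.pathways_gmt, uppercase_ids=config.uppercase_ids)
        regulons = read_gmt(regulons_path, uppercase_ids=config.uppercase_ids)
        hierarchy = read_hierarchy(config.hierarchy_path)
        graph = read_edges(config.edges_path)

        stage = "deg_summary"
        summary_rows = []
        for cutoff in sorted({config.fdr_cutoff_deg_strict, config.fdr_cutoff_deg}):
            deg_at = select_deg(table, cutoff)
            counts = count_by_direction(deg_at, table)
            summary_rows.append(
                {
                    "fdr_cutoff": format(cutoff, ".6g"),
                    "n_deg": len(deg_at),
                    "n_up": counts.n_up,
                    "n_down": counts.n_down,
                    "n_zero": counts.n_zero,
                }
            )
        path = out_dir / "deg_summary.tsv"
        pd.DataFrame(summary_rows).to_csv(path, sep="\t", index=False)
        written.append(path)

        stage = "pathway_impact"
        scores = score_collection(pathways, table, config.fdr_cutoff_deg)
        path = out_dir / "pathway_impact.tsv"
        write_report(scores, path)
        written.append(path)
        for level in ("subcategory", "category"):
            aggregates = aggregate_hierarchy(scores, hierarchy, level)
            path = out_dir / f"{level}_impact.tsv"
            write_report(aggregates, path, result_type=AggregateResult)
            written.append(path)
        top = {}
        for mode in ("up", "down"):
            top[mode] = rank_top(scores, config.top_n, mode)
            path = out_dir / f"top_{mode}.tsv"
            write_report(top[mode], path, result_type=type(scores[0]))
            written.append(path)

        stage = "tf_state"
        tf_results = tf_state_report(
            regulons, table, config.fdr_cutoff_deg, config.fdr_cutoff_tf
        )
        path = out_dir / "tf_state.tsv"
        write_report(tf_results, path, result_type=TFStateResult)
        written.append(path)

        stage = "network"
        if config.network_seeds:
            seeds = frozenset(config.network_seeds)
        else:
            # default seeds: the top up-/downregulated pathways that exist
            # in the link graph
            seeds = frozenset(
                r.set_id for r in (*top["up"], *top["down"]) if r.set_id in graph.nodes
            )
        deg = select_deg(table, config.fdr_cutoff_deg)
        if seeds:
            view = expand_neighborhood(graph, seeds, config.network_levels)
            view = map_genes_to_network(view, pathways, deg, table)
            view = attach_tf_layer(view, tf_results)
        else:
            from .network import NetworkView

            view = NetworkView(nodes=(), edges=())
        nodes_path, edges_path = export_network(view, out_dir)
        written.extend([nodes_path, edges_path])

        stage = "manifest"
        manifest = {
            "package": "diaflux",
            "version": __version__,
            "config": {
                **{k: str(v) for k, v in input_paths.items()},
                "fdr_cutoff_deg": config.fdr_cutoff_deg,
                "fdr_cutoff_deg_strict": config.fdr_cutoff_deg_strict,
                "fdr_cutoff_tf": config.fdr_cutoff_tf,
                "top_n": config.top_n,
                "network_seeds": sorted(seeds),
                "network_levels": config.network_levels,
                "uppercase_ids": config.uppercase_ids,
                "seed": config.seed,
            },
            "input_checksums": checksums,
            "outputs": sorted(p.name for p in written) + ["manifest.json"],
            "counts": {
                "n_genes": len(table),
                "n_deg": summary_rows[-1]["n_deg"],
                "n_pathways": len(pathways),
                "n_regulons": len(regulons),
                "n_significant_tf": len(tf_results),
                "n_network_nodes": len(view.nodes),
                "n_network_edges": len(view.edges),
            },
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        written.append(manifest_path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage '{stage}': {exc}") from exc
    logger.info("pipeline complete: %d output files in %s", len(written), out_dir)
    return manifest
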