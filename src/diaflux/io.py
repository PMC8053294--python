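"""Readers and writers for every external format the pipeline touches.

All tables are UTF-8 TSV. Gene sets use standard GMT (set_id, description,
members...). Numeric output is formatted to 6 significant digits, which is
presentation only — stored values are full precision.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .model import (
    AggregateResult,
    DEGTable,
    EnrichmentResult,
    GeneSet,
    GeneSetCollection,
    GeneStat,
    HierarchyEntry,
    ImpactResult,
    PathwayGraph,
    PathwayHierarchy,
    TFStateResult,
    deduplicate_gene_stats,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_deg_table",
    "read_gmt",
    "read_hierarchy",
    "read_edges",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]

_DEG_COLUMNS = ("gene_id", "log2fc", "pvalue", "fdr")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_deg_table(path: str | Path, uppercase_ids: bool = False) -> DEGTable:
    """Read a DE statistics table (columns gene_id, log2fc, pvalue, fdr;
    extra columns ignored).

    Duplicate gene ids are collapsed to the record with the smallest raw
    P-value (ties: smallest ``|log2fc|``, then first occurrence). Set
    ``uppercase_ids`` to normalize gene symbols to upper case.
    """
    df = _read_tsv(path, _DEG_COLUMNS)
    records: list[GeneStat] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        gene_id = str(getattr(row, "gene_id"))
        if uppercase_ids:
            gene_id = gene_id.upper()
        values = {}
        for col in ("log2fc", "pvalue", "fdr"):
            raw = getattr(row, col)
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: line {line_no}: non-numeric {col} value {raw!r}"
                ) from None
            if math.isnan(val):
                raise FormatError(f"{path}: line {line_no}: NaN {col} value")
            values[col] = val
        try:
            records.append(GeneStat(gene_id=gene_id, **values))
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {line_no}: {exc}") from None
    return DEGTable(deduplicate_gene_stats(records))


def read_gmt(
    path: str | Path, library_name: str = "", uppercase_ids: bool = False
) -> GeneSetCollection:
    """Read a GMT gene-set library: one set per line, tab-separated as
    set_id, description, member genes. Duplicate members within a line are
    collapsed; a duplicate set_id is an error."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {line_no}: expected >= 3 tab-separated fields"
                )
            set_id, description = fields[0], fields[1]
            members = [m for m in fields[2:] if m]
            if uppercase_ids:
                members = [m.upper() for m in members]
            if not members:
                raise FormatError(f"{path}: line {line_no}: set has no members")
            sets.append(
                GeneSet(set_id=set_id, description=description, members=frozenset(members))
            )
    try:
        return GeneSetCollection(sets, library_name=library_name or path.stem)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def read_hierarchy(path: str | Path) -> PathwayHierarchy:
    """Read the pathway hierarchy TSV (pathway_id, pathway_name,
    subcategory, category); each pathway must appear exactly once."""
    df = _read_tsv(path, ("pathway_id", "pathway_name", "subcategory", "category"))
    entries: dict[str, HierarchyEntry] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        pid = str(row.pathway_id)
        if pid in entries:
            raise ValidationError(f"{path}: line {i + 2}: duplicate pathway_id {pid!r}")
        entries[pid] = HierarchyEntry(
            pathway_name=str(row.pathway_name),
            subcategory=str(row.subcategory),
            category=str(row.category),
        )
    return PathwayHierarchy(entries)


def read_edges(path: str | Path) -> PathwayGraph:
    """Read the pathway-link edge TSV (source_id, target_id) into an
    undirected graph. Duplicate edges (either orientation) are collapsed;
    self-loops are dropped with a warning, keeping the node."""
    df = _read_tsv(path, ("source_id", "target_id"))
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        a, b = str(row.source_id), str(row.target_id)
        nodes.update((a, b))
        if a == b:
            logger.warning("dropping self-loop on pathway %r", a)
            continue
        edges.add((min(a, b), max(a, b)))
    return PathwayGraph(nodes=nodes, edges=edges)


REPORT_COLUMNS: dict[type, tuple[str, ...]] = {
    ImpactResult: (
        "set_id",
        "n_background",
        "n_deg",
        "proportion",
        "magnitude",
        "significance",
        "impact",
        "direction",
        "flux",
        "deg_members",
    ),
    AggregateResult: ("group_id", "level", "impact", "flux", "n_pathways"),
    EnrichmentResult: (
        "set_id",
        "n_universe",
        "n_deg",
        "n_set",
        "n_overlap",
        "pvalue",
        "fdr",
        "rank",
        "overlap_genes",
    ),
    TFStateResult: (
        "tf_id",
        "impact",
        "flux",
        "predicted_state",
        "rank",
        "pvalue",
        "fdr",
        "overlap_genes",
    ),
}


def _format_value(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return format(value, ".6g")
    if isinstance(value, (tuple, list, frozenset)):
        return ",".join(sorted(value) if isinstance(value, frozenset) else value)
    return str(value)


def _result_row(result) -> dict[str, str]:
    if isinstance(result, TFStateResult):
        enr = result.enrichment
        raw = {
            "tf_id": enr.set_id,
            "impact": result.impact,
            "flux": result.flux,
            "predicted_state": result.state.value,
            "rank": enr.rank,
            "pvalue": enr.pvalue,
            "fdr": enr.fdr,
            "overlap_genes": enr.overlap_genes,
        }
    else:
        raw = {col: getattr(result, col) for col in REPORT_COLUMNS[type(result)]}
    return {col: _format_value(raw[col]) for col in REPORT_COLUMNS[type(result)]}


def write_report(results: Sequence, path: str | Path, result_type: type | None = None) -> None:
    """Write a result collection as TSV with a stable column order and
    numbers formatted to 6 significant digits.

    ``result_type`` selects the header when ``results`` is empty.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"{path.parent}: directory does not exist")
    if isinstance(results, pd.DataFrame):
        out = results.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = out[col].map(lambda v: format(v, ".6g"))
        out.to_csv(path, sep="\t", index=False)
        return
    results = list(results)
    if results:
        result_type = type(results[0])
    if result_type is None or result_type not in REPORT_COLUMNS:
        raise ValidationError(
            "cannot infer report columns; pass result_type for empty results"
        )
    columns = REPORT_COLUMNS[result_type]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for result in results:
            row = _result_row(result)
            fh.write("\t".join(row[c] for c in columns) + "\n")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    return pd.read_csv(path, sep="\t")
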