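"""Serialization of optimization reports and DFS trees.

Writes a canonical JSON report (no timestamps, sorted keys, so the same
config and seed produce byte-identical output), per-group tree JSON and
Graphviz DOT files with visited nodes flagged and numbered in visit
order, and per-node candidate/metric tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .scheduler import OptimizationReport
from .search import DFSTree, NodeStatus

__all__ = ["write_report", "load_report", "tree_to_dot"]


def tree_to_dot(tree: DFSTree, name: str = "dfs") -> str:
    """Render a DFS tree in Graphviz DOT form.

    Visited nodes are filled green and labelled ``#k`` with their visit
    order; unvisited (pending) nodes stay black-on-white.  A node that
    ended the search successfully is drawn as a double circle.
    """
    order = {nid: i + 1 for i, nid in enumerate(tree.visit_log)}
    lines = [f'digraph "{name}" {{', "  node [shape=circle];"]
    for node in tree.nodes():
        visited = node.node_id in order
        label_bits = []
        if visited:
            label_bits.append(f"#{order[node.node_id]}")
        label_bits.append(f"d{node.depth}")
        label_bits.append(node.status.value)
        attrs = [f'label="{" ".join(label_bits)}"']
        if visited:
            attrs.append('style=filled fillcolor="palegreen"')
        if node.status is NodeStatus.SUCCESS:
            attrs.append("shape=doublecircle")
        lines.append(f"  n{node.node_id} [{' '.join(attrs)}];")
        for child in node.children:
            lines.append(f"  n{node.node_id} -> n{child.node_id};")
    lines.append("}")
    return "\n".join(lines)


def _tree_tables(tree: DFSTree, group_index: int) -> pd.DataFrame:
    rows = []
    for node in tree.nodes():
        for cand in node.candidates:
            row = {
                "group": group_index,
                "node_id": node.node_id,
                "depth": node.depth,
                "node_status": node.status.value,
            }
            for k, v in cand.coordinates.items():
                row[f"param:{k}"] = v
            if cand.averaged:
                for k, v in cand.averaged.items():
                    row[f"metric:{k}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: OptimizationReport, outdir: str | Path) -> dict[str, Path]:
    """Write report JSON, per-group tree JSON/DOT and candidate CSV tables.

    Returns a mapping of artifact names to the written paths.  The JSON
    report round-trips all numeric fields exactly (Python's JSON float
    encoding uses the shortest exact representation).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    report_path = outdir / "report.json"
    report_path.write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    written["report"] = report_path

    tables = []
    for gidx, tree in report.trees.items():
        dot_path = outdir / f"tree_group{gidx}.dot"
        dot_path.write_text(tree_to_dot(tree, name=f"group{gidx}") + "\n", encoding="utf-8")
        written[f"tree_dot_{gidx}"] = dot_path
        tree_path = outdir / f"tree_group{gidx}.json"
        tree_path.write_text(
            json.dumps(tree.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        written[f"tree_json_{gidx}"] = tree_path
        tables.append(_tree_tables(tree, gidx))

    csv_path = outdir / "candidates.csv"
    pd.concat(tables, ignore_index=True).to_csv(csv_path, index=False)
    written["candidates"] = csv_path
    return written


def load_report(path: str | Path) -> dict:
    """Load a previously written report JSON back into a dictionary."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
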