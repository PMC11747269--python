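"""Compound-target-pathway tripartite network assembly and reporting.

Consumes a compound -> targets mapping and a target -> pathways mapping
(e.g. the output of an external enrichment service) and builds a typed
directed graph with compound -> target and target -> pathway edges only.
Target nodes are classed by how many pathways they participate in:
single-pathway, two-pathway, or multi-pathway (three or more).  Pathway
enrichment itself is out of scope; mappings arrive as plain inputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

__all__ = [
    "TripartiteNetwork",
    "build_network",
    "shared_target_report",
    "export_edge_list",
]


@dataclass
class TripartiteNetwork:
    graph: nx.DiGraph
    summary: dict
    target_classes: dict[str, str]


def _classify(n_pathways: int) -> str:
    # targets without a pathway mapping are grouped with single-pathway
    if n_pathways >= 3:
        return "multi-pathway"
    if n_pathways == 2:
        return "two-pathway"
    return "single-pathway"


def build_network(compound_targets: dict[str, "set[str] | list[str]"],
                  target_pathways: dict[str, "set[str] | list[str]"],
                  ) -> TripartiteNetwork:
    """Assemble the tripartite network and its exact summary counts.

    Every key of ``target_pathways`` must be a target referenced by some
    compound; dangling references raise a validation error naming them.
    """
    targets = set().union(*compound_targets.values()) if compound_targets else set()
    dangling = sorted(set(target_pathways) - targets)
    if dangling:
        raise ValueError(f"target_pathways references unknown targets: {dangling}")

    g = nx.DiGraph()
    pathways = set()
    for c, ts in sorted(compound_targets.items()):
        g.add_node(c, kind="compound")
        for t in sorted(set(ts)):
            g.add_node(t, kind="target")
            g.add_edge(c, t)
    for t, ps in sorted(target_pathways.items()):
        for p in sorted(set(ps)):
            pathways.add(p)
            g.add_node(p, kind="pathway")
            g.add_edge(t, p)

    classes = {t: _classify(len(set(target_pathways.get(t, ())))) for t in targets}
    nx.set_node_attributes(g, {t: c for t, c in classes.items()}, "node_class")
    summary = {
        "n_compounds": len(compound_targets),
        "n_targets": len(targets),
        "n_pathways": len(pathways),
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
    }
    assert summary["n_nodes"] == (summary["n_compounds"] + summary["n_targets"]
                                  + summary["n_pathways"])
    return TripartiteNetwork(g, summary, classes)


def shared_target_report(compound_targets: dict[str, "set[str] | list[str]"]
                         ) -> list[tuple[str, tuple[str, ...]]]:
    """Targets hit by two or more compounds, sorted by sharing degree.

    Returns (target, sharing compounds) rows, highest degree first, ties
    by target id.
    """
    if len(compound_targets) < 2:
        raise ValueError("need at least two compounds")
    sharers: dict[str, set[str]] = {}
    for c, ts in compound_targets.items():
        for t in set(ts):
            sharers.setdefault(t, set()).add(c)
    rows = [(t, tuple(sorted(cs))) for t, cs in sharers.items() if len(cs) >= 2]
    rows.sort(key=lambda r: (-len(r[1]), r[0]))
    return rows


def export_edge_list(net: TripartiteNetwork, path: "str | Path") -> None:
    """Write edges and a node-attribute sidecar as plain CSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target"])
        for u, v in net.graph.edges():
            w.writerow([u, v])
    with open(path.with_suffix(".nodes.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node", "kind", "node_class"])
        for node, attrs in sorted(net.graph.nodes(data=True)):
            w.writerow([node, attrs.get("kind", ""), attrs.get("node_class", "")])
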