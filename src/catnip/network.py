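"""Score-weighted drug network construction, pruning and cross-ATC summaries.

Drugs are nodes, raw classifier scores are edge weights. Pruning at a raw
score of 7.4 (predicted sharing probability > 99%) keeps only confident
edges; cross-ATC medians over the pruned network highlight repurposing
signal between anatomical drug classes.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .io import FormatError, IntegrityError, PairKey

__all__ = [
    "DEFAULT_THRESHOLD",
    "build_network",
    "prune",
    "connected_components",
    "atc_cross_class_summary",
    "export_graph",
    "read_graph",
]

#: raw-score pruning cutoff; sigma(7.4) > 0.99
DEFAULT_THRESHOLD = 7.4


def build_network(
    scores: pd.Series | Mapping[PairKey, float],
    atc_codes: Mapping[str, set[str]] | None = None,
) -> nx.Graph:
    """Weighted undirected graph over all scored drug pairs.

    *scores* is either a Series indexed by (drug_a, drug_b) or a mapping
    from :class:`PairKey`; duplicate pairs are an integrity error. ATC
    level-1 letters, when given, are stored as a node attribute.
    """
    graph = nx.Graph()
    if isinstance(scores, pd.Series):
        items = [(PairKey(a, b), float(v)) for (a, b), v in scores.items()]
    else:
        items = [(PairKey(*k) if not isinstance(k, PairKey) else k, float(v)) for k, v in scores.items()]
    seen: set[PairKey] = set()
    for pk, w in items:
        if pk in seen:
            raise IntegrityError(f"duplicate pair {pk}")
        seen.add(pk)
        graph.add_edge(pk.drug_a, pk.drug_b, weight=w)
    n = graph.number_of_nodes()
    if graph.number_of_edges() < n * (n - 1) // 2:
        warnings.warn("score table does not cover all drug pairs; network is incomplete")
    for node in graph.nodes:
        codes = sorted((atc_codes or {}).get(node, set()))
        graph.nodes[node]["atc"] = ",".join(codes)
    return graph


def prune(graph: nx.Graph, threshold: float = DEFAULT_THRESHOLD) -> nx.Graph:
    """Keep edges with weight >= threshold (inclusive); drop isolated nodes."""
    out = nx.Graph()
    for node, data in graph.nodes(data=True):
        out.add_node(node, **data)
    for a, b, data in graph.edges(data=True):
        if data["weight"] >= threshold:
            out.add_edge(a, b, **data)
    out.remove_nodes_from([n for n in list(out) if out.degree(n) == 0])
    return out


def connected_components(graph: nx.Graph) -> list[set[str]]:
    """Components sorted by decreasing size (ties by smallest member id)."""
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def _node_codes(graph: nx.Graph, node: str) -> set[str]:
    raw = graph.nodes[node].get("atc", "")
    return {c for c in raw.split(",") if c}


def atc_cross_class_summary(
    graph: nx.Graph, atc_codes: Mapping[str, set[str]] | None = None
) -> pd.DataFrame:
    """Per unordered ATC-class pair: contributing edge count, median and mean score.

    Only edges whose two endpoints each carry exactly one ATC code, with the
    two codes differing, contribute (the exclusivity rule: a drug with
    multiple codes is ambiguous between classes and is left out).
    Within-class edges are excluded. Class pairs with no qualifying edge are
    omitted.
    """
    weights: dict[tuple[str, str], list[float]] = {}
    for a, b, data in graph.edges(data=True):
        ca = atc_codes.get(a, set()) if atc_codes is not None else _node_codes(graph, a)
        cb = atc_codes.get(b, set()) if atc_codes is not None else _node_codes(graph, b)
        if len(ca) != 1 or len(cb) != 1:
            continue
        (xa,), (xb,) = ca, cb
        if xa == xb:
            continue
        key = tuple(sorted((xa, xb)))
        weights.setdefault(key, []).append(float(data["weight"]))
    rows = [
        {
            "atc_a": k[0],
            "atc_b": k[1],
            "n_pairs": len(v),
            "median_score": float(pd.Series(v).median()),
            "mean_score": float(pd.Series(v).mean()),
        }
        for k, v in sorted(weights.items())
    ]
    return pd.DataFrame(rows, columns=["atc_a", "atc_b", "n_pairs", "median_score", "mean_score"])


def export_graph(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write the network to GraphML or an annotated edge list.

    Both formats round-trip node ATC attributes and edge weights (weights
    preserved to at least 1e-6). The edge-list dialect is two line kinds:
    ``node <id> <atc-codes>`` and ``edge <a> <b> <weight>``.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edgelist":
        with open(path, "w") as fh:
            for node in sorted(graph.nodes):
                fh.write(f"node\t{node}\t{graph.nodes[node].get('atc', '')}\n")
            for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
                fh.write(f"edge\t{a}\t{b}\t{graph.edges[a, b]['weight']:.10g}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_graph(path: str | Path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edgelist":
        graph = nx.Graph()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if fields[0] == "node" and len(fields) >= 2:
                    graph.add_node(fields[1], atc=fields[2] if len(fields) > 2 else "")
                elif fields[0] == "edge" and len(fields) == 4:
                    graph.add_edge(fields[1], fields[2], weight=float(fields[3]))
                else:
                    raise FormatError(f"{path}:{lineno}: bad line")
        return graph
    raise ValueError(f"unknown format {format!r}")
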