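"""Two-level theme-sharing networks.

Overview level: one node per ECOD X-group present in the bridge table,
coloured by structural class (derived from the architecture level), one
edge per X-group pair sharing at least one theme — drawn solid when some
representative's local theme alignment exceeds 20 residues, dashed
otherwise.  Nested level: for one X-group pair, a bipartite graph of the
individual domains, one edge per representative candidate.

Export: GraphML (attributes embedded) or SIF plus an attribute TSV
sidecar; node and edge ordering is sorted, so output is deterministic.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

SOLID_MIN_ALIGNED = 20  # solid edge: local alignment longer than this

#: Structural classes and their display colours (categorical; renderers
#: pick the palette).  Keyed by architecture (A-level) id.
CLASS_COLORS = {
    "all-alpha": "blue",
    "all-beta": "red",
    "alpha+beta": "yellow",
    "alpha/beta": "green",
    "mixed": "yellow-green",
    "other": "cyan",
    "unknown": "gray",
}

#: Default architecture-id -> class mapping.  Covers the synthetic
#: generator's cycling architecture ids; extend or replace for real ECOD
#: architecture numbering.
DEFAULT_AGROUP_CLASSES = {
    "1": "all-alpha",
    "2": "all-beta",
    "3": "alpha+beta",
    "4": "alpha/beta",
    "5": "mixed",
    "6": "other",
}


def _xgroup_class(xgroup: str, classification: dict[str, str],
                  agroup_classes: dict[str, str]) -> str:
    for label in classification.values():
        parts = label.split(".")
        if parts[1] == xgroup:
            cls = agroup_classes.get(parts[0])
            if cls is None:
                logger.warning("X-group %s: unknown architecture %s, coloured gray",
                               xgroup, parts[0])
                return "unknown"
            return cls
    return "unknown"


def build_overview(bridge_table: pd.DataFrame, classification: dict[str, str],
                   agroup_classes: dict[str, str] | None = None,
                   solid_min_aligned: int = SOLID_MIN_ALIGNED) -> nx.Graph:
    """Overview network: X-group nodes, one edge per connected pair.

    Edge attributes: ``style`` (solid iff any representative of the pair
    uses the local aligner with more than ``solid_min_aligned`` aligned
    residues), ``count`` (number of representatives collapsed into the
    edge) and ``themes`` (their theme ids).
    """
    if bridge_table.empty:
        raise ValueError("bridge table is empty")
    agroup_classes = agroup_classes or DEFAULT_AGROUP_CLASSES
    g = nx.Graph(level="overview")

    xgroups = sorted(set(bridge_table["xgroup_a"]) | set(bridge_table["xgroup_b"]))
    for xg in xgroups:
        cls = _xgroup_class(xg, classification, agroup_classes)
        g.add_node(xg, label=xg, structural_class=cls,
                   color=CLASS_COLORS[cls])

    edges: dict[tuple[str, str], dict] = {}
    for row in bridge_table.sort_values(["theme_id", "domain_a", "domain_b"]).itertuples():
        key = tuple(sorted((row.xgroup_a, row.xgroup_b)))
        solid = row.mode == "local" and row.n_aligned > solid_min_aligned
        e = edges.setdefault(key, {"count": 0, "themes": [], "solid": False})
        e["count"] += 1
        if row.theme_id not in e["themes"]:
            e["themes"].append(row.theme_id)
        e["solid"] = e["solid"] or solid
    for (x1, x2), e in sorted(edges.items()):
        g.add_edge(x1, x2, style="solid" if e["solid"] else "dashed",
                   count=e["count"], themes=",".join(e["themes"]))
    return g


def build_nested(bridge_table: pd.DataFrame, xgroup_pair: tuple[str, str],
                 classification: dict[str, str] | None = None) -> nx.Graph:
    """Nested network for one X-group pair: bipartite domain graph.

    Node attribute ``htf`` carries the lower-level (H.T.F) classification
    when available; edges carry the alignment statistics of their
    representative candidate.
    """
    pair = tuple(sorted(xgroup_pair))
    mask = bridge_table.apply(
        lambda r: tuple(sorted((r["xgroup_a"], r["xgroup_b"]))) == pair, axis=1)
    sub = bridge_table[mask]
    if sub.empty:
        available = sorted({tuple(sorted(t)) for t in
                            zip(bridge_table["xgroup_a"], bridge_table["xgroup_b"])})
        raise ValueError(
            f"X-group pair {pair} not in bridge table; available pairs: {available}")

    g = nx.Graph(level="nested", xgroup_1=pair[0], xgroup_2=pair[1])
    for row in sub.sort_values(["theme_id", "domain_a", "domain_b"]).itertuples():
        for domain, xg in ((row.domain_a, row.xgroup_a), (row.domain_b, row.xgroup_b)):
            if domain not in g:
                htf = ""
                if classification and domain in classification:
                    htf = ".".join(classification[domain].split(".")[2:])
                g.add_node(domain, label=domain, xgroup=xg,
                           side=0 if xg == pair[0] else 1, htf=htf)
        if not g.has_edge(row.domain_a, row.domain_b):
            g.add_edge(row.domain_a, row.domain_b,
                       theme_id=row.theme_id, mode=row.mode,
                       score=float(row.theme_score), n_aligned=int(row.n_aligned),
                       pct_identity=float(row.pct_identity),
                       pct_similarity=float(row.pct_similarity),
                       p_value=float(row.p_value))
    return g


def export_graph(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> list[Path]:
    """Write a network to disk deterministically.

    ``graphml`` embeds all attributes; ``sif`` writes topology plus an
    attribute TSV sidecar (``<path>.attrs.tsv``).  Returns the files
    written.
    """
    path = Path(path)
    ordered = nx.Graph(**graph.graph)
    for n in sorted(graph.nodes):
        ordered.add_node(n, **graph.nodes[n])
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        ordered.add_edge(u, v, **graph.edges[u, v])

    if fmt == "graphml":
        nx.write_graphml(ordered, path, named_key_ids=True, edge_id_from_attribute=None)
        return [path]
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in ordered.edges:
                fh.write(f"{u}\tshares_theme\t{v}\n")
        sidecar = path.with_suffix(path.suffix + ".attrs.tsv")
        with open(sidecar, "w") as fh:
            fh.write("kind\tid\tattribute\tvalue\n")
            for n in ordered.nodes:
                for k, v in sorted(ordered.nodes[n].items()):
                    fh.write(f"node\t{n}\t{k}\t{v}\n")
            for u, v in ordered.edges:
                for k, val in sorted(ordered.edges[u, v].items()):
                    fh.write(f"edge\t{u}|{v}\t{k}\t{val}\n")
        return [path, sidecar]
    raise ValueError(f"unknown format {fmt!r}; choose graphml or sif")
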