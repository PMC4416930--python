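"""Regulatory-network construction from curated edge tables.

The combined network has two node types — transcription factors (TF) and
microRNAs (miRNA) — and three edge kinds, each constraining its endpoint
types: ``tf_mirna`` (TF regulates a miRNA gene transcriptionally),
``tf_tf`` (TF–TF regulation), and ``mirna_tf`` (miRNA represses a TF
post-transcriptionally).  Identifiers are matched case-insensitively
after trimming whitespace, preserving the first-seen casing for display;
curated source tables mix symbol casings.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import networkx as nx

logger = logging.getLogger(__name__)

TF = "TF"
MIRNA = "miRNA"

#: edge kind -> (required source node type, required target node type)
EDGE_KINDS: dict[str, tuple[str, str]] = {
    "tf_mirna": (TF, MIRNA),
    "tf_tf": (TF, TF),
    "mirna_tf": (MIRNA, TF),
}


@dataclass(frozen=True)
class RegulatoryEdge:
    """A directed, provenance-tagged regulation between two elements."""

    source_id: str
    target_id: str
    edge_kind: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.edge_kind not in EDGE_KINDS:
            raise ValueError(
                f"unknown edge_kind {self.edge_kind!r}; "
                f"expected one of {sorted(EDGE_KINDS)}"
            )

    @property
    def source_type(self) -> str:
        return EDGE_KINDS[self.edge_kind][0]

    @property
    def target_type(self) -> str:
        return EDGE_KINDS[self.edge_kind][1]


@dataclass
class NetworkStats:
    """Summary counts for a regulatory network.

    Components are weak components (edge direction ignored);
    ``largest_component_node_fraction`` is the share of all nodes lying
    in the largest weak component.
    """

    n_tf: int
    n_mirna: int
    n_edges: int
    n_components: int
    largest_component_edges: int
    largest_component_node_fraction: float


class RegulatoryNetwork:
    """Typed directed graph of TF and miRNA nodes.

    Wraps a :class:`networkx.DiGraph` whose nodes carry a ``node_type``
    attribute and whose edges carry ``edge_kind`` and ``provenance``.
    Node keys are display ids (first-seen casing); lookup is
    case-insensitive via an internal key map.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        self._display: dict[str, str] = {}  # casefolded key -> display id

    # -- construction -------------------------------------------------

    def _intern(self, raw_id: str) -> str:
        key = raw_id.casefold()
        if key not in self._display:
            self._display[key] = raw_id
        return self._display[key]

    def add_edge(self, edge: RegulatoryEdge) -> None:
        src = self._intern(edge.source_id)
        tgt = self._intern(edge.target_id)
        for node, ntype in ((src, edge.source_type), (tgt, edge.target_type)):
            existing = self.graph.nodes[node]["node_type"] if node in self.graph else None
            if existing is not None and existing != ntype:
                prev = self.graph.nodes[node].get("provenance", "?")
                raise ValueError(
                    f"type conflict for id {node!r}: {existing} (from {prev}) "
                    f"vs {ntype} (from {edge.provenance or '?'})"
                )
            if existing is None:
                self.graph.add_node(node, node_type=ntype, provenance=edge.provenance)
        if self.graph.has_edge(src, tgt):
            return  # same-kind duplicate (parallel kinds impossible by typing)
        self.graph.add_edge(src, tgt, edge_kind=edge.edge_kind, provenance=edge.provenance)

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[RegulatoryEdge]:
        return [
            RegulatoryEdge(u, v, d["edge_kind"], d.get("provenance", ""))
            for u, v, d in self.graph.edges(data=True)
        ]

    def node_type(self, node_id: str) -> str:
        return self.graph.nodes[self._display[node_id.casefold()]]["node_type"]

    @property
    def tfs(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["node_type"] == TF]

    @property
    def mirnas(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["node_type"] == MIRNA]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            dict(self.graph.nodes(data="node_type"))
            == dict(other.graph.nodes(data="node_type"))
            and {(u, v): k for u, v, k in self.graph.edges(data="edge_kind")}
            == {(u, v): k for u, v, k in other.graph.edges(data="edge_kind")}
        )


def _as_lines(stream: str | Path | TextIO) -> tuple[Iterable[str], str]:
    """Accept a path, a text blob containing tabs/newlines, or a file object."""
    if isinstance(stream, Path):
        return stream.read_text().splitlines(), str(stream)
    if isinstance(stream, str):
        if "\n" in stream or "\t" in stream:
            return stream.splitlines(), "<string>"
        return Path(stream).read_text().splitlines(), stream
    return stream.read().splitlines(), getattr(stream, "name", "<stream>")


def parse_edge_table(
    stream: str | Path | TextIO,
    edge_kind: str,
    provenance: str = "",
    aliases: Mapping[str, str] | None = None,
) -> list[RegulatoryEdge]:
    """Parse a two-column TSV (``source_id<TAB>target_id``, with header).

    Rows are deduplicated on the (case-insensitively normalised) ordered
    pair, preserving first-occurrence order.  Self-loops are dropped with
    a warning: a self-loop can never occur inside a simple path.

    Parameters
    ----------
    aliases:
        Optional identifier alias map applied after trimming
        (case-insensitive keys), e.g. to harmonise miRNA naming.
    """
    if edge_kind not in EDGE_KINDS:
        raise ValueError(f"unknown edge_kind {edge_kind!r}; expected one of {sorted(EDGE_KINDS)}")
    lines, name = _as_lines(stream)
    alias_map = {k.strip().casefold(): v.strip() for k, v in (aliases or {}).items()}
    provenance = provenance or name

    edges: list[RegulatoryEdge] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 or not line.strip():
            continue  # header / blank
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(
                f"{name}: line {lineno}: expected 2 tab-separated columns, got {len(fields)}"
            )
        src, tgt = (f.strip() for f in fields)
        if not src or not tgt:
            raise ValueError(f"{name}: line {lineno}: empty identifier")
        src = alias_map.get(src.casefold(), src)
        tgt = alias_map.get(tgt.casefold(), tgt)
        if src.casefold() == tgt.casefold():
            logger.warning("%s: line %d: self-loop %r dropped", name, lineno, src)
            continue
        key = (src.casefold(), tgt.casefold())
        if key in seen:
            continue
        seen.add(key)
        edges.append(RegulatoryEdge(src, tgt, edge_kind, provenance))
    return edges


def build_network(edge_lists: Iterable[Iterable[RegulatoryEdge]]) -> RegulatoryNetwork:
    """Union edge collections into one deduplicated typed network.

    Raises ``ValueError`` if an identifier is claimed as both TF and
    miRNA across tables, naming the id and the two provenances.
    """
    net = RegulatoryNetwork()
    for edges in edge_lists:
        for edge in edges:
            net.add_edge(edge)
    return net


def network_stats(net: RegulatoryNetwork) -> NetworkStats:
    """Node/edge counts and weak-component structure of the network."""
    g = net.graph
    if g.number_of_nodes() == 0:
        return NetworkStats(0, 0, 0, 0, 0, 0.0)
    components = list(nx.weakly_connected_components(g))
    largest = max(components, key=len)
    return NetworkStats(
        n_tf=len(net.tfs),
        n_mirna=len(net.mirnas),
        n_edges=g.number_of_edges(),
        n_components=len(components),
        largest_component_edges=g.subgraph(largest).number_of_edges(),
        largest_component_node_fraction=len(largest) / g.number_of_nodes(),
    )


def export_network(net: RegulatoryNetwork, path: str | Path, fmt: str | None = None) -> None:
    """Write the network as SIF (relation = edge_kind) or GraphML.

    Format is taken from the filename suffix when ``fmt`` is omitted.
    Both formats round-trip ``node_type`` and ``edge_kind``.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "sif":
        with path.open("w") as fh:
            for e in net.edges:
                fh.write(f"{e.source_id} {e.edge_kind} {e.target_id}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path, named_key_ids=True)
    else:
        raise ValueError(f"unsupported export format {fmt!r} (use 'sif' or 'graphml')")


def read_network(path: str | Path) -> RegulatoryNetwork:
    """Read a GraphML file written by :func:`export_network`."""
    g = nx.read_graphml(path)
    net = RegulatoryNetwork()
    for u, v, d in g.edges(data=True):
        net.add_edge(RegulatoryEdge(u, v, d["edge_kind"], d.get("provenance", "")))
    # isolated nodes (none are produced by edge tables, but be faithful)
    for n, d in g.nodes(data=True):
        if n.casefold() not in net._display:
            net.graph.add_node(net._intern(n), node_type=d["node_type"])
    return net
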