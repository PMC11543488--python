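"""Assembly graph data model and GFA 1.0 I/O.

The central structure is :class:`AssemblyGraph`: a directed graph whose
vertices are oriented long reads and whose edges record suffix->prefix
overlaps between them.  Graphs come either from a GFA file (the Hifiasm
dialect: S lines with sequences, L lines whose CIGAR encodes the overlap
length) or from the coordinate-based builder in :mod:`graphasm.simulate`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: CIGAR operators accepted on GFA L lines.
ALLOWED_CIGAR_OPS = frozenset("MID=X")
#: Operators that consume bases of the source (From) segment.
_SOURCE_CONSUMING = frozenset("M=XI")

SCORE_TAG = "ps"   # edge probability score, float tag on L lines
LABEL_TAG = "gt"   # ground-truth edge label, int tag on L lines


class GFAParseError(ValueError):
    """Malformed GFA record; message names the offending line number."""


class GFAReferenceError(ValueError):
    """An L line references a segment with no S line."""


@dataclass
class Node:
    """An oriented read: one vertex of the assembly graph."""

    node_id: int
    read_id: str
    orientation: str = "+"
    read_length: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if self.read_length <= 0:
            raise ValueError(f"read_length must be positive, got {self.read_length}")


@dataclass
class Edge:
    """A suffix->prefix overlap between two oriented reads."""

    edge_id: int
    source: int
    target: int
    overlap_length: int
    cigar: str | None = None


@dataclass
class AssemblyGraph:
    """Directed overlap graph with O(1) per-node adjacency lookup."""

    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    out_edges: dict[int, list[int]] = field(default_factory=dict)
    in_edges: dict[int, list[int]] = field(default_factory=dict)

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def add_node(self, read_id: str, orientation: str = "+", read_length: int = 0) -> Node:
        node = Node(len(self.nodes), read_id, orientation, read_length)
        self.nodes.append(node)
        self.out_edges[node.node_id] = []
        self.in_edges[node.node_id] = []
        return node

    def add_edge(
        self, source: int, target: int, overlap_length: int, cigar: str | None = None
    ) -> Edge:
        if source == target:
            raise ValueError("self-loop edges are not allowed")
        for nid in (source, target):
            if not 0 <= nid < len(self.nodes):
                raise ValueError(f"unknown node id {nid}")
        if not 0 < overlap_length < min(
            self.nodes[source].read_length, self.nodes[target].read_length
        ):
            raise ValueError(
                f"overlap_length {overlap_length} not in (0, min incident read length)"
            )
        edge = Edge(len(self.edges), source, target, overlap_length, cigar)
        self.edges.append(edge)
        self.out_edges[source].append(edge.edge_id)
        self.in_edges[target].append(edge.edge_id)
        return edge

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        for i, node in enumerate(self.nodes):
            if node.node_id != i:
                raise ValueError(f"node_id {node.node_id} at index {i}")
        n_adj = sum(len(v) for v in self.out_edges.values())
        if n_adj != len(self.edges) or sum(len(v) for v in self.in_edges.values()) != len(self.edges):
            raise ValueError("adjacency inconsistent with edge list")
        for j, edge in enumerate(self.edges):
            if edge.edge_id != j:
                raise ValueError(f"edge_id {edge.edge_id} at index {j}")
            if edge.edge_id not in self.out_edges[edge.source]:
                raise ValueError(f"edge {j} missing from out-adjacency")
            if edge.edge_id not in self.in_edges[edge.target]:
                raise ValueError(f"edge {j} missing from in-adjacency")


def degrees(graph: AssemblyGraph) -> np.ndarray:
    """Per-node ``(out_degree, in_degree)`` table, indexed by node_id.

    Column sums both equal the edge count.
    """
    table = np.zeros((graph.num_nodes, 2), dtype=np.int64)
    for edge in graph.edges:
        table[edge.source, 0] += 1
        table[edge.target, 1] += 1
    return table


def cigar_source_length(cigar: str) -> int:
    """Number of source-segment bases consumed by a GFA overlap CIGAR.

    Accepts M/I/D/=/X; M, =, X and I consume the source, D does not.
    A single ``<k>M`` CIGAR yields ``k``.
    """
    pos = 0
    total = 0
    for match in _CIGAR_RE.finditer(cigar):
        if match.start() != pos:
            raise ValueError(f"malformed CIGAR {cigar!r}")
        pos = match.end()
        length, op = int(match.group(1)), match.group(2)
        if op not in ALLOWED_CIGAR_OPS:
            raise ValueError(f"unsupported CIGAR operator {op!r} in {cigar!r}")
        if op in _SOURCE_CONSUMING:
            total += length
    if pos != len(cigar) or not cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return total


def _parse_tags(fields: list[str], lineno: int) -> dict[str, tuple[str, str]]:
    tags = {}
    for raw in fields:
        parts = raw.split(":", 2)
        if len(parts) != 3:
            raise GFAParseError(f"line {lineno}: malformed tag {raw!r}")
        tags[parts[0]] = (parts[1], parts[2])
    return tags


def read_gfa(path) -> tuple[AssemblyGraph, dict[str, str]]:
    """Load a GFA 1.0 file into an :class:`AssemblyGraph`.

    Returns ``(graph, sequences)`` where ``sequences`` maps read_id to the
    forward-strand sequence for every S line that carried one.  One node is
    created per S line (forward orientation) and per additional
    (segment, orientation) pair referenced by an L line; one edge per L line.
    The overlap length is the source-consumed length of the L-line CIGAR.
    Edges whose overlap is not strictly shorter than both incident reads are
    dropped with a warning.
    """
    segments: dict[str, tuple[str | None, int]] = {}
    links: list[tuple[int, str, str, str, str, str, dict]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "H":
                continue
            if kind == "S":
                if len(fields) < 3:
                    raise GFAParseError(f"line {lineno}: S line needs name and sequence")
                name, seq = fields[1], fields[2]
                tags = _parse_tags(fields[3:], lineno)
                if seq == "*":
                    if "LN" not in tags:
                        raise GFAParseError(
                            f"line {lineno}: S line without sequence needs LN tag"
                        )
                    segments[name] = (None, int(tags["LN"][1]))
                else:
                    segments[name] = (seq.upper(), len(seq))
            elif kind == "L":
                if len(fields) < 6:
                    raise GFAParseError(f"line {lineno}: L line needs 5 fields + CIGAR")
                tags = _parse_tags(fields[6:], lineno)
                links.append(
                    (lineno, fields[1], fields[2], fields[3], fields[4], fields[5], tags)
                )
            # P/W and other record types are outside this dialect; ignore.

    graph = AssemblyGraph()
    sequences: dict[str, str] = {}
    node_index: dict[tuple[str, str], int] = {}
    for name, (seq, length) in segments.items():
        node = graph.add_node(name, "+", length)
        node_index[(name, "+")] = node.node_id
        if seq is not None:
            sequences[name] = seq

    def resolve(name: str, orient: str, lineno: int) -> int:
        if name not in segments:
            raise GFAReferenceError(f"line {lineno}: L line references unknown segment {name!r}")
        if orient not in "+-":
            raise GFAParseError(f"line {lineno}: bad orientation {orient!r}")
        key = (name, orient)
        if key not in node_index:
            node = graph.add_node(name, orient, segments[name][1])
            node_index[key] = node.node_id
        return node_index[key]

    for lineno, from_seg, from_orient, to_seg, to_orient, cigar, tags in links:
        src = resolve(from_seg, from_orient, lineno)
        dst = resolve(to_seg, to_orient, lineno)
        try:
            overlap = cigar_source_length(cigar)
        except ValueError as exc:
            raise GFAParseError(f"line {lineno}: {exc}") from exc
        min_len = min(graph.nodes[src].read_length, graph.nodes[dst].read_length)
        if not 0 < overlap < min_len:
            logger.warning(
                "line %d: dropping edge %s->%s with overlap %d not in (0, %d)",
                lineno, from_seg, to_seg, overlap, min_len,
            )
            continue
        if src == dst:
            logger.warning("line %d: dropping self-loop on %s", lineno, from_seg)
            continue
        graph.add_edge(src, dst, overlap, cigar)
    return graph, sequences


def write_gfa(
    graph: AssemblyGraph,
    path,
    sequences: dict[str, str] | None = None,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> None:
    """Write a GFA 1.0 file; one S line per distinct read, one L line per edge.

    ``scores`` (per-edge floats) go into a ``ps:f`` tag, ``labels`` (per-edge
    0/1) into a ``gt:i`` tag, both aligned to edge_id order.
    """
    sequences = sequences or {}
    if scores is not None and len(scores) != graph.num_edges:
        raise ValueError("scores not aligned to edges")
    if labels is not None and len(labels) != graph.num_edges:
        raise ValueError("labels not aligned to edges")
    with open(path, "w") as handle:
        handle.write("H\tVN:Z:1.0\n")
        seen: set[str] = set()
        for node in graph.nodes:
            if node.read_id in seen:
                continue
            seen.add(node.read_id)
            seq = sequences.get(node.read_id)
            if seq is None:
                handle.write(f"S\t{node.read_id}\t*\tLN:i:{node.read_length}\n")
            else:
                handle.write(f"S\t{node.read_id}\t{seq}\n")
        for edge in graph.edges:
            src = graph.nodes[edge.source]
            dst = graph.nodes[edge.target]
            cigar = edge.cigar if edge.cigar is not None else f"{edge.overlap_length}M"
            fields = [
                "L", src.read_id, src.orientation, dst.read_id, dst.orientation, cigar,
            ]
            if scores is not None:
                fields.append(f"{SCORE_TAG}:f:{float(scores[edge.edge_id]):.6g}")
            if labels is not None:
                fields.append(f"{LABEL_TAG}:i:{int(labels[edge.edge_id])}")
            handle.write("\t".join(fields) + "\n")


def read_gfa_tags(path, tag: str, typ: str = "f") -> np.ndarray:
    """Collect a per-edge tag (e.g. ``ps`` scores) from L lines, in file order."""
    values = []
    prefix = f"{tag}:{typ}:"
    cast = float if typ == "f" else int
    with open(path) as handle:
        for line in handle:
            if not line.startswith("L\t"):
                continue
            for raw in line.rstrip("\n").split("\t")[6:]:
                if raw.startswith(prefix):
                    values.append(cast(raw[len(prefix):]))
                    break
            else:
                raise ValueError(f"L line without {tag} tag: {line.strip()}")
    return np.asarray(values)
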