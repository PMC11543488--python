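"""Position-based ground-truth edge labels for assembly graphs.

An edge is a valid assembly step only if the two reads truly dovetail on the
genome (same strand, staggered start/end positions).  Among those retained
edges, tips — branches that a genome-spanning walk cannot both enter and
leave — are negative.  Tips are found with a pair of breadth-first sweeps:
forward from the lowest-starting read, backward from the farthest-reaching
read visited; edges traversed by both sweeps are positive, everything else
negative.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .graph import AssemblyGraph
from .simulate import SimulatedRead


class LabelingError(ValueError):
    pass


@dataclass
class EdgeLabels:
    """Per-edge 0/1 labels aligned to edge_id order."""

    labels: np.ndarray

    @property
    def positive_count(self) -> int:
        return int(self.labels.sum())

    @property
    def negative_count(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def _reads_by_node(graph: AssemblyGraph, reads: list[SimulatedRead]) -> list[SimulatedRead]:
    by_id = {r.read_id: r for r in reads}
    out = []
    for node in graph.nodes:
        read = by_id.get(node.read_id)
        if read is None:
            raise LabelingError(f"node {node.node_id} ({node.read_id}) has no coordinates")
        out.append(read)
    return out


def retain_edges(graph: AssemblyGraph, reads: list[SimulatedRead]) -> np.ndarray:
    """Boolean mask over edges: True iff the edge is a true positional dovetail.

    Edge A->B is retained iff strand(A) == strand(B), start(A) < start(B),
    end(A) > start(B) and end(B) > end(A).  Containments, disjoint pairs and
    strand mismatches are not retained.
    """
    node_reads = _reads_by_node(graph, reads)
    mask = np.zeros(graph.num_edges, dtype=bool)
    for edge in graph.edges:
        a, b = node_reads[edge.source], node_reads[edge.target]
        mask[edge.edge_id] = (
            a.strand == b.strand
            and a.start < b.start
            and a.end > b.start
            and b.end > a.end
        )
    return mask


def label_edges(
    graph: AssemblyGraph,
    retained: np.ndarray,
    reads: list[SimulatedRead],
    endpoint: str = "end",
) -> EdgeLabels:
    """Mark positive the retained edges traversed both forward and backward.

    Repeatedly: seed at the unvisited node with the lowest read start
    position (ties by read_id); BFS forward over retained edges; from the
    visited node with the highest position (read end by default,
    ``endpoint='start'`` switches to start coordinate), BFS backward against
    retained edges.  Edges swept in both directions get label 1; edges swept
    once, never reached, or not retained get 0.  The loop reseeds until every
    node has been visited, so every edge is labeled.
    """
    if endpoint not in ("end", "start"):
        raise ValueError("endpoint must be 'end' or 'start'")
    node_reads = _reads_by_node(graph, reads)
    m = graph.num_nodes
    forward_mark = np.zeros(graph.num_edges, dtype=bool)
    backward_mark = np.zeros(graph.num_edges, dtype=bool)
    visited_global = np.zeros(m, dtype=bool)

    def sort_key(nid: int):
        return (node_reads[nid].start, node_reads[nid].read_id)

    while not visited_global.all():
        seed = min(
            (nid for nid in range(m) if not visited_global[nid]), key=sort_key
        )
        # forward sweep
        component: list[int] = []
        seen = {seed}
        queue = deque([seed])
        while queue:
            u = queue.popleft()
            component.append(u)
            for eid in graph.out_edges[u]:
                if not retained[eid]:
                    continue
                forward_mark[eid] = True
                v = graph.edges[eid].target
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        # backward sweep from the farthest-reaching visited node
        if endpoint == "end":
            back_seed = max(component, key=lambda nid: (node_reads[nid].end, node_reads[nid].read_id))
        else:
            back_seed = max(component, key=lambda nid: (node_reads[nid].start, node_reads[nid].read_id))
        bseen = {back_seed}
        queue = deque([back_seed])
        while queue:
            v = queue.popleft()
            for eid in graph.in_edges[v]:
                if not retained[eid]:
                    continue
                backward_mark[eid] = True
                u = graph.edges[eid].source
                if u not in bseen:
                    bseen.add(u)
                    queue.append(u)
        for nid in seen | bseen:
            visited_global[nid] = True

    labels = (forward_mark & backward_mark & retained).astype(np.int8)
    return EdgeLabels(labels)


def label_graph(
    graph: AssemblyGraph, reads: list[SimulatedRead], endpoint: str = "end"
) -> EdgeLabels:
    """Convenience: retention followed by bidirectional-BFS labeling."""
    return label_edges(graph, retain_edges(graph, reads), reads, endpoint=endpoint)


def class_balance(labels: EdgeLabels) -> float:
    """Positive:negative ratio, with a guarded denominator."""
    n = len(labels.labels)
    if n == 0:
        raise LabelingError("cannot compute class balance of an empty graph")
    return labels.positive_count / max(labels.negative_count, 1)


def write_labels(labels: EdgeLabels, path) -> None:
    """Two-column text table: edge_id, label."""
    with open(path, "w") as handle:
        handle.write("edge_id\tlabel\n")
        for eid, lab in enumerate(labels.labels):
            handle.write(f"{eid}\t{int(lab)}\n")


def read_labels(path) -> EdgeLabels:
    values = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("edge_id"):
            raise ValueError("expected 'edge_id\\tlabel' header")
        for line in handle:
            _, lab = line.split()
            values.append(int(lab))
    return EdgeLabels(np.asarray(values, dtype=np.int8))
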