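"""Greedy path search over a scored assembly graph and contig construction.

Decoding is iterative: take the N highest-scoring edges whose endpoints are
still unvisited, extend each bidirectionally by always following the
highest-scoring admissible edge, keep the candidate yielding the longest
contig, mark its nodes visited, and repeat until the best path falls below a
minimum read count.  Reads along each winning path are concatenated,
trimming each overlap once, to form contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import AssemblyGraph


@dataclass
class AssemblyPath:
    """An ordered walk: ``node_sequence[i] -> node_sequence[i+1]`` via ``edge_sequence[i]``."""

    node_sequence: list[int]
    edge_sequence: list[int]

    def __len__(self) -> int:
        return len(self.node_sequence)

    def path_bases(self, graph: AssemblyGraph) -> int:
        """Contig length implied by the path: sum of read lengths minus overlaps."""
        total = sum(graph.nodes[n].read_length for n in self.node_sequence)
        total -= sum(graph.edges[e].overlap_length for e in self.edge_sequence)
        return total


@dataclass
class Contig:
    name: str
    sequence: str
    path: AssemblyPath


@dataclass
class ContigSet:
    contigs: list[Contig] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contigs)

    def lengths(self) -> list[int]:
        return [len(c.sequence) for c in self.contigs]

    def to_fasta(self, path) -> None:
        with open(path, "w") as handle:
            for contig in self.contigs:
                handle.write(f">{contig.name} reads={len(contig.path)}\n")
                handle.write(contig.sequence + "\n")


def _best_edge(graph, scores, edge_ids, blocked, pick_node) -> int | None:
    """Highest-scoring admissible edge; ties broken by lowest edge_id."""
    best = None
    for eid in edge_ids:
        if pick_node(graph.edges[eid]) in blocked:
            continue
        if best is None or scores[eid] > scores[best] or (
            scores[eid] == scores[best] and eid < best
        ):
            best = eid
    return best


def greedy_extend(
    graph: AssemblyGraph,
    scores: np.ndarray,
    start_edge: int,
    visited: set[int],
    direction: str = "forward",
) -> AssemblyPath:
    """Extend greedily from one edge in one direction.

    Forward: repeatedly follow the best-scoring out-edge of the path head
    whose target is unvisited.  Backward: follow the best in-edge of the
    path tail whose source is unvisited.  The returned path includes the
    start edge.  ``visited`` is not modified.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    edge = graph.edges[start_edge]
    nodes = [edge.source, edge.target]
    edges = [start_edge]
    blocked = set(visited) | set(nodes)
    if direction == "forward":
        current = edge.target
        while True:
            eid = _best_edge(
                graph, scores, graph.out_edges[current], blocked, lambda e: e.target
            )
            if eid is None:
                break
            current = graph.edges[eid].target
            nodes.append(current)
            edges.append(eid)
            blocked.add(current)
    else:
        current = edge.source
        while True:
            eid = _best_edge(
                graph, scores, graph.in_edges[current], blocked, lambda e: e.source
            )
            if eid is None:
                break
            current = graph.edges[eid].source
            nodes.insert(0, current)
            edges.insert(0, eid)
            blocked.add(current)
    return AssemblyPath(nodes, edges)


def _bidirectional(graph, scores, start_edge, visited) -> AssemblyPath:
    """Backward path (reversed) + start edge + forward path, nodes unique."""
    forward = greedy_extend(graph, scores, start_edge, visited, "forward")
    # block the forward part so the backward sweep cannot reuse its nodes
    backward = greedy_extend(
        graph, scores, start_edge, visited | set(forward.node_sequence), "backward"
    )
    nodes = backward.node_sequence[:-2] + forward.node_sequence
    edges = backward.edge_sequence[:-1] + forward.edge_sequence
    return AssemblyPath(nodes, edges)


def decode(
    graph: AssemblyGraph,
    scores: np.ndarray,
    n_candidates: int = 16,
    min_path_reads: int = 3,
    seed: int = 0,
) -> list[AssemblyPath]:
    """Iterative N-start bidirectional greedy search.

    Per iteration the ``n_candidates`` highest-scoring edges between
    unvisited nodes seed candidate paths (equal scores are ordered by a
    seeded random key); candidates may overlap each other, but only the
    winner — the candidate implying the longest contig — has its nodes
    marked visited.  Iteration stops when the best candidate has fewer than
    ``min_path_reads`` reads.  Emitted paths are node-disjoint.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) != graph.num_edges:
        raise ValueError("scores not aligned to edges")
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(graph.num_edges) if graph.num_edges else np.empty(0)
    order = sorted(
        range(graph.num_edges), key=lambda eid: (-scores[eid], tiebreak[eid])
    )
    visited: set[int] = set()
    paths: list[AssemblyPath] = []
    while True:
        candidates = []
        for eid in order:
            edge = graph.edges[eid]
            if edge.source in visited or edge.target in visited:
                continue
            candidates.append(eid)
            if len(candidates) == n_candidates:
                break
        if not candidates:
            break
        best_path = None
        best_len = -1
        for eid in candidates:
            path = _bidirectional(graph, scores, eid, visited)
            length = path.path_bases(graph)
            if length > best_len:
                best_len = length
                best_path = path
        if best_path is None or len(best_path) < min_path_reads:
            break
        visited.update(best_path.node_sequence)
        paths.append(best_path)
    return paths


class MalformedPathError(ValueError):
    pass


def paths_to_contigs(
    paths: list[AssemblyPath],
    read_sequences: dict[str, str],
    graph: AssemblyGraph,
    name_prefix: str = "contig",
) -> ContigSet:
    """Concatenate reads along each path, trimming each overlap once.

    contig = first read + each subsequent read minus its overlap-length
    prefix.  Reads on '-' nodes contribute their reverse complement.
    """
    from .simulate import revcomp

    contigs = []
    for i, path in enumerate(paths):
        parts = []
        for j, nid in enumerate(path.node_sequence):
            node = graph.nodes[nid]
            seq = read_sequences[node.read_id]
            if node.orientation == "-":
                seq = revcomp(seq)
            if j == 0:
                parts.append(seq)
            else:
                overlap = graph.edges[path.edge_sequence[j - 1]].overlap_length
                if overlap >= len(seq):
                    raise MalformedPathError(
                        f"path {i}: overlap {overlap} >= read length {len(seq)}"
                    )
                parts.append(seq[overlap:])
        contigs.append(Contig(f"{name_prefix}_{i}", "".join(parts), path))
    return ContigSet(contigs)


def write_paths(paths: list[AssemblyPath], graph: AssemblyGraph, path) -> None:
    """Text table: contig name then the ordered read ids of its path."""
    with open(path, "w") as handle:
        for i, p in enumerate(paths):
            reads = "\t".join(graph.nodes[n].read_id for n in p.node_sequence)
            handle.write(f"contig_{i}\t{reads}\n")
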