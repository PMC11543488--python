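import numpy as np
import pytest

from graphasm.graph import AssemblyGraph
from graphasm.labels import label_graph
from graphasm.layout import (
    MalformedPathError,
    decode,
    greedy_extend,
    paths_to_contigs,
)

from conftest import make_chain, random_graph


def random_dag(rng, max_nodes=12):
    """Random DAG whose edges respect a topological node order."""
    m = int(rng.integers(4, max_nodes + 1))
    graph = AssemblyGraph()
    for i in range(m):
        graph.add_node(f"r{i}", "+", 1000)
    for u in range(m):
        for v in range(u + 1, m):
            if rng.random() < 0.35:
                graph.add_edge(u, v, int(rng.integers(1, 500)))
    # discrete scores force ties to exercise the edge-id tie-break
    scores = rng.choice([0.2, 0.5, 0.8], size=graph.num_edges)
    return graph, scores


def oracle_extend(graph, scores, start_edge, visited, direction):
    """Step-wise exhaustive re-application of the greedy rule (independent)."""
    edge = graph.edges[start_edge]
    nodes = [edge.source, edge.target]
    edges = [start_edge]
    blocked = set(visited) | set(nodes)
    while True:
        if direction == "forward":
            frontier = [
                e for e in graph.edges
                if e.source == nodes[-1] and e.target not in blocked
            ]
        else:
            frontier = [
                e for e in graph.edges
                if e.target == nodes[0] and e.source not in blocked
            ]
        if not frontier:
            return nodes, edges
        best = max(frontier, key=lambda e: (scores[e.edge_id], -e.edge_id))
        if direction == "forward":
            nodes.append(best.target)
            edges.append(best.edge_id)
            blocked.add(best.target)
        else:
            nodes.insert(0, best.source)
            edges.insert(0, best.edge_id)
            blocked.add(best.source)


class TestGreedyExtend:
    def test_dead_end_returns_start_edge_only(self):
        graph = make_chain([100, 100], [40])
        path = greedy_extend(graph, np.array([0.9]), 0, set(), "forward")
        assert path.node_sequence == [0, 1]
        assert path.edge_sequence == [0]

    def test_decreasing_chain_fully_traversed(self):
        graph = make_chain([100] * 5, [40] * 4)
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        path = greedy_extend(graph, scores, 0, set(), "forward")
        assert path.node_sequence == [0, 1, 2, 3, 4]

    def test_backward_direction(self):
        graph = make_chain([100] * 4, [40] * 3)
        path = greedy_extend(graph, np.array([0.5] * 3), 2, set(), "backward")
        assert path.node_sequence == [0, 1, 2, 3]
        assert path.edge_sequence == [0, 1, 2]

    def test_visited_nodes_skipped(self):
        graph = make_chain([100] * 4, [40] * 3)
        path = greedy_extend(graph, np.array([0.5] * 3), 0, {3}, "forward")
        assert path.node_sequence == [0, 1, 2]

    def test_matches_stepwise_oracle_on_random_dags(self):
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(40):
            graph, scores = random_dag(rng)
            if graph.num_edges == 0:
                continue
            start = int(rng.integers(graph.num_edges))
            for direction in ("forward", "backward"):
                path = greedy_extend(graph, scores, start, set(), direction)
                nodes, edges = oracle_extend(graph, scores, start, set(), direction)
                assert path.node_sequence == nodes
                assert path.edge_sequence == edges
                checked += 1
        assert checked >= 40


class TestDecode:
    def test_single_chain_single_path(self):
        graph = make_chain([100] * 6, [40] * 5)
        paths = decode(graph, np.full(5, 0.9), n_candidates=4, min_path_reads=2, seed=0)
        assert len(paths) == 1
        assert paths[0].node_sequence == [0, 1, 2, 3, 4, 5]

    def test_two_chains_longest_first(self):
        graph = AssemblyGraph()
        for i in range(13):
            graph.add_node(f"r{i}", "+", 100)
        for i in range(9):
            graph.add_edge(i, i + 1, 40)       # 10-node chain
        for i in range(10, 12):
            graph.add_edge(i, i + 1, 40)       # 3-node chain
        scores = np.full(graph.num_edges, 0.8)
        paths = decode(graph, scores, n_candidates=4, min_path_reads=2, seed=1)
        assert len(paths) == 2
        assert len(paths[0]) == 10
        assert len(paths[1]) == 3

    def test_min_path_reads_stops_iteration(self):
        graph = make_chain([100, 100], [40])
        assert decode(graph, np.array([0.9]), min_path_reads=3, seed=0) == []

    def test_emitted_paths_node_disjoint_random(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            graph, scores = random_dag(rng, max_nodes=15)
            if graph.num_edges == 0:
                continue
            paths = decode(graph, scores, n_candidates=3, min_path_reads=2, seed=3)
            seen = set()
            for path in paths:
                assert not (set(path.node_sequence) & seen)
                seen.update(path.node_sequence)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(21)
        graph, scores = random_dag(rng, max_nodes=12)
        a = decode(graph, scores, seed=5, min_path_reads=2)
        b = decode(graph, scores, seed=5, min_path_reads=2)
        assert [p.node_sequence for p in a] == [p.node_sequence for p in b]

    def test_empty_graph(self):
        assert decode(AssemblyGraph(), np.zeros(0), seed=0) == []


class TestPathsToContigs:
    def test_overlap_arithmetic(self):
        graph = make_chain([100, 100], [40])
        seqs = {"r0": "A" * 100, "r1": "C" * 100}
        paths = decode(graph, np.array([0.9]), min_path_reads=2, seed=0)
        contigs = paths_to_contigs(paths, seqs, graph)
        assert len(contigs.contigs[0].sequence) == 160

    def test_single_read_path(self):
        from graphasm.layout import AssemblyPath

        graph = make_chain([50], [])
        contigs = paths_to_contigs([AssemblyPath([0], [])], {"r0": "G" * 50}, graph)
        assert contigs.contigs[0].sequence == "G" * 50

    def test_malformed_overlap_raises(self):
        graph = make_chain([100, 100], [40])
        seqs = {"r0": "A" * 100, "r1": "C" * 30}  # next read shorter than overlap
        paths = decode(graph, np.array([0.9]), min_path_reads=2, seed=0)
        with pytest.raises(MalformedPathError):
            paths_to_contigs(paths, seqs, graph)

    def test_oracle_decoding_reconstructs_clean_genome(self, clean_sim):
        genome, reads, graph = clean_sim
        labels = label_graph(graph, reads)
        scores = labels.labels.astype(float)
        paths = decode(graph, scores, n_candidates=8, min_path_reads=3, seed=0)
        seqs = {r.read_id: r.sequence for r in reads}
        contigs = paths_to_contigs(paths, seqs, graph)
        longest = max(contigs.contigs, key=lambda c: len(c.sequence))
        assert longest.sequence in genome.sequence
        assert len(longest.sequence) >= 0.99 * len(genome)

    def test_length_conservation(self, clean_sim):
        genome, reads, graph = clean_sim
        labels = label_graph(graph, reads)
        paths = decode(graph, labels.labels.astype(float), seed=0)
        seqs = {r.read_id: r.sequence for r in reads}
        contigs = paths_to_contigs(paths, seqs, graph)
        total_reads = sum(len(r.sequence) for r in reads)
        for contig in contigs.contigs:
            expected = sum(
                graph.nodes[n].read_length for n in contig.path.node_sequence
            ) - sum(
                graph.edges[e].overlap_length for e in contig.path.edge_sequence
            )
            assert len(contig.sequence) == expected
        assert sum(contigs.lengths()) <= total_reads
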