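import numpy as np
import pytest

from graphasm.features import extract_features
from graphasm.graph import AssemblyGraph
from graphasm.labels import label_graph
from graphasm.simulate import build_overlap_graph, generate_genome, simulate_reads
from graphasm.train import LabeledGraph


def make_chain(lengths, overlaps):
    """Linear chain graph: node i -> node i+1 with the given overlaps."""
    graph = AssemblyGraph()
    for i, length in enumerate(lengths):
        graph.add_node(f"r{i}", "+", length)
    for i, ol in enumerate(overlaps):
        graph.add_edge(i, i + 1, ol)
    return graph


def random_graph(m, n_edges, rng, read_length=1000, max_overlap=500):
    """Random simple directed graph without self-loops or duplicate edges."""
    graph = AssemblyGraph()
    for i in range(m):
        graph.add_node(f"r{i}", "+", read_length)
    seen = set()
    while graph.num_edges < n_edges:
        u, v = rng.integers(0, m, size=2)
        if u == v or (u, v) in seen:
            continue
        seen.add((u, v))
        graph.add_edge(int(u), int(v), int(rng.integers(1, max_overlap)))
    return graph


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free, repeat-free simulation: genome, reads, overlap graph."""
    genome = generate_genome(60_000, repeat_fraction=0.0, seed=11)
    reads = simulate_reads(
        genome, coverage=12, mean_length=4_000, length_sd=800, error_rate=0.0, seed=11
    )
    graph = build_overlap_graph(reads, min_overlap=500)
    return genome, reads, graph


@pytest.fixture(scope="session")
def repeat_sim():
    """Simulation with a multi-copy repeat family (negative edges present)."""
    genome = generate_genome(50_000, seed=5)
    reads = simulate_reads(
        genome, coverage=15, mean_length=4_000, length_sd=800, error_rate=0.0, seed=5
    )
    graph = build_overlap_graph(reads, min_overlap=500, repeat_annotations=genome.repeat_annotations)
    return genome, reads, graph


@pytest.fixture(scope="session")
def labeled_repeat_sim(repeat_sim):
    genome, reads, graph = repeat_sim
    labels = label_graph(graph, reads)
    features = extract_features(graph)
    return LabeledGraph(graph, features, labels), reads, genome
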