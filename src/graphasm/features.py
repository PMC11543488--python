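"""Raw node/edge features of an assembly graph and their dense embedding.

Node features are the out- and in-degree of each vertex; edge features are
the overlap length and the overlap similarity

    overlap_similarity = (overlap_length - edit_distance) / overlap_length

where the edit distance is the Levenshtein distance between the source
read's overlap suffix and the target read's overlap prefix (computed with
edlib).  Both 2-column matrices are lifted to the model width with a
three-layer fully connected map with ReLU activations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:
    import edlib
except ImportError:  # pragma: no cover - edlib is a hard dependency
    edlib = None

from .autodiff import Tensor
from .graph import AssemblyGraph, Edge, degrees

DEFAULT_DIM = 64


@dataclass
class FeatureSet:
    """Raw (m x 2 node, n x 2 edge) feature matrices in graph index order."""

    node_raw: np.ndarray
    edge_raw: np.ndarray

    def __post_init__(self) -> None:
        self.node_raw = np.asarray(self.node_raw, dtype=np.float64)
        self.edge_raw = np.asarray(self.edge_raw, dtype=np.float64)


def overlap_similarity(overlap_length: int, edit_distance: int) -> float:
    """``max(0, (ol - ed) / ol)``; the clamp keeps noisy edges in [0, 1]."""
    if overlap_length <= 0:
        raise ValueError("overlap_length must be positive")
    if edit_distance < 0:
        raise ValueError("edit_distance must be non-negative")
    return max(0.0, (overlap_length - edit_distance) / overlap_length)


def edge_edit_distance(
    graph: AssemblyGraph, read_sequences: dict[str, str], edge: Edge
) -> int:
    """Levenshtein distance between the overlap suffix and prefix of an edge.

    The compared windows are the source read's last ``overlap_length`` bases
    and the target read's first ``overlap_length`` bases (global alignment,
    reads taken in their node orientation).
    """
    src = graph.nodes[edge.source]
    dst = graph.nodes[edge.target]
    ol = edge.overlap_length
    try:
        s_seq = read_sequences[src.read_id]
        t_seq = read_sequences[dst.read_id]
    except KeyError as exc:
        raise KeyError(f"no sequence for read {exc.args[0]!r}") from exc
    if src.orientation == "-":
        s_seq = _revcomp(s_seq)
    if dst.orientation == "-":
        t_seq = _revcomp(t_seq)
    if len(s_seq) < ol or len(t_seq) < ol:
        raise ValueError(
            f"edge {edge.edge_id}: overlap {ol} exceeds a read length"
        )
    suffix = s_seq[-ol:]
    prefix = t_seq[:ol]
    result = edlib.align(suffix, prefix, mode="NW", task="distance")
    return int(result["editDistance"])


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def extract_features(
    graph: AssemblyGraph,
    read_sequences: dict[str, str] | None = None,
    zscore: bool = False,
) -> FeatureSet:
    """Raw feature matrices for a graph.

    Without sequences every edge similarity is set to 1.0 (exact overlaps).
    ``zscore`` optionally standardizes each raw column (default off: raw
    degrees and overlap lengths are used as-is).
    """
    node_raw = degrees(graph).astype(np.float64)
    edge_raw = np.zeros((graph.num_edges, 2), dtype=np.float64)
    for edge in graph.edges:
        edge_raw[edge.edge_id, 0] = edge.overlap_length
        if read_sequences is None:
            edge_raw[edge.edge_id, 1] = 1.0
        else:
            ed = edge_edit_distance(graph, read_sequences, edge)
            edge_raw[edge.edge_id, 1] = overlap_similarity(edge.overlap_length, ed)
    if zscore:
        for mat in (node_raw, edge_raw):
            if len(mat):
                sd = mat.std(axis=0)
                sd[sd == 0] = 1.0
                mat -= mat.mean(axis=0)
                mat /= sd
    return FeatureSet(node_raw, edge_raw)


def init_embed_params(
    in_dim: int, d: int, rng: np.random.Generator
) -> list[tuple[Tensor, Tensor]]:
    """He-initialized weights for the three-layer embedding ``in_dim -> d``."""
    dims = [in_dim, d, d, d]
    params = []
    for a, b in zip(dims[:-1], dims[1:]):
        w = Tensor(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)), requires_grad=True)
        bias = Tensor(np.zeros(b), requires_grad=True)
        params.append((w, bias))
    return params


def embed(raw, weights: list[tuple[Tensor, Tensor]]) -> Tensor:
    """Three affine maps with ReLU between them, applied row-wise.

    ``raw`` may be a numpy matrix or a Tensor; the output is a Tensor of
    width equal to the last weight's output dimension.
    """
    x = raw if isinstance(raw, Tensor) else Tensor(raw)
    if not np.all(np.isfinite(x.data)):
        raise ValueError("non-finite values in raw features")
    for i, (w, b) in enumerate(weights):
        x = x @ w + b
        if i < len(weights) - 1:
            x = x.relu()
    return x
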