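"""Supervised training of the edge scorer on labeled assembly graphs.

The learning task is binary edge classification: predict the position-derived
ground-truth label of every overlap edge.  Graphs are split into node-disjoint
subgraphs (METIS if importable, otherwise a seeded BFS-growing partitioner
with the same contract), one optimizer step per subgraph, with Adam on a
class-weighted binary cross-entropy: negatives usually dominate, so positive
examples are up-weighted by the negative:positive ratio (``auto`` mode).
Everything is seeded; two runs with the same seed produce identical loss
trajectories.
"""

from __future__ import annotations

import copy
import csv
import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor
from .features import FeatureSet
from .graph import AssemblyGraph
from .labels import EdgeLabels
from .model import EdgeScorer, ModelConfig

logger = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 50
    seed: int = 0
    partition_count: int = 1
    pos_weight_mode: str = "auto"  # "auto": negatives/positives; "fixed": pos_weight
    pos_weight: float = 1.0
    patience: int = 10

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.partition_count < 1:
            raise ValueError("partition_count must be >= 1")
        if self.pos_weight_mode not in ("auto", "fixed"):
            raise ValueError("pos_weight_mode must be 'auto' or 'fixed'")


@dataclass
class LabeledGraph:
    """A graph together with its raw features and ground-truth edge labels."""

    graph: AssemblyGraph
    features: FeatureSet
    labels: EdgeLabels


@dataclass
class Subgraph:
    """A node-induced subgraph with mappings back to the parent graph."""

    graph: AssemblyGraph
    node_map: np.ndarray  # local node_id -> global node_id
    edge_map: np.ndarray  # local edge_id -> global edge_id


def partition_graph(
    graph: AssemblyGraph, parts: int, seed: int = 0
) -> list[Subgraph]:
    """Node-disjoint partition into ``parts`` subgraphs with id mappings.

    Uses METIS when the pymetis bindings are importable; otherwise grows
    parts by synchronized BFS from seeded start nodes, which gives the same
    contract (every node in exactly one part, each subgraph keeping only its
    internal edges).  Cross-partition edges belong to no subgraph.
    """
    m = graph.num_nodes
    if parts > m:
        raise ValueError(f"cannot split {m} nodes into {parts} parts")
    if parts == 1:
        assignment = np.zeros(m, dtype=np.intp)
    else:
        assignment = _metis_assignment(graph, parts)
        if assignment is None:
            assignment = _bfs_assignment(graph, parts, seed)
    subgraphs = []
    for part in range(parts):
        node_ids = np.nonzero(assignment == part)[0]
        local = {int(g): i for i, g in enumerate(node_ids)}
        sub = AssemblyGraph()
        for gid in node_ids:
            node = graph.nodes[gid]
            sub.add_node(node.read_id, node.orientation, node.read_length)
        edge_ids = []
        for edge in graph.edges:
            if edge.source in local and edge.target in local:
                sub.add_edge(
                    local[edge.source], local[edge.target], edge.overlap_length, edge.cigar
                )
                edge_ids.append(edge.edge_id)
        subgraphs.append(Subgraph(sub, node_ids, np.asarray(edge_ids, dtype=np.intp)))
    dropped = graph.num_edges - sum(len(s.edge_map) for s in subgraphs)
    if dropped:
        logger.info("partitioning dropped %d cross-partition edges", dropped)
    return subgraphs


def _metis_assignment(graph: AssemblyGraph, parts: int) -> np.ndarray | None:
    try:
        import pymetis
    except ImportError:
        return None
    adj = [[] for _ in range(graph.num_nodes)]
    for edge in graph.edges:
        adj[edge.source].append(edge.target)
        adj[edge.target].append(edge.source)
    _, membership = pymetis.part_graph(parts, adjacency=adj)
    return np.asarray(membership, dtype=np.intp)


def _bfs_assignment(graph: AssemblyGraph, parts: int, seed: int) -> np.ndarray:
    """Grow ``parts`` regions by synchronized BFS from random distinct seeds."""
    m = graph.num_nodes
    rng = np.random.default_rng(seed)
    assignment = np.full(m, -1, dtype=np.intp)
    neighbors = [[] for _ in range(m)]
    for edge in graph.edges:
        neighbors[edge.source].append(edge.target)
        neighbors[edge.target].append(edge.source)
    seeds = rng.choice(m, size=parts, replace=False)
    queues = [deque([int(s)]) for s in seeds]
    for part, s in enumerate(seeds):
        assignment[s] = part
    sizes = [1] * parts
    remaining = m - parts
    while remaining > 0:
        progressed = False
        for part in range(parts):
            queue = queues[part]
            while queue:
                u = queue.popleft()
                claimed = False
                for v in neighbors[u]:
                    if assignment[v] == -1:
                        assignment[v] = part
                        sizes[part] += 1
                        remaining -= 1
                        queue.append(v)
                        claimed = True
                if claimed:
                    progressed = True
                    break
        if not progressed:
            # disconnected remainder: reseed into the smallest part
            unassigned = np.nonzero(assignment == -1)[0]
            if len(unassigned) == 0:
                break
            part = int(np.argmin(sizes))
            s = int(unassigned[0])
            assignment[s] = part
            sizes[part] += 1
            remaining -= 1
            queues[part].append(s)
    return assignment


def weighted_bce(predictions, labels, pos_weight: float = 1.0):
    """Mean of ``-[w*y*log(p) + (1-y)*log(1-p)]`` over edges.

    Accepts a Tensor (returns a Tensor, for training) or an array (returns a
    float).  Predictions at exactly 0 or 1 are clipped to ``1e-7`` away from
    the boundary.
    """
    y = labels.labels if isinstance(labels, EdgeLabels) else np.asarray(labels)
    y = y.astype(np.float64)
    is_tensor = isinstance(predictions, Tensor)
    p = predictions if is_tensor else Tensor(np.asarray(predictions, dtype=np.float64))
    if np.any(p.data <= 0) or np.any(p.data >= 1):
        logger.debug("clipping predictions at the (0,1) boundary")
    p = p.clip(_EPS, 1 - _EPS)
    yt = Tensor(y)
    loss = -(yt * p.log() * pos_weight + (1.0 - yt) * (1.0 - p).log()).mean()
    return loss if is_tensor else float(loss.data)


def classification_metrics(scores: np.ndarray, labels: EdgeLabels) -> dict[str, float]:
    """Accuracy, F1 and the majority-class baseline at threshold 0.5."""
    y = labels.labels.astype(int)
    pred = (np.asarray(scores) >= 0.5).astype(int)
    acc = float((pred == y).mean()) if len(y) else float("nan")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    baseline = float(max(y.mean(), 1 - y.mean())) if len(y) else float("nan")
    return {"accuracy": acc, "f1": f1, "majority_baseline": baseline}


@dataclass
class TrainResult:
    model: EdgeScorer
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1


def _snapshot(model: EdgeScorer):
    return (
        [p.data.copy() for p in model.parameters()],
        [copy.deepcopy(n.state()) for n in model._norms()],
    )


def _restore(model: EdgeScorer, snap) -> None:
    params, norms = snap
    for p, data in zip(model.parameters(), params):
        p.data = data.copy()
    for norm, state in zip(model._norms(), norms):
        norm.running_mean = state["running_mean"].copy()
        norm.running_var = state["running_var"].copy()


def train(
    train_graphs: list[LabeledGraph],
    val_graphs: list[LabeledGraph],
    config: TrainConfig | None = None,
    model: EdgeScorer | None = None,
    model_config: ModelConfig | None = None,
    metrics_path=None,
) -> TrainResult:
    """Optimize the scorer on the training graphs, early-stopping on validation.

    One Adam step per subgraph per epoch; the best-validation-loss parameters
    are restored before returning.  ``epochs=0`` returns the freshly
    initialized model with an empty history.
    """
    config = config or TrainConfig()
    if not train_graphs:
        raise ValueError("need at least one training graph")
    if not val_graphs:
        raise ValueError("validation set must not be empty")
    if model is None:
        model = EdgeScorer(model_config, seed=config.seed)

    if config.pos_weight_mode == "auto":
        pos = sum(g.labels.positive_count for g in train_graphs)
        neg = sum(g.labels.negative_count for g in train_graphs)
        # single-class label sets degenerate to uniform weighting
        pos_weight = neg / pos if pos > 0 and neg > 0 else 1.0
    else:
        pos_weight = config.pos_weight
    logger.info("pos_weight = %.4f", pos_weight)

    # fixed partitioning, computed once
    steps: list[tuple[Subgraph, FeatureSet, EdgeLabels]] = []
    for gi, lg in enumerate(train_graphs):
        parts = min(config.partition_count, lg.graph.num_nodes)
        for sub in partition_graph(lg.graph, parts, seed=config.seed + gi):
            if sub.graph.num_edges == 0:
                continue
            feats = FeatureSet(
                lg.features.node_raw[sub.node_map], lg.features.edge_raw[sub.edge_map]
            )
            labs = EdgeLabels(lg.labels.labels[sub.edge_map])
            steps.append((sub, feats, labs))

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best = (np.inf, -1, _snapshot(model))
    since_best = 0

    for epoch in range(config.epochs):
        train_losses = []
        for sub, feats, labs in steps:
            optimizer.zero_grad()
            pred = model.forward(sub.graph, feats, training=True, rng=rng)
            loss = weighted_bce(pred, labs, pos_weight)
            loss.backward()
            optimizer.step()
            train_losses.append(float(loss.data))
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        val_losses, val_scores, val_labels = [], [], []
        for lg in val_graphs:
            scores = model.score_edges(lg.graph, lg.features)
            val_losses.append(weighted_bce(scores, lg.labels, pos_weight))
            val_scores.append(scores)
            val_labels.append(lg.labels.labels)
        val_loss = float(np.mean(val_losses))
        merged = classification_metrics(
            np.concatenate(val_scores), EdgeLabels(np.concatenate(val_labels))
        )
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(train_losses)),
            "val_loss": val_loss,
            "val_accuracy": merged["accuracy"],
            "val_f1": merged["f1"],
        }
        history.append(record)
        logger.info(
            "epoch %d: train %.4f val %.4f acc %.4f f1 %.4f",
            epoch, record["train_loss"], val_loss, merged["accuracy"], merged["f1"],
        )
        if val_loss < best[0]:
            best = (val_loss, epoch, _snapshot(model))
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                logger.info("early stop at epoch %d", epoch)
                break

    _restore(model, best[2])
    if metrics_path is not None and history:
        with open(metrics_path, "w", newline="") as handle:
            writer = csv.DictWriter(handle, fieldnames=list(history[0]))
            writer.writeheader()
            writer.writerows(history)
    return TrainResult(model=model, history=history, best_epoch=best[1])
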