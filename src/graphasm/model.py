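"""Edge-conditioned graph-transformer scorer for assembly-graph edges.

Node and edge features are embedded to width ``d``, Laplacian positional
encodings are added to the node stream, and ``L`` transformer layers update
both streams.  Per layer and per head, the attention logit for an edge
j -> i is the scaled dot product of the receiving node's query with the
neighbor's key, modulated elementwise by a projection of the edge feature;
logits are clamped to ``[-clamp, +clamp]`` for numerical stability before a
softmax over each node's in-neighbors.  Both streams pass residual + batch
normalization around a two-layer ReLU feed-forward block.  Each edge is
finally scored by a three-layer MLP on [h_source, h_target, e_edge] followed
by a sigmoid, giving a probability in (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.linalg

from .autodiff import Tensor, concat, gather_rows, segment_softmax, segment_sum
from .features import FeatureSet, embed, init_embed_params
from .graph import AssemblyGraph


@dataclass
class ModelConfig:
    d: int = 64
    heads: int = 8
    layers: int = 4
    lappe_k: int = 16
    clamp: float = 5.0
    mlp_hidden: tuple[int, ...] = (64, 32, 1)
    edge_gate: str = "multiplicative"  # or "additive" (ablation)
    normalized_laplacian: bool = True

    def __post_init__(self) -> None:
        if self.d % self.heads:
            raise ValueError("hidden dimension d must be divisible by heads")
        if self.clamp <= 0:
            raise ValueError("clamp must be positive")
        if self.edge_gate not in ("multiplicative", "additive"):
            raise ValueError("edge_gate must be 'multiplicative' or 'additive'")

    @property
    def d_head(self) -> int:
        return self.d // self.heads


# --------------------------------------------------------------------- LapPE


def laplacian_matrix(graph: AssemblyGraph, normalized: bool = True) -> np.ndarray:
    """Laplacian of the undirected, unweighted version of the graph."""
    m = graph.num_nodes
    a = np.zeros((m, m))
    for edge in graph.edges:
        a[edge.source, edge.target] = 1.0
        a[edge.target, edge.source] = 1.0
    deg = a.sum(axis=1)
    if not normalized:
        return np.diag(deg) - a
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    lap = -a * dinv[:, None] * dinv[None, :]
    np.fill_diagonal(lap, np.where(deg > 0, 1.0, 0.0))
    return lap


def laplacian_spectrum(graph: AssemblyGraph, normalized: bool = True) -> np.ndarray:
    """All Laplacian eigenvalues, ascending (zero multiplicity = #components)."""
    return scipy.linalg.eigh(laplacian_matrix(graph, normalized), eigvals_only=True)


def laplacian_pe(
    graph: AssemblyGraph,
    k: int,
    normalized: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """m x k matrix of Laplacian eigenvectors, smallest nontrivial first.

    The single globally smallest eigenvalue (the trivial constant mode on a
    connected graph) is skipped.  Signs are fixed deterministically — the
    entry of largest magnitude is made positive — unless ``rng`` is given,
    in which case each column's sign is flipped uniformly at random (the
    standard training-time augmentation).
    """
    m = graph.num_nodes
    if m == 0:
        raise ValueError("empty graph")
    if k >= m:
        raise ValueError(f"lappe_k={k} must be < number of nodes ({m})")
    lap = laplacian_matrix(graph, normalized)
    vals, vecs = scipy.linalg.eigh(lap)
    pe = vecs[:, 1 : k + 1].copy()
    for j in range(pe.shape[1]):
        col = pe[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            col *= -1.0
    if rng is not None:
        pe *= np.where(rng.random(pe.shape[1]) < 0.5, -1.0, 1.0)
    return pe


# ----------------------------------------------------------------- BatchNorm


class BatchNorm:
    """1-d batch normalization with running statistics for eval mode."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            )
            n = x.shape[0]
            unbiased = var.data[0] * n / max(n - 1, 1)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
        else:
            mu = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


# --------------------------------------------------------------------- model


def _linear(rng, a, b):
    w = Tensor(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)), requires_grad=True)
    bias = Tensor(np.zeros(b), requires_grad=True)
    return w, bias


class TransformerLayer:
    """One edge-aware attention layer updating node and edge streams."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.d
        self.cfg = cfg
        self.wq, self.bq = _linear(rng, d, d)
        self.wk, self.bk = _linear(rng, d, d)
        self.wv, self.bv = _linear(rng, d, d)
        self.we, self.be = _linear(rng, d, d)
        self.oh, self.boh = _linear(rng, d, d)
        self.oe, self.boe = _linear(rng, d, d)
        self.w1, self.b1 = _linear(rng, d, 2 * d)
        self.w2, self.b2 = _linear(rng, 2 * d, d)
        self.we1, self.be1 = _linear(rng, d, 2 * d)
        self.we2, self.be2 = _linear(rng, 2 * d, d)
        self.last_attention: np.ndarray | None = None
        self.norm_h1 = BatchNorm(d)
        self.norm_h2 = BatchNorm(d)
        self.norm_e1 = BatchNorm(d)
        self.norm_e2 = BatchNorm(d)

    def parameters(self) -> list[Tensor]:
        params = [
            self.wq, self.bq, self.wk, self.bk, self.wv, self.bv, self.we, self.be,
            self.oh, self.boh, self.oe, self.boe,
            self.w1, self.b1, self.w2, self.b2,
            self.we1, self.be1, self.we2, self.be2,
        ]
        for norm in (self.norm_h1, self.norm_h2, self.norm_e1, self.norm_e2):
            params.extend(norm.parameters())
        return params

    def norms(self) -> list[BatchNorm]:
        return [self.norm_h1, self.norm_h2, self.norm_e1, self.norm_e2]

    def __call__(
        self,
        h: Tensor,
        e: Tensor,
        src: np.ndarray,
        dst: np.ndarray,
        training: bool,
    ) -> tuple[Tensor, Tensor]:
        cfg = self.cfg
        m = h.shape[0]
        n = e.shape[0]
        hd, dk = cfg.heads, cfg.d_head

        q = (h @ self.wq + self.bq).reshape(m, hd, dk)
        k = (h @ self.wk + self.bk).reshape(m, hd, dk)
        v = (h @ self.wv + self.bv).reshape(m, hd, dk)
        ep = (e @ self.we + self.be).reshape(n, hd, dk)

        if n:
            # per-head score vector for edge j -> i (receiver i = dst)
            base = gather_rows(q, dst) * gather_rows(k, src) * (1.0 / np.sqrt(dk))
            if cfg.edge_gate == "multiplicative":
                score = base * ep
            else:
                score = base + ep
            score = score.clip(-cfg.clamp, cfg.clamp)
            e_hat = score.reshape(n, cfg.d) @ self.oe + self.boe
            logits = score.sum(axis=2).clip(-cfg.clamp, cfg.clamp)
            attn = segment_softmax(logits, dst, m)  # rows sum to 1 per (node, head)
            self.last_attention = attn.data  # (n, heads); inspection/diagnostics
            msg = attn.reshape(n, hd, 1) * gather_rows(v, src)
            agg = segment_sum(msg, dst, m)  # zero rows for in-degree-0 nodes
            h_hat = agg.reshape(m, cfg.d) @ self.oh + self.boh
        else:
            self.last_attention = None
            h_hat = Tensor(np.zeros((m, cfg.d)))
            e_hat = e

        h1 = self.norm_h1(h + h_hat, training)
        h2 = (h1 @ self.w1 + self.b1).relu() @ self.w2 + self.b2
        h_out = self.norm_h2(h1 + h2, training)
        if n:
            e1 = self.norm_e1(e + e_hat, training)
            e2 = (e1 @ self.we1 + self.be1).relu() @ self.we2 + self.be2
            e_out = self.norm_e2(e1 + e2, training)
        else:
            e_out = e
        return h_out, e_out


class EdgeScorer:
    """Full scorer: feature embedding + LapPE + L transformer layers + MLP head."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.node_embed = init_embed_params(2, cfg.d, rng)
        self.edge_embed = init_embed_params(2, cfg.d, rng)
        self.wpe, self.bpe = _linear(rng, cfg.lappe_k, cfg.d)
        self.layers = [TransformerLayer(cfg, rng) for _ in range(cfg.layers)]
        widths = [3 * cfg.d, *cfg.mlp_hidden]
        self.mlp = []
        for a, b in zip(widths[:-1], widths[1:]):
            self.mlp.append(_linear(rng, a, b))
        if widths[-1] != 1:
            raise ValueError("score head must end in width 1")
        self._pe_cache: dict[int, np.ndarray] = {}

    # ------------------------------------------------------------- parameters

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for w, b in (*self.node_embed, *self.edge_embed):
            params.extend([w, b])
        params.extend([self.wpe, self.bpe])
        for layer in self.layers:
            params.extend(layer.parameters())
        for w, b in self.mlp:
            params.extend([w, b])
        return params

    def _norms(self) -> list[BatchNorm]:
        out = []
        for layer in self.layers:
            out.extend(layer.norms())
        return out

    # ----------------------------------------------------------------- forward

    def _positional(self, graph: AssemblyGraph, rng) -> np.ndarray:
        cfg = self.config
        m = graph.num_nodes
        k_eff = min(cfg.lappe_k, m - 1)
        cached = self._pe_cache.get(id(graph))
        if cached is None or cached.shape != (m, cfg.lappe_k):
            cached = np.zeros((m, cfg.lappe_k))
            if k_eff > 0:
                cached[:, :k_eff] = laplacian_pe(
                    graph, k_eff, normalized=cfg.normalized_laplacian
                )
            self._pe_cache[id(graph)] = cached
        if rng is not None:
            # training-time augmentation: random per-column sign flips
            return cached * np.where(rng.random(cfg.lappe_k) < 0.5, -1.0, 1.0)
        return cached

    def forward(
        self,
        graph: AssemblyGraph,
        features: FeatureSet,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        cfg = self.config
        m, n = graph.num_nodes, graph.num_edges
        if features.node_raw.shape[0] != m or features.edge_raw.shape[0] != n:
            raise ValueError("features not aligned to graph")
        if n == 0:
            return Tensor(np.zeros((0,)))
        src = np.fromiter((e.source for e in graph.edges), dtype=np.intp, count=n)
        dst = np.fromiter((e.target for e in graph.edges), dtype=np.intp, count=n)

        h = embed(features.node_raw, self.node_embed)
        pe = self._positional(graph, rng if training else None)
        h = h + (Tensor(pe) @ self.wpe + self.bpe)
        e = embed(features.edge_raw, self.edge_embed)

        for layer in self.layers:
            h, e = layer(h, e, src, dst, training)

        x = concat([gather_rows(h, src), gather_rows(h, dst), e], axis=1)
        for i, (w, b) in enumerate(self.mlp):
            x = x @ w + b
            if i < len(self.mlp) - 1:
                x = x.relu()
        # bound the final logit so scores stay strictly inside (0,1) in float64
        return x.reshape(n).clip(-30.0, 30.0).sigmoid()

    def score_edges(self, graph: AssemblyGraph, features: FeatureSet) -> np.ndarray:
        """Eval-mode probability per edge, aligned to edge_id order."""
        return self.forward(graph, features, training=False).data

    # ------------------------------------------------------------- checkpoint

    def save(self, path) -> None:
        arrays = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"p{i}"] = p.data
        for i, norm in enumerate(self._norms()):
            for key, val in norm.state().items():
                arrays[f"bn{i}_{key}"] = val
        cfg = asdict(self.config)
        cfg["mlp_hidden"] = list(cfg["mlp_hidden"])
        arrays["config_json"] = np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "EdgeScorer":
        data = np.load(path)
        cfg_dict = json.loads(bytes(data["config_json"]).decode())
        cfg_dict["mlp_hidden"] = tuple(cfg_dict["mlp_hidden"])
        model = cls(ModelConfig(**cfg_dict))
        for i, p in enumerate(model.parameters()):
            p.data = np.array(data[f"p{i}"])
        for i, norm in enumerate(model._norms()):
            norm.running_mean = np.array(data[f"bn{i}_running_mean"])
            norm.running_var = np.array(data[f"bn{i}_running_var"])
        return model
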