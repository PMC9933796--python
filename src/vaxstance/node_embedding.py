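"""Walk-based node embeddings: DeepWalk and Walklets trained by SGNS.

Both methods sample truncated random walks from the undirected simple graph
and treat them as sentences.  DeepWalk extracts (center, context) pairs at
all offsets 1..w inside a sliding window; Walklets extracts pairs at offset
exactly k, which makes the co-occurrence statistics approximate the k-th
power of the adjacency matrix, and learns one sub-embedding per scale
k = 1..K from the *same* walk corpus before concatenating them.

Training is skip-gram with negative sampling (SGNS), implemented as
vectorized mini-batch SGD in numpy with a linearly decaying learning rate
and noise draws from the unigram^(3/4) node distribution.  Single-threaded
and bit-reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class WalkConfig:
    """Random-walk sampling parameters (r walks of length l per node)."""

    walks_per_node: int = 10
    walk_length: int = 80
    node2vec_p: float = 1.0
    node2vec_q: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walks_per_node < 1 or self.walk_length < 1:
            raise ValueError("walks_per_node and walk_length must be >= 1")
        if self.node2vec_p <= 0 or self.node2vec_q <= 0:
            raise ValueError("node2vec_p and node2vec_q must be positive")


@dataclass(frozen=True)
class EmbedConfig:
    """SGNS training parameters.

    ``total_dim`` is the final embedding width; Walklets splits it evenly
    over ``scales`` sub-embeddings (per-scale width total_dim / scales).
    ``window`` applies to DeepWalk only.  The learning rate decays linearly
    from ``learning_rate`` to 1e-4 of it over all updates.
    """

    total_dim: int = 128
    scales: int = 4
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    batch_size: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_dim < 1 or self.scales < 1 or self.window < 1:
            raise ValueError("total_dim, scales and window must be >= 1")
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 1 and learning_rate positive")


@dataclass
class EmbeddingMatrix:
    """Node-id-indexed dense embedding with full provenance."""

    node_ids: np.ndarray
    vectors: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.node_ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, node) -> bool:
        return node in self._index

    def row(self, node) -> np.ndarray | None:
        """Embedding row for ``node``, or None when absent (e.g. pruned)."""
        i = self._index.get(node)
        return None if i is None else self.vectors[i]


# ---------------------------------------------------------------------------
# walks


def _csr_adjacency(graph: nx.Graph):
    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    indptr = np.zeros(len(nodes) + 1, dtype=np.int64)
    neigh_lists = []
    for i, n in enumerate(nodes):
        nb = sorted(index[m] for m in graph.neighbors(n))
        neigh_lists.append(np.asarray(nb, dtype=np.int64))
        indptr[i + 1] = indptr[i] + len(nb)
    indices = np.concatenate(neigh_lists) if neigh_lists else np.empty(0, dtype=np.int64)
    return nodes, index, indptr, indices


def sample_walks(graph: nx.Graph, config: WalkConfig) -> list[np.ndarray]:
    """Sample ``walks_per_node`` truncated random walks from every node.

    With node2vec_p = node2vec_q = 1 walks are first-order uniform over
    neighbors (vectorized across all walks); otherwise the second-order
    node2vec bias (return weight 1/p, in-neighborhood weight 1, outward
    weight 1/q) is applied.  Isolated nodes yield length-1 walks.  Walks are
    returned as arrays of original node ids.
    """
    nodes, _, indptr, indices = _csr_adjacency(graph)
    n = len(nodes)
    if n == 0:
        return []
    rng = np.random.default_rng([10, config.seed])
    ids = np.asarray(nodes, dtype=object)
    starts = np.tile(np.arange(n, dtype=np.int64), config.walks_per_node)
    deg = np.diff(indptr)

    if config.node2vec_p == 1.0 and config.node2vec_q == 1.0:
        walks = np.empty((len(starts), config.walk_length), dtype=np.int64)
        walks[:, 0] = starts
        active = deg[starts] > 0
        for step in range(1, config.walk_length):
            cur = walks[active, step - 1]
            offs = (rng.random(cur.shape[0]) * deg[cur]).astype(np.int64)
            walks[active, step] = indices[indptr[cur] + offs]
        lengths = np.where(deg[starts] > 0, config.walk_length, 1)
        return [ids[w[:length]] for w, length in zip(walks, lengths)]

    # second-order biased walks (node2vec); per-walk loop, used at small scale
    neigh = [indices[indptr[i]:indptr[i + 1]] for i in range(n)]
    neigh_sets = [set(a.tolist()) for a in neigh]
    out: list[np.ndarray] = []
    for start in starts:
        walk = [int(start)]
        for _ in range(config.walk_length - 1):
            cur = walk[-1]
            nb = neigh[cur]
            if len(nb) == 0:
                break
            if len(walk) == 1:
                nxt = int(nb[rng.integers(0, len(nb))])
            else:
                prev = walk[-2]
                w = np.where(
                    nb == prev,
                    1.0 / config.node2vec_p,
                    np.where(
                        [x in neigh_sets[prev] for x in nb], 1.0, 1.0 / config.node2vec_q
                    ),
                )
                nxt = int(nb[rng.choice(len(nb), p=w / w.sum())])
            walk.append(nxt)
        out.append(ids[np.asarray(walk, dtype=np.int64)])
    return out


# ---------------------------------------------------------------------------
# pair extraction


def extract_pairs(
    corpus: list[np.ndarray], mode: str, k_or_window: int, index: dict | None = None
) -> np.ndarray:
    """(center, context) pairs from a walk corpus, shape (n_pairs, 2).

    ``walklets`` emits both ordered pairs for every pair of walk positions at
    offset exactly ``k_or_window``; ``deepwalk`` does the same for every
    offset 1..window.  With ``index`` given, node ids are mapped to integer
    rows; otherwise pairs hold original ids.
    """
    if mode == "walklets":
        offsets = [k_or_window]
    elif mode == "deepwalk":
        offsets = list(range(1, k_or_window + 1))
    else:
        raise ValueError(f"unknown pair-extraction mode: {mode!r}")
    if k_or_window < 1:
        raise ValueError("skip factor / window must be >= 1")

    chunks = []
    for walk in corpus:
        if index is not None:
            walk = np.asarray([index[x] for x in walk], dtype=np.int64)
        for off in offsets:
            if off >= len(walk):
                continue
            a, b = walk[:-off], walk[off:]
            chunks.append(np.stack([a, b], axis=1))
            chunks.append(np.stack([b, a], axis=1))
    if not chunks:
        return np.empty((0, 2), dtype=np.int64 if index is not None else object)
    return np.concatenate(chunks, axis=0)


# ---------------------------------------------------------------------------
# SGNS


def sgns_pair_loss(u: np.ndarray, v_pos: np.ndarray, v_neg: np.ndarray):
    """Loss and analytic gradients for one SGNS example.

    loss = -log σ(u·v_pos) - Σ_j log σ(-u·v_neg_j).  Returns
    (loss, grad_u, grad_v_pos, grad_v_neg); used directly by training and by
    the finite-difference gradient check.
    """
    s_pos = float(u @ v_pos)
    s_neg = v_neg @ u
    loss = float(np.logaddexp(0.0, -s_pos) + np.logaddexp(0.0, s_neg).sum())
    g_pos = expit(s_pos) - 1.0  # d loss / d s_pos
    g_neg = expit(s_neg)  # d loss / d s_neg_j
    grad_u = g_pos * v_pos + g_neg @ v_neg
    grad_v_pos = g_pos * u
    grad_v_neg = g_neg[:, None] * u[None, :]
    return loss, grad_u, grad_v_pos, grad_v_neg


def train_sgns(
    pairs: np.ndarray,
    n_nodes: int,
    dim: int,
    cfg: EmbedConfig,
    seed: int | None = None,
    track_loss: bool = False,
):
    """Train SGNS on integer (center, context) pairs; returns the center matrix.

    Negatives are drawn from the unigram^(3/4) distribution of context
    tokens.  Pairs are reshuffled every epoch; updates are applied per
    mini-batch with `np.add.at` so repeated rows accumulate.  With
    ``track_loss`` returns (matrix, per-epoch mean losses).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([11, seed, dim])
    W = (rng.random((n_nodes, dim)) - 0.5) / dim  # center vectors
    C = np.zeros((n_nodes, dim))  # context vectors
    m = len(pairs)
    if m == 0:
        return (W, []) if track_loss else W

    counts = np.bincount(pairs[:, 1].astype(np.int64), minlength=n_nodes).astype(float)
    noise = counts**0.75
    noise /= noise.sum()

    total_steps = cfg.epochs * m
    lr0, lr_min = cfg.learning_rate, cfg.learning_rate * 1e-4
    done = 0
    losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(m)
        epoch_loss = 0.0
        for lo in range(0, m, cfg.batch_size):
            batch = pairs[order[lo:lo + cfg.batch_size]]
            B = len(batch)
            c = batch[:, 0]
            ctx = np.concatenate(
                [batch[:, 1:2], rng.choice(n_nodes, size=(B, cfg.negatives), p=noise)],
                axis=1,
            )  # (B, 1+neg); column 0 is the positive
            lr = max(lr_min, lr0 * (1.0 - done / total_steps))

            Wc = W[c]  # (B, d)
            Cc = C[ctx]  # (B, 1+neg, d)
            scores = np.einsum("bd,bkd->bk", Wc, Cc)
            if track_loss:
                epoch_loss += float(
                    np.logaddexp(0.0, -scores[:, 0]).sum()
                    + np.logaddexp(0.0, scores[:, 1:]).sum()
                )
            g = expit(scores)
            g[:, 0] -= 1.0  # sigmoid - label
            grad_W = np.einsum("bk,bkd->bd", g, Cc)
            grad_C = g[:, :, None] * Wc[:, None, :]
            np.add.at(W, c, -lr * grad_W)
            np.add.at(C, ctx.reshape(-1), -lr * grad_C.reshape(-1, dim))
            done += B
        if track_loss:
            losses.append(epoch_loss / m)
    return (W, losses) if track_loss else W


# ---------------------------------------------------------------------------
# full embedders


def walklets_embed(
    graph: nx.Graph, walk_cfg: WalkConfig | None = None, embed_cfg: EmbedConfig | None = None
) -> EmbeddingMatrix:
    """Multi-scale Walklets embedding.

    One shared walk corpus; for each scale k = 1..K an SGNS model of width
    total_dim/K is trained on offset-k pairs; sub-embeddings are concatenated
    in ascending k order.
    """
    walk_cfg = walk_cfg or WalkConfig()
    embed_cfg = embed_cfg or EmbedConfig()
    if embed_cfg.total_dim % embed_cfg.scales != 0:
        raise ValueError("total_dim must be divisible by scales")
    sub_dim = embed_cfg.total_dim // embed_cfg.scales

    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    corpus = sample_walks(graph, walk_cfg)
    mapped = [np.asarray([index[x] for x in w], dtype=np.int64) for w in corpus]
    parts = []
    for k in range(1, embed_cfg.scales + 1):
        pairs = extract_pairs(mapped, "walklets", k)
        parts.append(
            train_sgns(pairs, len(nodes), sub_dim, embed_cfg, seed=embed_cfg.seed * 1000 + k)
        )
    vectors = np.concatenate(parts, axis=1) if parts else np.empty((len(nodes), 0))
    return EmbeddingMatrix(
        node_ids=np.asarray(nodes, dtype=object),
        vectors=vectors,
        provenance=_provenance("walklets", walk_cfg, embed_cfg),
    )


def deepwalk_embed(
    graph: nx.Graph, walk_cfg: WalkConfig | None = None, embed_cfg: EmbedConfig | None = None
) -> EmbeddingMatrix:
    """DeepWalk embedding: window-based pairs, one SGNS of width total_dim."""
    walk_cfg = walk_cfg or WalkConfig()
    embed_cfg = embed_cfg or EmbedConfig()
    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    corpus = sample_walks(graph, walk_cfg)
    mapped = [np.asarray([index[x] for x in w], dtype=np.int64) for w in corpus]
    pairs = extract_pairs(mapped, "deepwalk", embed_cfg.window)
    vectors = train_sgns(pairs, len(nodes), embed_cfg.total_dim, embed_cfg)
    return EmbeddingMatrix(
        node_ids=np.asarray(nodes, dtype=object),
        vectors=vectors,
        provenance=_provenance("deepwalk", walk_cfg, embed_cfg),
    )


def node2vec_embed(
    graph: nx.Graph, walk_cfg: WalkConfig, embed_cfg: EmbedConfig | None = None
) -> EmbeddingMatrix:
    """DeepWalk-style training on second-order (p, q)-biased walks."""
    emb = deepwalk_embed(graph, walk_cfg, embed_cfg)
    emb.provenance["method"] = "node2vec"
    return emb


def _provenance(method: str, walk_cfg: WalkConfig, embed_cfg: EmbedConfig) -> dict:
    return {
        "method": method,
        "walk_config": dataclasses.asdict(walk_cfg),
        "embed_config": dataclasses.asdict(embed_cfg),
    }


# ---------------------------------------------------------------------------
# text round trip


def write_embedding(emb: EmbeddingMatrix, path) -> None:
    """TSV (node id + floats) with a JSON provenance sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    with open(path, "w") as fh:
        for node, vec in zip(emb.node_ids, emb.vectors):
            fh.write(str(node) + "\t" + "\t".join(repr(float(x)) for x in vec) + "\n")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(emb.provenance, fh, indent=1)


def read_embedding(path) -> EmbeddingMatrix:
    import json
    from pathlib import Path

    path = Path(path)
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            node = parts[0]
            try:
                node = int(node)
            except ValueError:
                pass
            ids.append(node)
            rows.append([float(x) for x in parts[1:]])
    sidecar = path.with_suffix(path.suffix + ".json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return EmbeddingMatrix(
        node_ids=np.asarray(ids, dtype=object),
        vectors=np.asarray(rows, dtype=float),
        provenance=provenance,
    )
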