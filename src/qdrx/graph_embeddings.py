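"""Node encoders for the knowledge graph, trained with an anchor-compactness loss.

Two encoder families, matching the two entity classes:

* genes — an inductive two-layer mean-neighborhood-aggregation encoder
  (per layer: linear transform of ``[self || mean(neighbors)]``, ReLU, and an
  L2-normalized output layer) trained on an unsupervised link objective over
  the gene-incident subgraph;
* drugs — a variational graph autoencoder: the encoder produces per-node
  means and log-variances, latents are drawn by reparameterization, and an
  inner-product decoder with a sigmoid reconstructs adjacency against
  sampled non-edges.

Both objectives add ``lambda_cluster`` times the anchor clustering loss (the
maximum pairwise Euclidean distance among embeddings of the known disease
entities) and an L2 penalty on the weights. During gradient steps the
clustering loss uses a smooth maximum (temperature-0.1 log-sum-exp) because
the subgradient of the hard maximum destabilizes training; reported values
always use the exact maximum.

The networks are small and the graphs full-batch, so forward/backward passes
are written directly in NumPy with an Adam optimizer; a numerical gradient
check in the test suite guards the derivations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit, logsumexp

from .kg import KnowledgeGraph

log = logging.getLogger(__name__)

_SMOOTH_MAX_TEMPERATURE = 0.1


@dataclass(frozen=True)
class EncoderConfig:
    embedding_dim: int = 16
    n_layers: int = 2
    hidden_dim: int | None = None  # defaults to 2 * embedding_dim
    lambda_cluster: float = 1.0
    l2_weight: float = 1e-2
    epochs: int = 200
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.lambda_cluster < 0 or self.l2_weight < 0:
            raise ValueError("lambda_cluster and l2_weight must be >= 0")
        if self.n_layers != 2:
            raise ValueError("this implementation is fixed at 2 aggregation layers")

    @property
    def hidden(self) -> int:
        return self.hidden_dim if self.hidden_dim is not None else 2 * self.embedding_dim

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class EmbeddingTable:
    """Per-node embedding vectors with provenance metadata."""

    ids: list[str]
    vectors: np.ndarray
    kind: str
    config_digest: str = ""
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("vectors must be (n_ids, dim)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding vectors must be finite")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate node ids in embedding table")
        self._index = {node: i for i, node in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def vector(self, node_id: str) -> np.ndarray:
        if node_id not in self._index:
            raise KeyError(f"no embedding for node {node_id!r}")
        return self.vectors[self._index[node_id]]

    def subset(self, node_ids) -> np.ndarray:
        return np.vstack([self.vector(n) for n in node_ids])

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        cols = [f"v{i + 1}" for i in range(self.dim)]
        df = pd.DataFrame(self.vectors, columns=cols)
        df.insert(0, "node_id", self.ids)
        df.to_csv(path, sep="\t", index=False)
        meta = {"kind": self.kind, "dim": self.dim, "config_digest": self.config_digest}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmbeddingTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        return cls(
            ids=df["node_id"].astype(str).tolist(),
            vectors=df.drop(columns=["node_id"]).to_numpy(float),
            kind=meta["kind"],
            config_digest=meta.get("config_digest", ""),
        )


# ---------------------------------------------------------------------------
# anchor clustering loss
# ---------------------------------------------------------------------------

def cluster_loss(vectors) -> float:
    """Maximum pairwise Euclidean distance within a set of vectors.

    This is the anchor-compactness penalty: minimizing it pulls the known
    disease entities into a tight cluster. A singleton has loss 0.
    """
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.size == 0 or arr.shape[0] == 0:
        raise ValueError("cluster_loss needs at least one vector")
    if arr.ndim != 2:
        raise ValueError("vectors must share a common dimension")
    if arr.shape[0] == 1:
        return 0.0
    diff = arr[:, None, :] - arr[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())


def _smooth_cluster_grad(z: np.ndarray, temperature: float = _SMOOTH_MAX_TEMPERATURE):
    """Smooth-max pairwise distance and its gradient w.r.t. the vectors."""
    m = z.shape[0]
    grad = np.zeros_like(z)
    if m < 2:
        return 0.0, grad
    iu, ju = np.triu_indices(m, k=1)
    diff = z[iu] - z[ju]
    dist = np.sqrt((diff**2).sum(axis=1) + 1e-12)
    value = temperature * logsumexp(dist / temperature)
    w = np.exp(dist / temperature - logsumexp(dist / temperature))
    g = (w / dist)[:, None] * diff
    np.add.at(grad, iu, g)
    np.add.at(grad, ju, -g)
    return float(value), grad


# ---------------------------------------------------------------------------
# shared pieces
# ---------------------------------------------------------------------------

def _row_normalized_adjacency(graph: nx.Graph, nodes: list[str]) -> sp.csr_matrix:
    idx = {n: i for i, n in enumerate(nodes)}
    rows, cols = [], []
    for u, v in graph.edges():
        if u in idx and v in idx:
            rows += [idx[u], idx[v]]
            cols += [idx[v], idx[u]]
    n = len(nodes)
    a = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(a.sum(axis=1)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    return sp.diags(inv) @ a  # isolated nodes aggregate a zero vector


def _edge_index(graph: nx.Graph, nodes: list[str]) -> np.ndarray:
    idx = {n: i for i, n in enumerate(nodes)}
    pairs = sorted((min(idx[u], idx[v]), max(idx[u], idx[v])) for u, v in graph.edges())
    return np.array(pairs, dtype=int).reshape(-1, 2)


def _sample_negatives(rng: np.random.Generator, n_nodes: int, count: int) -> np.ndarray:
    i = rng.integers(n_nodes, size=count)
    j = rng.integers(n_nodes, size=count)
    clash = i == j
    j[clash] = (j[clash] + 1) % n_nodes
    return np.column_stack([i, j])


def _bce_grad(z: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """Binary cross-entropy over edge logits z_i . z_j, and gradient dL/dZ."""
    pairs = np.vstack([pos, neg]) if len(neg) else pos
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    zi, zj = z[pairs[:, 0]], z[pairs[:, 1]]
    logits = (zi * zj).sum(axis=1)
    p = expit(logits)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    g = ((p - y) / len(y))[:, None]
    dz = np.zeros_like(z)
    np.add.at(dz, pairs[:, 0], g * zj)
    np.add.at(dz, pairs[:, 1], g * zi)
    return loss, dz


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def _check_anchors(anchors, nodes: list[str]) -> list[str]:
    anchors = list(anchors)
    if not anchors:
        raise ValueError("anchor set must be nonempty")
    present = set(nodes)
    for a in anchors:
        if a not in present:
            raise ValueError(f"anchor id absent from graph: {a!r}")
    return anchors


# ---------------------------------------------------------------------------
# gene encoder (mean-aggregation, link objective)
# ---------------------------------------------------------------------------

def _sage_forward(params, x, a):
    c0 = np.hstack([x, a @ x])
    s1 = c0 @ params["W1"] + params["b1"]
    h1 = np.maximum(s1, 0.0)
    c1 = np.hstack([h1, a @ h1])
    s2 = c1 @ params["W2"] + params["b2"]
    r = np.sqrt((s2**2).sum(axis=1, keepdims=True)) + 1e-12
    z = s2 / r
    return {"c0": c0, "s1": s1, "h1": h1, "c1": c1, "s2": s2, "r": r, "z": z}


def _sage_loss_grads(params, x, a, pos, neg, anchor_idx, lam, l2):
    """Total loss and parameter gradients for one full-batch step."""
    f = _sage_forward(params, x, a)
    z = f["z"]
    link_loss, dz = _bce_grad(z, pos, neg)
    smooth, ganchor = _smooth_cluster_grad(z[anchor_idx])
    dz[anchor_idx] += lam * ganchor
    loss = link_loss + lam * smooth + l2 * ((params["W1"] ** 2).sum() + (params["W2"] ** 2).sum())

    # back through row L2-normalization: z = s2 / r
    ds2 = (dz - z * (z * dz).sum(axis=1, keepdims=True)) / f["r"]
    h = params["W1"].shape[1]
    dW2 = f["c1"].T @ ds2 + 2 * l2 * params["W2"]
    db2 = ds2.sum(axis=0)
    dc1 = ds2 @ params["W2"].T
    dh1 = dc1[:, :h] + a.T @ dc1[:, h:]
    ds1 = dh1 * (f["s1"] > 0)
    dW1 = f["c0"].T @ ds1 + 2 * l2 * params["W1"]
    db1 = ds1.sum(axis=0)
    grads = {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}
    return loss, grads, f


def train_gene_encoder(
    kg: KnowledgeGraph,
    anchors,
    config: EncoderConfig | None = None,
    graph: nx.Graph | None = None,
) -> EmbeddingTable:
    """Train the gene encoder and return embeddings for every gene node.

    The training graph defaults to the gene-incident subgraph of ``kg``
    (gene-gene edges plus co-neighbor projection); pass ``graph`` to train on
    an explicit gene graph, e.g. with held-out edges.
    """
    config = config or EncoderConfig()
    if graph is None:
        graph = kg.gene_context_graph()
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("no gene nodes to embed")
    anchors = _check_anchors(anchors, nodes)
    pos = _edge_index(graph, nodes)
    if len(pos) == 0:
        raise ValueError("gene graph has no edges to train on")

    rng_init, rng_sample = np.random.default_rng(config.seed).spawn(2)
    n, h, d = len(nodes), config.hidden, config.embedding_dim
    x = rng_init.standard_normal((n, h)) / np.sqrt(h)
    a = _row_normalized_adjacency(graph, nodes)
    params = {
        "W1": _glorot(rng_init, 2 * h, h),
        "b1": np.zeros(h),
        "W2": _glorot(rng_init, 2 * h, d),
        "b2": np.zeros(d),
    }
    idx = {node: i for i, node in enumerate(nodes)}
    anchor_idx = np.array([idx[g] for g in anchors])

    opt = _Adam(params, config.learning_rate)
    history = []
    for _ in range(config.epochs):
        neg = _sample_negatives(rng_sample, n, len(pos))
        loss, grads, _ = _sage_loss_grads(
            params, x, a, pos, neg, anchor_idx, config.lambda_cluster, config.l2_weight
        )
        if not np.isfinite(loss):
            raise FloatingPointError("training loss diverged")
        opt.step(params, grads)
        history.append(float(loss))

    z = _sage_forward(params, x, a)["z"]
    return EmbeddingTable(
        ids=nodes, vectors=z, kind="gene", config_digest=config.digest(), history=history
    )


# ---------------------------------------------------------------------------
# drug encoder (variational autoencoder on the drug projection graph)
# ---------------------------------------------------------------------------

def edge_probability(z_i, z_j) -> float:
    """Inner-product decoder: sigmoid(z_i . z_j)."""
    return float(expit(np.dot(np.asarray(z_i, float), np.asarray(z_j, float))))


def _vgae_forward(params, x, a, eps):
    c0 = np.hstack([x, a @ x])
    s1 = c0 @ params["W1"] + params["b1"]
    h1 = np.maximum(s1, 0.0)
    b = np.hstack([h1, a @ h1])
    mu = b @ params["Wm"] + params["bm"]
    lv_raw = b @ params["Wl"] + params["bl"]
    lv = np.clip(lv_raw, -8.0, 8.0)
    z = mu + np.exp(0.5 * lv) * eps
    return {"c0": c0, "s1": s1, "h1": h1, "b": b, "mu": mu,
            "lv": lv, "lv_raw": lv_raw, "z": z}


def _vgae_loss_grads(params, x, a, pos, neg, eps, anchor_idx, lam, l2):
    f = _vgae_forward(params, x, a, eps)
    n = x.shape[0]
    mu, lv, z = f["mu"], f["lv"], f["z"]
    recon, dz = _bce_grad(z, pos, neg)
    # reconstruction is accounted per node (sum over sampled pairs / n), the
    # same relative weighting against the per-node KL as the canonical VGAE
    # full-adjacency objective; a per-pair mean lets the KL term collapse the
    # posterior means to a point
    scale = (len(pos) + len(neg)) / n
    recon *= scale
    dz = dz * scale
    kl = float(-0.5 / n * (1 + lv - mu**2 - np.exp(lv)).sum())
    smooth, ganchor = _smooth_cluster_grad(mu[anchor_idx])
    w_l2 = (params["W1"] ** 2).sum() + (params["Wm"] ** 2).sum() + (params["Wl"] ** 2).sum()
    loss = recon + kl + lam * smooth + l2 * w_l2

    dmu = dz + mu / n
    dmu[anchor_idx] += lam * ganchor
    dlv = dz * eps * 0.5 * np.exp(0.5 * lv) + 0.5 * (np.exp(lv) - 1.0) / n
    dlv *= np.abs(f["lv_raw"]) < 8.0  # clip gate
    h = params["W1"].shape[1]
    dWm = f["b"].T @ dmu + 2 * l2 * params["Wm"]
    dWl = f["b"].T @ dlv + 2 * l2 * params["Wl"]
    dbm, dbl = dmu.sum(axis=0), dlv.sum(axis=0)
    db = dmu @ params["Wm"].T + dlv @ params["Wl"].T
    dh1 = db[:, :h] + a.T @ db[:, h:]
    ds1 = dh1 * (f["s1"] > 0)
    dW1 = f["c0"].T @ ds1 + 2 * l2 * params["W1"]
    db1 = ds1.sum(axis=0)
    grads = {"W1": dW1, "b1": db1, "Wm": dWm, "bm": dbm, "Wl": dWl, "bl": dbl}
    return loss, grads, f


def train_drug_encoder(
    kg: KnowledgeGraph,
    anchors,
    config: EncoderConfig | None = None,
    graph: nx.Graph | None = None,
) -> EmbeddingTable:
    """Train the variational drug encoder; returns the posterior means.

    The adjacency being reconstructed is the one-mode drug projection of the
    knowledge graph (drugs connected when they share at least one target
    gene), so the inner-product decoder sees a homogeneous graph.
    """
    config = config or EncoderConfig()
    if graph is None:
        graph = kg.drug_projection_graph()
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("no drug nodes to embed")
    anchors = _check_anchors(anchors, nodes)
    pos = _edge_index(graph, nodes)
    if len(pos) == 0:
        raise ValueError("drug projection graph has no edges to train on")

    rng_init, rng_sample, rng_eps = np.random.default_rng(config.seed).spawn(3)
    n, h, d = len(nodes), config.hidden, config.embedding_dim
    x = rng_init.standard_normal((n, h)) / np.sqrt(h)
    a = _row_normalized_adjacency(graph, nodes)
    params = {
        "W1": _glorot(rng_init, 2 * h, h),
        "b1": np.zeros(h),
        "Wm": _glorot(rng_init, 2 * h, d),
        "bm": np.zeros(d),
        "Wl": _glorot(rng_init, 2 * h, d),
        "bl": np.zeros(d),
    }
    idx = {node: i for i, node in enumerate(nodes)}
    anchor_idx = np.array([idx[g] for g in anchors])

    opt = _Adam(params, config.learning_rate)
    history = []
    for _ in range(config.epochs):
        neg = _sample_negatives(rng_sample, n, len(pos))
        eps = rng_eps.standard_normal((n, d))
        loss, grads, _ = _vgae_loss_grads(
            params, x, a, pos, neg, eps, anchor_idx, config.lambda_cluster, config.l2_weight
        )
        if not np.isfinite(loss):
            raise FloatingPointError("training loss diverged")
        opt.step(params, grads)
        history.append(float(loss))

    mu = _vgae_forward(params, x, a, np.zeros((n, d)))["mu"]
    return EmbeddingTable(
        ids=nodes, vectors=mu, kind="drug", config_digest=config.digest(), history=history
    )


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------

def holdout_edges(graph: nx.Graph, test_frac: float = 0.1, seed: int = 0):
    """Split a graph into a training graph plus held-out positive edges and
    an equal count of sampled non-edges."""
    rng = np.random.default_rng(seed)
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    n_test = max(1, int(round(test_frac * len(edges))))
    test_idx = rng.choice(len(edges), size=n_test, replace=False)
    test_pos = [edges[i] for i in sorted(test_idx)]
    train = graph.copy()
    train.remove_edges_from(test_pos)
    nodes = sorted(graph.nodes)
    edge_set = set(edges)
    neg = []
    while len(neg) < n_test:
        u, v = rng.choice(len(nodes), size=2, replace=False)
        e = tuple(sorted((nodes[u], nodes[v])))
        if e not in edge_set and e not in neg:
            neg.append(e)
    return train, test_pos, neg


def reconstruction_auc(table: EmbeddingTable, pos_edges, neg_edges) -> float:
    """Rank AUC of decoder scores for held-out edges vs sampled non-edges."""
    from .scoring_eval import roc_auc

    scores, labels = [], []
    for u, v in pos_edges:
        scores.append(float(np.dot(table.vector(u), table.vector(v))))
        labels.append(1)
    for u, v in neg_edges:
        scores.append(float(np.dot(table.vector(u), table.vector(v))))
        labels.append(0)
    return roc_auc(np.array(scores), np.array(labels))
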