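"""Biological-similarity graph and manifold penalties.

The graph carries nonnegative pairwise weights C_ij over training
individuals, built as a k-nearest-neighbor graph on normalized genotype
features with a Gaussian kernel w_ij = exp(-d_ij^2 / (2 h^2)) and
symmetrized by max(w_ij, w_ji).  Two penalties are evaluated on it:

* manifold loss: sum over ordered pairs of w_ij * ||Z_i - Z_j||^2,
  divided by the number of ordered edges (scale stability);
* output smoothness: weighted mean of (yhat_i - yhat_j)^2 over ordered
  edges — a soft realization of the "similar genotypes, similar
  predictions" constraint.

Both sums run over ordered pairs without the diagonal: every undirected
edge contributes twice, matching a double-index sum convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class SimilarityGraph:
    """Undirected weighted graph stored as unique (i<j) edges."""

    edges_i: np.ndarray      # int, i < j
    edges_j: np.ndarray
    weights: np.ndarray      # in [0, 1]
    n_nodes: int
    k: int
    bandwidth: float

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def subgraph(self, node_idx: np.ndarray) -> "SimilarityGraph":
        """Induced subgraph on ``node_idx`` with batch-local indices."""
        node_idx = np.asarray(node_idx)
        pos = -np.ones(self.n_nodes, dtype=int)
        pos[node_idx] = np.arange(len(node_idx))
        keep = (pos[self.edges_i] >= 0) & (pos[self.edges_j] >= 0)
        return SimilarityGraph(
            edges_i=pos[self.edges_i[keep]], edges_j=pos[self.edges_j[keep]],
            weights=self.weights[keep], n_nodes=len(node_idx),
            k=self.k, bandwidth=self.bandwidth)

    def dense(self) -> np.ndarray:
        C = np.zeros((self.n_nodes, self.n_nodes))
        C[self.edges_i, self.edges_j] = self.weights
        C[self.edges_j, self.edges_i] = self.weights
        return C

    def batch_view(self, node_idx: np.ndarray) -> "BatchGraphView":
        """Stabilized mini-batch view of the graph penalties.

        The induced subgraph of a small batch may contain very few
        edges, so normalizing by the realized edge count (or weight sum)
        makes the penalty gradient stiffness blow up as 1/E_batch.  The
        view instead normalizes by the EXPECTED count under uniform
        batch sampling — full-graph totals scaled by the probability
        that both endpoints land in the batch — which is an unbiased
        estimator of the full-graph penalty and coincides with the
        plain definition when the batch is the whole node set.
        """
        node_idx = np.asarray(node_idx)
        b, n = len(node_idx), self.n_nodes
        p_pair = (b * (b - 1)) / (n * (n - 1)) if n > 1 else 1.0
        sub = self.subgraph(node_idx)
        return BatchGraphView(
            sub=sub,
            norm_edges=max(self.n_edges * p_pair, 1e-12),
            norm_wsum=max(float(self.weights.sum()) * p_pair, 1e-12))


@dataclass
class BatchGraphView:
    sub: SimilarityGraph
    norm_edges: float
    norm_wsum: float


def build_similarity(Xg: np.ndarray, k: int = 10,
                     h: float | str = "median") -> SimilarityGraph:
    """kNN graph with Gaussian-kernel weights on genotype features."""
    Xg = np.asarray(Xg, dtype=float)
    n = Xg.shape[0]
    if np.isnan(Xg).any():
        raise ValueError("genotype features contain missing values")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    if k == 0:
        return SimilarityGraph(edges_i=np.array([], dtype=int),
                               edges_j=np.array([], dtype=int),
                               weights=np.array([]), n_nodes=n, k=0,
                               bandwidth=float("nan"))

    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xg)
    dist, idx = nn.kneighbors(Xg)
    dist, idx = dist[:, 1:], idx[:, 1:]        # drop self

    if h == "median":
        bandwidth = float(np.median(dist))
        if bandwidth == 0.0:
            positive = dist[dist > 0]
            if positive.size == 0:
                bandwidth = 1.0                # all points coincide
            else:
                bandwidth = float(positive.min())
    else:
        bandwidth = float(h)
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")

    w = np.exp(-dist ** 2 / (2.0 * bandwidth ** 2))
    src = np.repeat(np.arange(n), k)
    dst = idx.ravel()
    wts = w.ravel()

    # symmetrize by max over the two directions, store i<j once
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    order = np.lexsort((hi, lo))
    lo, hi, wts = lo[order], hi[order], wts[order]
    key = lo.astype(np.int64) * n + hi
    uniq, inverse = np.unique(key, return_inverse=True)
    wmax = np.zeros(len(uniq))
    np.maximum.at(wmax, inverse, wts)
    ei = (uniq // n).astype(int)
    ej = (uniq % n).astype(int)
    return SimilarityGraph(edges_i=ei, edges_j=ej, weights=wmax,
                           n_nodes=n, k=k, bandwidth=bandwidth)


def manifold_loss(Z: np.ndarray, graph: SimilarityGraph,
                  norm_edges: float | None = None) -> float:
    """Edge-normalized ordered-pair sum of w_ij ||Z_i - Z_j||^2.

    ``norm_edges`` overrides the denominator (used by the stabilized
    mini-batch estimator); by default it is the realized edge count.
    Both the ordered-pair sum and the ordered-edge normalizer carry a
    factor of two relative to the unordered sums, so the factors cancel.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != graph.n_nodes:
        raise ValueError(f"Z has {Z.shape[0]} rows but graph has "
                         f"{graph.n_nodes} nodes")
    if graph.n_edges == 0:
        return 0.0
    denom = graph.n_edges if norm_edges is None else norm_edges
    diff = Z[graph.edges_i] - Z[graph.edges_j]
    sq = np.einsum("ij,ij->i", diff, diff)
    return float(np.sum(graph.weights * sq) / denom)


def manifold_loss_grad(Z: np.ndarray, graph: SimilarityGraph,
                       norm_edges: float | None = None) -> np.ndarray:
    """d manifold_loss / dZ (same ordered-pair, edge-normalized form)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    grad = np.zeros_like(Z)
    if graph.n_edges == 0:
        return grad
    denom = graph.n_edges if norm_edges is None else norm_edges
    diff = Z[graph.edges_i] - Z[graph.edges_j]
    contrib = (2.0 / denom) * graph.weights[:, None] * diff
    np.add.at(grad, graph.edges_i, contrib)
    np.add.at(grad, graph.edges_j, -contrib)
    return grad


def manifold_loss_scaled(Z: np.ndarray, graph: SimilarityGraph,
                         norm_edges: float | None = None,
                         with_grad: bool = False):
    """Scale-invariant manifold penalty used during training.

    The plain edge-normalized penalty has a trivial global optimum at a
    collapsed (constant) embedding, and under adaptive optimizers its
    persistent shrink direction can win over the data term.  Dividing by
    the batch embedding variance removes the pure-scale direction from
    the gradient — the same normalization Laplacian eigenmaps impose via
    their unit-variance constraint.  The value equals
    manifold_loss(Z, graph) / (mean_i ||Z_i - mean(Z)||^2 + eps).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    eps = 1e-8
    U = manifold_loss(Z, graph, norm_edges)
    Zc = Z - Z.mean(axis=0, keepdims=True)
    V = float(np.mean(np.einsum("ij,ij->i", Zc, Zc))) + eps
    L = U / V
    if not with_grad:
        return L
    dU = manifold_loss_grad(Z, graph, norm_edges)
    dV = (2.0 / Z.shape[0]) * Zc
    return L, (dU - L * dV) / V


def output_smoothness(yhat: np.ndarray, graph: SimilarityGraph,
                      norm_wsum: float | None = None) -> float:
    """Weighted mean squared prediction gap over graph edges."""
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(yhat) != graph.n_nodes:
        raise ValueError("prediction vector / graph size mismatch")
    if graph.n_edges == 0 or (norm_wsum is None and graph.weights.sum() == 0):
        warnings.warn("empty similarity graph: smoothness penalty is 0",
                      stacklevel=2)
        return 0.0
    denom = float(graph.weights.sum()) if norm_wsum is None else norm_wsum
    gaps = (yhat[graph.edges_i] - yhat[graph.edges_j]) ** 2
    return float(np.sum(graph.weights * gaps) / denom)


def output_smoothness_grad(yhat: np.ndarray, graph: SimilarityGraph,
                           norm_wsum: float | None = None) -> np.ndarray:
    yhat = np.asarray(yhat, dtype=float).ravel()
    grad = np.zeros_like(yhat)
    if graph.n_edges == 0:
        return grad
    denom = (float(graph.weights.sum()) if norm_wsum is None else norm_wsum)
    if denom == 0:
        return grad
    diff = yhat[graph.edges_i] - yhat[graph.edges_j]
    contrib = (2.0 / denom) * graph.weights * diff
    np.add.at(grad, graph.edges_i, contrib)
    np.add.at(grad, graph.edges_j, -contrib)
    return grad


# ---------------------------------------------------------------------------
# Persistence: 3-column edge TSV + JSON sidecar
# ---------------------------------------------------------------------------

def write_graph(graph: SimilarityGraph, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "graph_edges.tsv", "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j, w in zip(graph.edges_i, graph.edges_j, graph.weights):
            fh.write(f"{i}\t{j}\t{w:.12g}\n")
    with open(out_dir / "graph_meta.json", "w") as fh:
        json.dump({"k": graph.k, "h": graph.bandwidth,
                   "n": graph.n_nodes}, fh)


def read_graph(out_dir: str | Path) -> SimilarityGraph:
    out_dir = Path(out_dir)
    with open(out_dir / "graph_meta.json") as fh:
        meta = json.load(fh)
    rows = np.loadtxt(out_dir / "graph_edges.tsv", skiprows=1, ndmin=2)
    if rows.size == 0:
        ei = ej = np.array([], dtype=int)
        w = np.array([])
    else:
        ei, ej = rows[:, 0].astype(int), rows[:, 1].astype(int)
        w = rows[:, 2]
    return SimilarityGraph(edges_i=ei, edges_j=ej, weights=w,
                           n_nodes=int(meta["n"]), k=int(meta["k"]),
                           bandwidth=float(meta["h"]))
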